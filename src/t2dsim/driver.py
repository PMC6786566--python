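"""Alternating-step life-course driver, study-arm scenarios and endpoint
comparison utilities.

Each slow step (one month by default) runs one complete simulated day at the
current compensation state, then advances the slow variables by explicit
Euler using the day's aggregates.  The whole pipeline is deterministic;
randomness enters only through the synthetic observed-data fixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .daily import DailySummary, calibrate_toxicity, fasting_inputs, simulate_day
from .experiments import (ClampResult, IndexPanel, OGTTResult, index_panel,
                          run_clamp, run_ogtt)
from .nephron import build_grid
from .params import (ParameterSet, ScenarioConfig, TreatmentSpec,
                     builtin_treatment, load_parameters, validate_scenario)
from .slow import SlowState, fasting_insulin, natural_controls, slow_rhs
from .therapy import apply_effects

__all__ = [
    "LifeCourse",
    "EndpointSeries",
    "step",
    "run_scenario",
    "extract_endpoints",
    "generate_fixture",
    "compare",
    "ENDPOINT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: CSV dialect for observed / fixture endpoint files.
ENDPOINT_COLUMNS = ["visit_mo", "arm", "Gf_mM", "G30_mM", "G2h_mM", "If_pM", "I30_pM"]


def _controls_at(t: float, spec: TreatmentSpec, p: ParameterSet) -> dict[str, float]:
    """Therapy-modified control values at slow time ``t``.

    The five therapy channels are applied to their natural time courses;
    the ``eta`` channel acts on the pancreatic recovery rate.  Rates the
    treatments never touch (insulin elimination, glucotoxicity coefficient,
    excess mortality) pass through unchanged.
    """
    nat = natural_controls(t, p)
    treated = apply_effects(
        {ch: nat[ch] for ch in ("k_XGI", "lam_GI", "k_JS", "k_IB", "eta")},
        spec, t,
    )
    return {**nat, **treated}


def step(
    state: SlowState,
    spec: TreatmentSpec,
    p: ParameterSet,
    grid=None,
    tox=None,
    dt: float | None = None,
) -> tuple[SlowState, DailySummary]:
    """Advance the slow state by one Euler step of length ``dt`` months.

    Sequence: evaluate the (therapy-modified) control values at ``t``; run
    one simulated day from the fasted fast-equilibrium state; advance
    ``(B, eta, G_f, A)`` with the day's aggregates; floor ``eta`` at zero
    and clip ``B`` to ``[0, B_max]``.
    """
    dt = p.slow_dt if dt is None else dt
    grid = grid if grid is not None else build_grid(p)
    controls = _controls_at(state.t, spec, p)
    inputs = fasting_inputs(state.B, state.G_f, controls, p, mode="day", grid=grid)
    try:
        _, summary = simulate_day(inputs, p, grid=grid, tox=tox)
    except RuntimeError as err:
        raise RuntimeError(f"fast model failed at slow time t = {state.t} mo: {err}")
    deriv = slow_rhs(state, summary, p, controls)
    new = SlowState(
        t=state.t + dt,
        B=float(np.clip(state.B + dt * deriv.dB, 0.0, p.B_max)),
        eta=max(state.eta + dt * deriv.deta, 0.0),
        G_f=state.G_f + dt * deriv.dG_f,
        A=state.A + dt * deriv.dA,
        controls=controls,
    )
    return new, summary


@dataclass
class LifeCourse:
    """Recorded life-course of one scenario."""

    arm: str
    params: ParameterSet
    states: list[SlowState]
    summaries: list[DailySummary]
    panels: list[IndexPanel]
    ogtt: dict[float, OGTTResult] = field(default_factory=dict)
    clamp: dict[float, ClampResult] = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def state_at(self, t: float) -> SlowState:
        idx = int(np.argmin(np.abs(self.t - t)))
        if abs(self.states[idx].t - t) > 1e-6:
            raise KeyError(f"no recorded state at t = {t} mo")
        return self.states[idx]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, d, x in zip(self.states, self.summaries, self.panels):
            rows.append(
                {
                    "t_mo": s.t, "B_Mc": s.B, "eta": s.eta, "Gf_mM": s.G_f,
                    "HbA1c_pct": s.A,
                    "If_pM": fasting_insulin(
                        s.B, s.G_f, self.params,
                        k_XI=s.controls.get("k_XI"), k_IBmax=s.controls.get("k_IB"),
                    ) if s.controls else fasting_insulin(s.B, s.G_f, self.params),
                    "Gf24_mM": d.G_f24 if d is not None else np.nan,
                    "GB_mM": d.G_B if d is not None else np.nan,
                    "Geta": d.G_eta if d is not None else np.nan,
                    "urinary_mmol_day": d.urinary_mmol if d is not None else np.nan,
                    "HomaIR": x.homa_ir, "HomaB": x.homa_b,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        first, last = df.iloc[0], df.iloc[-1]
        lines = [
            f"Life course - arm '{self.arm}', {len(df)} monthly steps "
            f"({first.t_mo:.0f} to {last.t_mo:.0f} mo)",
            f"  beta-cell mass  : {first.B_Mc:8.1f} -> {last.B_Mc:8.1f} Mc "
            f"(peak {df.B_Mc.max():.1f} at {df.t_mo[df.B_Mc.idxmax()]:.0f} mo)",
            f"  fasting glycemia: {first.Gf_mM:8.2f} -> {last.Gf_mM:8.2f} mM",
            f"  fasting insulin : {first.If_pM:8.1f} -> {last.If_pM:8.1f} pM",
            f"  HbA1c           : {first.HbA1c_pct:8.2f} -> {last.HbA1c_pct:8.2f} %",
            f"  recorded OGTTs  : {len(self.ogtt)}, clamps: {len(self.clamp)}",
        ]
        return "\n".join(lines)


def run_scenario(
    config: ScenarioConfig | None = None,
    params: ParameterSet | None = None,
    initial_state: SlowState | None = None,
    progress: bool = False,
) -> LifeCourse:
    """Run a life-course scenario.

    Starts from the baseline state at ``t0`` (or from ``initial_state``) and
    advances month by month to the configured horizon, recording the slow
    state, the daily summary and the clinical index panel at every step, and
    OGTT/clamp experiments at the configured recording times.
    """
    config = config or ScenarioConfig()
    p = params if params is not None else load_parameters(config.overrides or None)
    config, spec = validate_scenario(config, p)
    grid = build_grid(p)
    tox = calibrate_toxicity(((p.tox_G1, p.tox_T1), (p.tox_G2, p.tox_T2)), p.tox_Tmax)

    state = initial_state if initial_state is not None else SlowState.initial(p)
    state.validate(p)
    t_stop = p.t0 + config.horizon
    ogtt_times = list(config.ogtt_at)
    clamp_times = list(config.clamp_at)

    states: list[SlowState] = []
    summaries: list[DailySummary] = []
    panels: list[IndexPanel] = []
    course = LifeCourse(
        arm=spec.name, params=p, states=states, summaries=summaries, panels=panels
    )

    n_steps = 0
    while state.t < t_stop - 1e-9:
        if not state.controls:
            state.controls = _controls_at(state.t, spec, p)
        ogtt = None
        if any(abs(state.t - t) < 1e-9 for t in ogtt_times):
            ogtt = run_ogtt(state, p, grid=grid)
            course.ogtt[state.t] = ogtt
        if any(abs(state.t - t) < 1e-9 for t in clamp_times):
            course.clamp[state.t] = run_clamp(state, p, grid=grid)
        new_state, summary = step(state, spec, p, grid=grid, tox=tox)
        states.append(state)
        summaries.append(summary)
        panels.append(index_panel(state, p, ogtt=ogtt))
        state = new_state
        n_steps += 1
        if progress and n_steps % 60 == 0:
            logger.info("t = %6.1f mo  B = %8.1f  Gf = %5.2f", state.t, state.B, state.G_f)

    # record the terminal state (with experiments if scheduled)
    state.controls = _controls_at(state.t, spec, p)
    ogtt = None
    if any(abs(state.t - t) < 1e-9 for t in ogtt_times):
        ogtt = run_ogtt(state, p, grid=grid)
        course.ogtt[state.t] = ogtt
    if any(abs(state.t - t) < 1e-9 for t in clamp_times):
        course.clamp[state.t] = run_clamp(state, p, grid=grid)
    states.append(state)
    summaries.append(None)
    panels.append(index_panel(state, p, ogtt=ogtt))
    return course


@dataclass
class EndpointSeries:
    """The five study endpoints sampled at protocol visits."""

    arm: str
    frame: pd.DataFrame                # columns = ENDPOINT_COLUMNS

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path


def extract_endpoints(course: LifeCourse, visits) -> EndpointSeries:
    """Sample the five endpoints at the given visit times [mo].

    Fasting glycemia and insulinemia come from the recorded slow states;
    the OGTT-derived endpoints (30-min and 2-h glycemia, 30-min
    insulinemia) require an OGTT recorded at the visit.
    """
    rows = []
    for t in sorted(visits):
        s = course.state_at(t)
        if t not in course.ogtt:
            raise KeyError(f"no OGTT recorded at visit t = {t} mo")
        o = course.ogtt[t]
        rows.append(
            {
                "visit_mo": t,
                "arm": course.arm,
                "Gf_mM": s.G_f,
                "G30_mM": o.G[30],
                "G2h_mM": o.G[120],
                "If_pM": o.I[0],
                "I30_pM": o.I[30],
            }
        )
    return EndpointSeries(arm=course.arm, frame=pd.DataFrame(rows, columns=ENDPOINT_COLUMNS))


def generate_fixture(
    seed: int,
    arm: str = "placebo",
    noise_sd: dict[str, float] | None = None,
    endpoints: EndpointSeries | None = None,
    visits=None,
    config: ScenarioConfig | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Synthetic observed-means file: simulated endpoints plus Gaussian noise.

    Emulates the averaged study visit data (the real individual-level data
    are not distributed with the package).  If ``endpoints`` is not given,
    the arm is simulated with OGTTs recorded at the visit times.
    """
    noise_sd = dict(noise_sd or {})
    if endpoints is None:
        if config is None:
            config = ScenarioConfig(treatment=arm, horizon=660.0, t_thx=600.0)
        visits = list(visits) if visits is not None else [600.0 + 12 * k for k in range(6)]
        config.ogtt_at = sorted(set(config.ogtt_at) | set(visits))
        course = run_scenario(config)
        endpoints = extract_endpoints(course, visits)
    rng = np.random.default_rng(seed)
    df = endpoints.frame.copy()
    for col in ("Gf_mM", "G30_mM", "G2h_mM", "If_pM", "I30_pM"):
        sd = float(noise_sd.get(col, 0.0))
        if sd > 0:
            df[col] = df[col] + rng.normal(0.0, sd, size=len(df))
    if path is not None:
        df.to_csv(path, index=False)
    return df


def compare(model: EndpointSeries, observed: pd.DataFrame | str | Path) -> dict:
    """Quantify model-vs-observed discrepancies per endpoint.

    The model series is interpolated linearly onto the observed visit grid;
    observed points are never modified.  Returns per-endpoint RMS and
    maximum absolute deviation plus the aligned overlay table.
    """
    if not isinstance(observed, pd.DataFrame):
        observed = pd.read_csv(observed)
    missing = [c for c in ENDPOINT_COLUMNS if c not in observed.columns]
    if missing:
        raise ValueError(f"observed data missing column(s): {missing}")
    mdf = model.frame.sort_values("visit_mo")
    odf = observed.sort_values("visit_mo")
    lo, hi = mdf.visit_mo.min(), mdf.visit_mo.max()
    if odf.visit_mo.min() < lo - 1e-9 or odf.visit_mo.max() > hi + 1e-9:
        raise ValueError(
            f"observed visits outside the model series range [{lo}, {hi}] mo"
        )
    report: dict = {"arm": model.arm, "endpoints": {}}
    overlay = {"visit_mo": odf.visit_mo.to_numpy()}
    for col in ("Gf_mM", "G30_mM", "G2h_mM", "If_pM", "I30_pM"):
        pred = np.interp(odf.visit_mo, mdf.visit_mo, mdf[col])
        dev = odf[col].to_numpy() - pred
        report["endpoints"][col] = {
            "rms": float(np.sqrt(np.mean(dev**2))),
            "max_abs": float(np.max(np.abs(dev))),
        }
        overlay[f"{col}_model"] = pred
        overlay[f"{col}_obs"] = odf[col].to_numpy()
    report["overlay"] = pd.DataFrame(overlay)
    return report
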