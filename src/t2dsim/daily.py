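"""Fast (minute-scale) model of one day: gastrointestinal transit, plasma
glucose, insulin and glucagon, co-integrated with the renal tubule.

State variables (all non-negative):

* ``S`` stomach glucose [mmol] - first-order emptying, impulsive meals;
* ``J`` intestinal glucose [mmol] - fed by the stomach, absorbed at ``k_GJ``,
  a fraction ``f_GJ`` of absorption appearing in plasma (``ra``);
* ``G`` plasma glucose [mM] - saturable insulin-dependent uptake, linear
  insulin-independent uptake, insulin-suppressible hepatic glucose output,
  glucagon-driven production, saturable brain oxidation, meal appearance and
  urinary loss;
* ``I`` serum insulin [pM] - first-order elimination, glucose-driven
  saturable secretion amplified by intestinal glucose (incretin effect);
* ``L`` serum glucagon [pM] - first-order elimination, secretion decaying
  exponentially with glycemia.

Meals are instantaneous additions to ``S`` (integrator stop/restart), and
the tubule concentration profile is advanced as part of one monolithic stiff
system (BDF with a sparse Jacobian pattern), so no splitting error or CFL
restriction arises.  Cumulative flux integrals are carried as quadrature
states, which lets the daily glucose bookkeeping close to solver tolerance.

The glucotoxicity weight applied to the day's glycemia is an increasing Hill
function calibrated so that a constant 5.5 mM day scores exactly 1 and a
constant 30 mM day scores 3.5, saturating at 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .nephron import NephronGrid, build_grid, steady_state
from .params import ParameterSet
from .slow import fasting_insulin

__all__ = [
    "ToxicityFunction",
    "calibrate_toxicity",
    "DailyInputs",
    "DailyTrace",
    "DailySummary",
    "gut_rhs",
    "glucagon_rhs",
    "glucagon_steady",
    "insulin_rhs",
    "glucose_rhs",
    "simulate_day",
    "summarize_trace",
    "default_meals",
    "fasting_inputs",
]


# ---------------------------------------------------------------------------
# glucotoxicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToxicityFunction:
    """Saturating Hill toxicity ``T(G) = T_max G^h / (K^h + G^h)``."""

    T_max: float
    h: float
    K: float

    def __call__(self, G):
        g = np.maximum(np.asarray(G, dtype=float), 0.0) ** self.h
        out = self.T_max * g / (self.K**self.h + g)
        return out if np.ndim(G) else float(out)


def calibrate_toxicity(
    anchors: tuple[tuple[float, float], tuple[float, float]] = ((5.5, 1.0), (30.0, 3.5)),
    T_max: float = 4.0,
) -> ToxicityFunction:
    """Hill toxicity through two anchor points below the asymptote.

    Closed form: the exponent follows from the log-odds ratio of the two
    anchors, the half constant from either anchor.
    """
    (g1, t1), (g2, t2) = anchors
    if not (0 < g1 < g2 and 0 < t1 < t2):
        raise ValueError("anchors must be strictly increasing in both coordinates")
    if not t2 < T_max:
        raise ValueError("anchor values must lie strictly below T_max")
    h = np.log((t2 / (T_max - t2)) / (t1 / (T_max - t1))) / np.log(g2 / g1)
    if h <= 0:
        raise ValueError("anchors inconsistent with an increasing Hill curve")
    K = g1 * ((T_max - t1) / t1) ** (1.0 / h)
    tox = ToxicityFunction(T_max=float(T_max), h=float(h), K=float(K))
    for g, t in (anchors):
        if abs(tox(g) - t) > 1e-9:
            raise ValueError(f"anchor residual at {g} mM exceeds 1e-9")
    return tox


# ---------------------------------------------------------------------------
# flux pieces (shared by the packed system and by unit tests)
# ---------------------------------------------------------------------------

def gut_rhs(S: float, J: float, k_JS: float, p: ParameterSet):
    """Stomach/intestine balance between meals; returns (dS, dJ, ra)."""
    dS = -k_JS * S
    dJ = k_JS * S - p.k_GJ * J
    ra = p.f_GJ * p.k_GJ * J
    return dS, dJ, ra


def glucagon_rhs(L: float, G: float, p: ParameterSet) -> float:
    """Glucagon balance: linear elimination, secretion decaying with glycemia."""
    sec = p.k_LG_max * (p.f_LG_min + (1.0 - p.f_LG_min) * np.exp(-p.lam_LG * max(G, 0.0)))
    return -p.k_XL * L + sec


def glucagon_steady(G: float, p: ParameterSet) -> float:
    """Glucagon concentration at which secretion balances elimination [pM]."""
    sec = p.k_LG_max * (p.f_LG_min + (1.0 - p.f_LG_min) * np.exp(-p.lam_LG * max(G, 0.0)))
    return sec / p.k_XL


def insulin_rhs(
    I: float, G: float, J: float, B: float, p: ParameterSet,
    k_XI: float | None = None, k_IBmax: float | None = None,
) -> float:
    """Insulin balance; secretion drive amplified by intestinal glucose."""
    from .slow import psi_igluc

    if k_XI is None:
        k_XI = p.k_XI_start
    G_eff = max(G, 0.0) * (1.0 + p.f_IJ * max(J, 0.0) / (p.J_G50 + max(J, 0.0)))
    return -k_XI * I + psi_igluc(B, G_eff, p, k_IBmax) / (p.V_I * p.W)


def glucose_rhs(
    G: float, I: float, L: float, ra: float, ur: float, p: ParameterSet,
    k_XGImax: float | None = None, lam_GI: float | None = None,
) -> float:
    """Plasma glucose balance [mM/min].

    The hepatic-output suppression exponent uses insulinemia in uIU/ml
    (``I / insulin_pM_per_uIU``); see :class:`~t2dsim.params.ParameterSet`.
    """
    if k_XGImax is None:
        k_XGImax = p.k_XGI0max
    if lam_GI is None:
        lam_GI = p.lam_GI0
    Gp, Ip, Lp = max(G, 0.0), max(I, 0.0), max(L, 0.0)
    uptake = k_XGImax * Ip / (Ip + p.I_KXGI50) * Gp + p.k_XG * Gp
    hgo = p.k_GI_max * np.exp(-lam_GI * (Ip / p.insulin_pM_per_uIU) * Gp)
    gluc = p.k_GL_max * Lp / (p.L_G50 + Lp)
    brain = p.W * p.k_Xgbrox_max * Gp / (p.G_brox50 + Gp)
    return -uptake + (hgo + gluc - brain + ra - ur) / (p.V_G * p.W)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DailyInputs:
    """Initial data, control values and schedule for one fast run."""

    G0: float                          # starting glycemia [mM]
    I0: float                          # starting insulinemia [pM]
    L0: float                          # starting glucagon [pM]
    B: float                           # beta-cell population [Mc]
    controls: dict[str, float]         # k_XGI, lam_GI, k_IB, k_JS, k_XI
    meals: list[tuple[float, float]]   # (tau [min], mass [mmol])
    tau_span: tuple[float, float]      # integration window [min]
    mode: str = "day"                  # day | ogtt | clamp
    C0: np.ndarray | None = None       # tubule profile (default: steady at G0)

    def validate(self) -> None:
        lo, hi = self.tau_span
        for tau, m in self.meals:
            if not (lo <= tau <= hi):
                raise ValueError(f"meal time {tau} outside window {self.tau_span}")
            if m < 0:
                raise ValueError(f"meal mass {m} must be non-negative")
        for v, name in ((self.G0, "G0"), (self.I0, "I0"), (self.L0, "L0"), (self.B, "B")):
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class DailyTrace:
    """Minute-resolution trajectories of the fast state and fluxes."""

    tau: np.ndarray
    S: np.ndarray
    J: np.ndarray
    G: np.ndarray
    I: np.ndarray
    L: np.ndarray
    ra: np.ndarray
    ur: np.ndarray
    C_end: np.ndarray                  # final tubule profile (incl. boundary)
    cumulative: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau_min": self.tau, "S": self.S, "J": self.J, "G": self.G,
                "I": self.I, "L": self.L, "ra": self.ra, "ur": self.ur,
            }
        )


@dataclass
class DailySummary:
    """Aggregates of one simulated day used by the slow model and indices."""

    G_f24: float                       # glycemia 24 h after the day start [mM]
    G_B: float                         # mean daily glycemia [mM]
    G_eta: float                       # mean daily glucotoxicity [#]
    G_mean: float
    G_sd: float
    G_min: float
    G_max: float
    I_mean: float
    I_sd: float
    I_min: float
    I_max: float
    urinary_mmol: float                # urinary glucose over the day [mmol]
    samples: dict[int, tuple[float, float]] = field(default_factory=dict)
    fluxes: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        eps = 1e-9
        if not (self.G_min - eps <= self.G_mean <= self.G_max + eps):
            raise ValueError("glycemia min <= mean <= max violated")
        if not (self.I_min - eps <= self.I_mean <= self.I_max + eps):
            raise ValueError("insulinemia min <= mean <= max violated")
        if self.G_eta < 0:
            raise ValueError("G_eta must be non-negative")


# ---------------------------------------------------------------------------
# the packed fast system
# ---------------------------------------------------------------------------

_N_CUM = 5  # ra, uptake, brain, production, urinary


def _make_rhs(p: ParameterSet, grid: NephronGrid, controls: dict[str, float], B: float):
    k_JS = controls["k_JS"]
    k_XI = controls["k_XI"]
    k_IB = controls["k_IB"]
    k_XGI = controls["k_XGI"]
    lam = controls["lam_GI"]
    VGW = p.V_G * p.W
    VIW = p.V_I * p.W
    nuIG, GI50 = p.nu_IG, p.G_I50 ** p.nu_IG
    pm_per_uiu = p.insulin_pM_per_uIU
    phi, dz, vin, sink_cap, c50 = grid.phi, grid.dz, grid.v[1:], grid.sink_cap[1:], grid.C_GU50
    nC = grid.z.size - 1

    def rhs(tau, y):
        S, J, G, I, L = y[0], y[1], y[2], y[3], y[4]
        C = y[5:5 + nC]
        Gp = G if G > 0 else 0.0
        Ip = I if I > 0 else 0.0
        Lp = L if L > 0 else 0.0
        # gut
        dS = -k_JS * S
        dJ = k_JS * S - p.k_GJ * J
        ra = p.f_GJ * p.k_GJ * J
        # tubule (conservative upwind)
        Cfull = np.empty(nC + 1)
        Cfull[0] = Gp
        np.maximum(C, 0.0, out=Cfull[1:])
        flux = phi * Cfull
        sink = sink_cap * Cfull[1:] / (c50 + Cfull[1:])
        dC = (-(flux[1:] - flux[:-1]) / dz - sink) / vin
        ur = p.W * Cfull[-1] * p.F_urine
        # plasma glucose
        uptake = k_XGI * Ip / (Ip + p.I_KXGI50) * Gp + p.k_XG * Gp
        hgo = p.k_GI_max * np.exp(-lam * (Ip / pm_per_uiu) * Gp)
        gluc = p.k_GL_max * Lp / (p.L_G50 + Lp)
        brain = p.W * p.k_Xgbrox_max * Gp / (p.G_brox50 + Gp)
        dG = -uptake + (hgo + gluc - brain + ra - ur) / VGW
        # insulin
        G_eff = Gp * (1.0 + p.f_IJ * J / (p.J_G50 + J)) if J > 0 else Gp
        g = G_eff ** nuIG
        dI = -k_XI * I + k_IB * B * g / (GI50 + g) / VIW
        # glucagon
        dL = -p.k_XL * L + p.k_LG_max * (
            p.f_LG_min + (1.0 - p.f_LG_min) * np.exp(-p.lam_LG * Gp)
        )
        out = np.empty(y.size)
        out[0], out[1], out[2], out[3], out[4] = dS, dJ, dG, dI, dL
        out[5:5 + nC] = dC
        # quadrature states: absorbed, uptake, brain, production, urinary
        out[5 + nC] = ra
        out[6 + nC] = uptake * VGW
        out[7 + nC] = brain
        out[8 + nC] = hgo + gluc
        out[9 + nC] = ur
        return out

    return rhs, nC


def _sparsity(nC: int) -> np.ndarray:
    n = 5 + nC + _N_CUM
    M = np.zeros((n, n), dtype=bool)
    M[0, 0] = True                      # S
    M[1, [0, 1]] = True                 # J
    M[2, [1, 2, 3, 4]] = True           # G <- J, G, I, L
    M[2, 5 + nC - 1] = True             # G <- outlet concentration (ur)
    M[3, [1, 2, 3]] = True              # I <- J, G, I
    M[4, [2, 4]] = True                 # L <- G, L
    M[5, [2, 5]] = True                 # first tubule node <- boundary G
    for i in range(6, 5 + nC):
        M[i, [i - 1, i]] = True
    M[5 + nC, 1] = True                 # cumulative absorbed <- J
    M[6 + nC, [2, 3]] = True
    M[7 + nC, 2] = True
    M[8 + nC, [2, 3, 4]] = True
    M[9 + nC, 5 + nC - 1] = True
    return M


def default_meals(p: ParameterSet) -> list[tuple[float, float]]:
    """The standard three-meal schedule (breakfast, lunch, dinner)."""
    return [(p.tau1, p.M1_gluc), (p.tau2, p.M2_gluc), (p.tau3, p.M3_gluc)]


def fasting_inputs(
    B: float,
    G_f: float,
    controls: dict[str, float],
    p: ParameterSet,
    mode: str = "day",
    meals: list[tuple[float, float]] | None = None,
    grid: NephronGrid | None = None,
) -> DailyInputs:
    """Fast-equilibrium initial data for a fasted subject at glycemia ``G_f``.

    Insulin starts at its secretion/elimination equilibrium, glucagon at its
    glycemia-conditional steady state and the tubule at its steady profile,
    so a meal-free run stays (approximately) stationary.
    """
    grid = grid or build_grid(p)
    I0 = fasting_insulin(B, G_f, p, k_XI=controls["k_XI"], k_IBmax=controls["k_IB"])
    L0 = glucagon_steady(G_f, p)
    if mode == "ogtt":
        span = (0.0, 180.0)
        meals = [(0.0, p.M1_gluc)] if meals is None else meals
    else:
        span = (p.tau0, p.tau_end)
        meals = default_meals(p) if meals is None else meals
    return DailyInputs(
        G0=G_f, I0=I0, L0=L0, B=B, controls=dict(controls), meals=meals,
        tau_span=span, mode=mode, C0=steady_state(G_f, grid),
    )


def simulate_day(
    inputs: DailyInputs,
    p: ParameterSet,
    grid: NephronGrid | None = None,
    tox: ToxicityFunction | None = None,
) -> tuple[DailyTrace, DailySummary]:
    """Integrate the fast system over the configured window.

    Meals are applied as instantaneous stomach loads at their scheduled
    times (stop/restart of the integrator).  The trace is reported on a
    1-minute grid; the summary averages the first 1440 minutes of the
    window (the complete day) in ``day`` mode, or samples the standard
    offsets in ``ogtt`` mode.
    """
    inputs.validate()
    grid = grid or build_grid(p)
    tox = tox or calibrate_toxicity(
        ((p.tox_G1, p.tox_T1), (p.tox_G2, p.tox_T2)), p.tox_Tmax
    )
    rhs, nC = _make_rhs(p, grid, inputs.controls, inputs.B)
    C0 = inputs.C0 if inputs.C0 is not None else steady_state(inputs.G0, grid)
    y = np.concatenate(
        [[0.0, 0.0, inputs.G0, inputs.I0, inputs.L0], C0[1:], np.zeros(_N_CUM)]
    )
    lo, hi = inputs.tau_span
    meal_times = sorted({tau for tau, m in inputs.meals if m > 0})
    meal_mass = {}
    for tau, m in inputs.meals:
        meal_mass[tau] = meal_mass.get(tau, 0.0) + m
    breaks = [lo] + [t for t in meal_times if lo < t <= hi] + [hi]
    sparsity = _sparsity(nC)

    ts, ys = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        if a in meal_mass:
            y[0] += meal_mass[a]
        t_eval = np.arange(np.ceil(a), np.floor(b) + 0.5)
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(
            rhs, (a, b), y, method="BDF", t_eval=t_eval,
            rtol=p.fast_rtol, atol=p.fast_atol, jac_sparsity=sparsity,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(
                f"fast solver failed at tau ~ {sol.t[-1] if sol.t.size else a} min: "
                f"{sol.message}; state head {sol.y[:5, -1] if sol.y.size else y[:5]}"
            )
        keep = slice(0, -1) if b != breaks[-1] else slice(None)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()

    tau = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    if float(Y[:5 + nC].min()) < -0.05:
        raise RuntimeError(
            f"fast state went significantly negative (min {Y[:5+nC].min():.3g})"
        )
    Y[:5 + nC] = np.maximum(Y[:5 + nC], 0.0)

    ra = p.f_GJ * p.k_GJ * Y[1]
    ur = p.W * Y[4 + nC] * p.F_urine
    cum = dict(
        zip(["absorbed", "uptake", "brain", "production", "urinary"], Y[5 + nC:, -1])
    )
    C_end = np.concatenate([[Y[2, -1]], Y[5:5 + nC, -1]])
    trace = DailyTrace(
        tau=tau, S=Y[0], J=Y[1], G=Y[2], I=Y[3], L=Y[4],
        ra=ra, ur=ur, C_end=C_end, cumulative=cum,
    )
    summary = summarize_trace(trace, p, tox, mode=inputs.mode)
    return trace, summary


def summarize_trace(
    trace: DailyTrace,
    p: ParameterSet,
    tox: ToxicityFunction | None = None,
    mode: str = "day",
) -> DailySummary:
    """Aggregate a fast trace into the slow-model summary statistics.

    In ``day`` mode the averages run over the first 1440 minutes of the
    trace and ``G_f24`` is the glycemia exactly 1440 minutes after the
    start.  In ``ogtt`` mode the standard 0/30/60/120-minute samples are
    recorded (relative to the start of the trace).
    """
    tox = tox or calibrate_toxicity(
        ((p.tox_G1, p.tox_T1), (p.tox_G2, p.tox_T2)), p.tox_Tmax
    )
    tau = trace.tau
    t_day_end = tau[0] + 1440.0
    day = tau <= t_day_end + 1e-9
    tt, G, I = tau[day], trace.G[day], trace.I[day]
    span = tt[-1] - tt[0]
    G_B = float(np.trapezoid(G, tt) / span)
    G_eta = float(np.trapezoid(tox(G), tt) / span)
    G_f24 = float(np.interp(t_day_end, tau, trace.G))
    samples: dict[int, tuple[float, float]] = {}
    if mode == "ogtt":
        for off in (0, 30, 60, 120):
            samples[off] = (
                float(np.interp(tau[0] + off, tau, trace.G)),
                float(np.interp(tau[0] + off, tau, trace.I)),
            )
    summary = DailySummary(
        G_f24=G_f24,
        G_B=G_B,
        G_eta=G_eta,
        G_mean=G_B,
        G_sd=float(np.sqrt(max(np.trapezoid((G - G_B) ** 2, tt) / span, 0.0))),
        G_min=float(G.min()),
        G_max=float(G.max()),
        I_mean=float(np.trapezoid(I, tt) / span),
        I_sd=float(np.sqrt(max(np.trapezoid((I - np.trapezoid(I, tt) / span) ** 2, tt) / span, 0.0))),
        I_min=float(I.min()),
        I_max=float(I.max()),
        urinary_mmol=float(trace.cumulative.get("urinary", np.trapezoid(trace.ur, tau))),
        samples=samples,
        fluxes=dict(trace.cumulative),
    )
    summary.validate()
    return summary
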