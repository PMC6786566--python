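"""Virtual perturbation experiments and clinical indices.

At any point of the simulated life the virtual subject can undergo

* an oral glucose tolerance test (OGTT): fasted start, a single 75-g
  (417 mmol) stomach load at test time zero, glycemia/insulinemia sampled at
  0, 30, 60 and 120 minutes;
* a two-step euglycemic hyperinsulinemic clamp: insulinemia forced to
  100 pM for 120 min and then 420 pM for 120 min while glycemia is held at
  the euglycemic target by an algebraically computed glucose infusion rate
  (GIR); the M values are the mean GIR over the final 30 minutes of each
  step, expressed in mg/kgBW/min.

The homeostasis-model indices use the standard clinical formulas with
insulin converted to uIU/ml:

    HOMA-IR = I_f[uIU/ml] * G_f[mM] / 22.5
    HOMA-B  = 20 * I_f[uIU/ml] / (G_f[mM] - 3.5)
    IGI     = (I_30 - I_0)[uIU/ml] / (G_30 - G_0)[mM]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .daily import fasting_inputs, glucagon_steady, simulate_day
from .nephron import NephronGrid, build_grid, steady_state
from .params import ParameterSet
from .slow import SlowState, fasting_insulin, natural_controls

__all__ = [
    "OGTTResult",
    "ClampResult",
    "IndexPanel",
    "run_ogtt",
    "run_clamp",
    "homa_ir",
    "homa_b",
    "insulinogenic",
    "index_panel",
]


@dataclass
class OGTTResult:
    """Sampled glycemia/insulinemia during a simulated OGTT."""

    G: dict[int, float]                # mM at 0/30/60/120 min
    I: dict[int, float]                # pM at the same offsets
    dose_mmol: float

    def I_uIU(self, offset: int, p: ParameterSet) -> float:
        return self.I[offset] / p.insulin_pM_per_uIU


@dataclass
class ClampResult:
    """Two-step euglycemic hyperinsulinemic clamp outcome."""

    M1: float                          # mg/kgBW/min, low-insulinization step
    M2: float                          # mg/kgBW/min, high-insulinization step
    plateaus_pM: tuple[float, float]
    target_mM: float
    tau: np.ndarray                    # min
    gir: np.ndarray                    # mmol/min (floored at 0)
    gir_negative: bool = False         # True if the raw GIR went negative


@dataclass
class IndexPanel:
    """HOMA indices (and, when an OGTT is available, the insulinogenic index)."""

    homa_ir: float
    homa_b: float | None               # None when G_f <= 3.5 mM (undefined)
    igi: float | None = None

    def as_dict(self) -> dict:
        return {"HomaIR": self.homa_ir, "HomaB": self.homa_b, "Igenicx": self.igi}


def _controls_for(state: SlowState, p: ParameterSet) -> dict[str, float]:
    c = dict(state.controls) if state.controls else {}
    needed = ("k_XGI", "lam_GI", "k_IB", "k_JS", "k_XI")
    if not all(k in c for k in needed):
        c = {**natural_controls(state.t, p), **c}
    return c


def run_ogtt(
    state: SlowState,
    p: ParameterSet,
    dose_mmol: float | None = None,
    grid: NephronGrid | None = None,
) -> OGTTResult:
    """Simulate a 75-g OGTT at the given slow state.

    The test is run as a separate protocol day: fasted fast-equilibrium
    start at the current fasting glycemia, a single stomach load at time
    zero, 180-minute horizon.
    """
    if dose_mmol is None:
        dose_mmol = p.M1_gluc
    controls = _controls_for(state, p)
    inputs = fasting_inputs(
        state.B, state.G_f, controls, p, mode="ogtt",
        meals=[(0.0, float(dose_mmol))], grid=grid,
    )
    _, summary = simulate_day(inputs, p, grid=grid)
    return OGTTResult(
        G={k: v[0] for k, v in summary.samples.items()},
        I={k: v[1] for k, v in summary.samples.items()},
        dose_mmol=float(dose_mmol),
    )


def run_clamp(
    state: SlowState,
    p: ParameterSet,
    plateaus_pM: tuple[float, float] = (100.0, 420.0),
    step_min: float = 120.0,
    target_mM: float = 5.0,
    steady_window_min: float = 30.0,
    grid: NephronGrid | None = None,
) -> ClampResult:
    """Two-step euglycemic hyperinsulinemic clamp.

    Insulin dynamics are bypassed (square-wave plateaus); glycemia is held
    exactly at ``target_mM`` by the infusion rate that zeroes the plasma
    glucose balance, including the urinary loss at the clamped glycemia.
    Glucagon and the renal tubule evolve dynamically from their
    fasted-state steady profiles.
    """
    controls = _controls_for(state, p)
    grid = grid or build_grid(p)
    G = float(target_mM)
    nC = grid.z.size - 1
    phi, dz, vin = grid.phi, grid.dz, grid.v[1:]
    sink_cap, c50 = grid.sink_cap[1:], grid.C_GU50

    def rhs(tau, y):
        L, C = y[0], y[1:]
        dL = -p.k_XL * L + p.k_LG_max * (
            p.f_LG_min + (1.0 - p.f_LG_min) * math.exp(-p.lam_LG * G)
        )
        Cfull = np.empty(nC + 1)
        Cfull[0] = G
        np.maximum(C, 0.0, out=Cfull[1:])
        flux = phi * Cfull
        sink = sink_cap * Cfull[1:] / (c50 + Cfull[1:])
        dC = (-(flux[1:] - flux[:-1]) / dz - sink) / vin
        return np.concatenate([[dL], dC])

    # start from the fasted state: glucagon and tubule at the pre-clamp G_f
    y0 = np.concatenate([[glucagon_steady(state.G_f, p)], steady_state(state.G_f, grid)[1:]])
    total = 2 * step_min
    t_eval = np.arange(0.0, total + 0.5)
    sol = solve_ivp(rhs, (0.0, total), y0, method="BDF", t_eval=t_eval,
                    rtol=p.fast_rtol, atol=p.fast_atol)
    if not sol.success:
        raise RuntimeError(f"clamp solver failed: {sol.message}")
    L = np.maximum(sol.y[0], 0.0)
    C_out = np.maximum(sol.y[-1], 0.0)
    I = np.where(sol.t < step_min, plateaus_pM[0], plateaus_pM[1])

    uptake = controls["k_XGI"] * I / (I + p.I_KXGI50) * G + p.k_XG * G
    hgo = p.k_GI_max * np.exp(-controls["lam_GI"] * (I / p.insulin_pM_per_uIU) * G)
    gluc = p.k_GL_max * L / (p.L_G50 + L)
    brain = p.W * p.k_Xgbrox_max * G / (p.G_brox50 + G)
    ur = p.W * C_out * p.F_urine
    gir_raw = uptake * p.V_G * p.W - hgo - gluc + brain + ur
    gir = np.maximum(gir_raw, 0.0)

    def m_value(t_lo: float, t_hi: float) -> float:
        win = (sol.t >= t_lo) & (sol.t <= t_hi)
        mean_gir = float(np.trapezoid(gir[win], sol.t[win]) / (t_hi - t_lo))
        return mean_gir * p.glucose_mg_per_mmol / p.W

    M1 = m_value(step_min - steady_window_min, step_min)
    M2 = m_value(total - steady_window_min, total)
    return ClampResult(
        M1=M1, M2=M2, plateaus_pM=tuple(plateaus_pM), target_mM=G,
        tau=sol.t, gir=gir, gir_negative=bool(np.any(gir_raw < 0)),
    )


def homa_ir(G_f: float, I_f: float, p: ParameterSet) -> float:
    """HOMA insulin-resistance index [(uIU/ml) mM]."""
    if G_f <= 0 or I_f < 0:
        raise ValueError("require G_f > 0 and I_f >= 0")
    return (I_f / p.insulin_pM_per_uIU) * G_f / 22.5


def homa_b(G_f: float, I_f: float, p: ParameterSet) -> float | None:
    """HOMA beta-cell function index [(uIU/ml)/mM]; None below 3.5 mM."""
    if G_f <= 0 or I_f < 0:
        raise ValueError("require G_f > 0 and I_f >= 0")
    if G_f <= 3.5:
        return None
    return 20.0 * (I_f / p.insulin_pM_per_uIU) / (G_f - 3.5)


def insulinogenic(ogtt: OGTTResult, p: ParameterSet) -> float | None:
    """Insulinogenic index: 0-30 min insulin rise per unit glucose rise."""
    dG = ogtt.G[30] - ogtt.G[0]
    dI = (ogtt.I[30] - ogtt.I[0]) / p.insulin_pM_per_uIU
    if dG == 0:
        return None
    return dI / dG


def index_panel(
    state: SlowState, p: ParameterSet, ogtt: OGTTResult | None = None
) -> IndexPanel:
    """HOMA indices from the current fasting state (plus IGI if OGTT given)."""
    controls = _controls_for(state, p)
    I_f = fasting_insulin(
        state.B, state.G_f, p, k_XI=controls["k_XI"], k_IBmax=controls["k_IB"]
    )
    return IndexPanel(
        homa_ir=homa_ir(state.G_f, I_f, p),
        homa_b=homa_b(state.G_f, I_f, p),
        igi=insulinogenic(ogtt, p) if ogtt is not None else None,
    )
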