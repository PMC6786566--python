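"""Therapy-effect kinetics: difference-of-exponentials time courses.

A treatment acting on a control variable follows the classical
pharmacodynamic onset/offset curve

    fexp(Ampl, alpha, beta, t) = Ampl * (exp(-beta t) - exp(-alpha t)) / peak(alpha, beta)

with ``alpha > beta > 0``: zero at ``t = 0``, peak value exactly ``Ampl`` at
``t_peak = log(alpha/beta) / (alpha - beta)``, and decay back to zero.  The
effect multiplies the natural (age-determined) value of the control variable
from the therapy start time onwards.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from .params import CONTROL_CHANNELS, TreatmentSpec

__all__ = [
    "t_peak",
    "peak",
    "fexp",
    "effect_value",
    "apply_effects",
    "calibrate_amplitude",
    "APPLICATION_STRATEGIES",
]

#: Lower clip for proportional effects so that rates stay positive.
_MIN_EFFECT = -0.99


def _check_rates(alpha: float, beta: float) -> None:
    if not (alpha > beta > 0):
        raise ValueError(f"require alpha > beta > 0, got alpha={alpha}, beta={beta}")


def t_peak(alpha: float, beta: float) -> float:
    """Time of maximal effect, ``log(alpha/beta) / (alpha - beta)`` [mo]."""
    _check_rates(alpha, beta)
    return float(np.log(alpha / beta) / (alpha - beta))


def peak(alpha: float, beta: float) -> float:
    """Normalizer: value of ``exp(-beta t) - exp(-alpha t)`` at its maximum."""
    tp = t_peak(alpha, beta)
    return float(np.exp(-beta * tp) - np.exp(-alpha * tp))


def fexp(Ampl: float, alpha: float, beta: float, t):
    """Normalized difference of exponentials, peak value exactly ``Ampl``.

    ``t`` is time elapsed since therapy start (months); negative times give 0.
    Accepts scalars or arrays.
    """
    if Ampl == 0.0:
        return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
    _check_rates(alpha, beta)
    tt = np.asarray(t, dtype=float)
    val = Ampl * (np.exp(-beta * tt) - np.exp(-alpha * tt)) / peak(alpha, beta)
    val = np.where(tt >= 0.0, val, 0.0)
    return val if np.ndim(t) else float(val)


def effect_value(spec: TreatmentSpec, channel: str, t: float) -> float:
    """Proportional effect E(t) of a treatment on one control channel."""
    eff = spec.effects[channel]
    if eff.Ampl == 0.0 or t < spec.t_thx:
        return 0.0
    return float(fexp(eff.Ampl, eff.alpha, eff.beta, t - spec.t_thx))


def _multiplicative(natural: float, E: float) -> float:
    return natural * (1.0 + max(E, _MIN_EFFECT))


def _saturating(natural: float, E: float) -> float:
    # bounded version: proportional change saturates at +/-100%
    return natural * (1.0 + E / (1.0 + abs(E)))


APPLICATION_STRATEGIES: dict[str, Callable[[float, float], float]] = {
    "multiplicative": _multiplicative,
    "saturating": _saturating,
}


def apply_effects(
    naturals: Mapping[str, float], spec: TreatmentSpec, t: float
) -> dict[str, float]:
    """Apply a treatment to the natural control values at slow time ``t``.

    ``naturals`` maps control channels (any subset of
    ``("k_XGI", "lam_GI", "k_JS", "k_IB", "eta")``) to their natural,
    age-determined values.  Before ``t_thx`` the map is returned unchanged.
    """
    unknown = set(naturals) - set(CONTROL_CHANNELS)
    if unknown:
        raise KeyError(f"unknown control channel(s): {sorted(unknown)}")
    combine = APPLICATION_STRATEGIES[spec.application_strategy]
    out = {}
    for ch, nat in naturals.items():
        E = effect_value(spec, ch, t)
        out[ch] = combine(nat, E) if E != 0.0 else nat
    return out


def calibrate_amplitude(
    target_peak_fraction: float,
    natural: Callable[[float], float],
    alpha: float,
    beta: float,
    t_thx: float,
    baseline: float,
    strategy: str = "multiplicative",
    ampl_bracket: tuple[float, float] = (0.0, 50.0),
    horizon: float = 240.0,
) -> float:
    """Solve for the amplitude achieving a given peak absolute improvement.

    Finds ``Ampl`` such that ``max_t [actual(t) - natural(t)]`` equals
    ``target_peak_fraction * baseline``, where ``baseline`` is the
    young-adult value of the control variable and ``actual`` applies the
    effect with the chosen strategy on top of the natural time course.

    This utility maps reported percent-of-normal improvements back onto
    effect amplitudes when the tabulated amplitudes are not appropriate for
    the chosen application strategy.
    """
    if target_peak_fraction < 0:
        raise ValueError("target_peak_fraction must be non-negative")
    if target_peak_fraction == 0:
        return 0.0
    _check_rates(alpha, beta)
    combine = APPLICATION_STRATEGIES[strategy]
    grid = t_thx + np.linspace(0.0, horizon, 2001)

    def achieved_peak(ampl: float) -> float:
        E = fexp(ampl, alpha, beta, grid - t_thx)
        nat = np.array([natural(t) for t in grid])
        actual = np.array([combine(n, e) for n, e in zip(nat, E)])
        return float(np.max(actual - nat))

    target = target_peak_fraction * baseline
    lo, hi = ampl_bracket
    f_lo, f_hi = achieved_peak(lo) - target, achieved_peak(hi) - target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no amplitude in {ampl_bracket} achieves peak increment {target}"
        )
    return float(brentq(lambda a: achieved_peak(a) - target, lo, hi, xtol=1e-10))
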