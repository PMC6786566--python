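"""Slow (monthly) dynamics: beta-cell population, replication reserve,
fasting glycemia and glycated haemoglobin.

The slow state evolves under

    dB/dt   = k_BB(eta, G_B) * B * (1 - B/B_max) - mu(t) * B
    deta/dt = -k_XetaG * G_eta * eta + k_eta(t)
    dG_f/dt = k_GG * (G_f24 - G_f)
    dA/dt   = k_AG * G_B - k_XA * A

where ``G_B`` (mean daily glycemia), ``G_eta`` (mean daily glucotoxicity,
1 = the toxicity of a constant 5.5 mM day) and ``G_f24`` (glycemia exactly
24 h after the day's start) are supplied by the fast daily model, and
``k_BB = kBB_min + eta * G_B^nu / (G_B50^nu + G_B^nu)`` is the net
replication rate.  The HbA1c balance (linear production from mean glycemia,
first-order elimination) is the only form consistent with the units of
``k_AG`` [%/mo/mM] and ``k_XA`` [/mo].

The "natural" (untreated) time courses of the control variables are also
defined here: shared Hill-in-time declines for peripheral and hepatic
insulin sensitivity and for secretory ability, linear drifts for insulin
elimination and pancreatic recovery, and a sigmoidal excess-mortality term
(zero in the type 2 scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ParameterSet

__all__ = [
    "SlowState",
    "SlowDerivative",
    "k_BB",
    "beta_cell_rhs",
    "eta_rhs",
    "mu_of_t",
    "natural_decay",
    "linear_drift",
    "natural_controls",
    "psi_igluc",
    "fasting_insulin",
    "slow_rhs",
]


@dataclass
class SlowState:
    """Slow variables at one month, plus the control values in force."""

    t: float                 # slow time [mo]
    B: float                 # beta-cell population [Mc]
    eta: float               # replication reserve [/mo]
    G_f: float               # fasting glycemia [mM]
    A: float                 # HbA1c [%]
    controls: dict = field(default_factory=dict)

    def validate(self, p: ParameterSet) -> None:
        if not (0.0 <= self.B <= p.B_max):
            raise ValueError(f"B = {self.B} outside [0, {p.B_max}]")
        if self.eta < 0:
            raise ValueError(f"eta = {self.eta} negative")
        if self.G_f <= 0 or self.A <= 0:
            raise ValueError(f"G_f = {self.G_f}, A = {self.A} must be positive")

    @classmethod
    def initial(cls, p: ParameterSet) -> "SlowState":
        return cls(t=p.t0, B=p.B0, eta=p.eta0, G_f=p.G_f0, A=p.A0)


@dataclass
class SlowDerivative:
    dB: float                # [Mc/mo]
    deta: float              # [/mo^2]
    dG_f: float              # [mM/mo]
    dA: float                # [%/mo]


def k_BB(eta: float, G_B: float, p: ParameterSet) -> float:
    """Net beta-cell replication rate [/mo]; bounded in [kBB_min, kBB_min + eta]."""
    g = G_B ** p.nu_BG
    return p.kBB_min + eta * g / (p.G_B50 ** p.nu_BG + g)


def beta_cell_rhs(B: float, kbb: float, mu: float, p: ParameterSet) -> float:
    """Logistic beta-cell growth with excess mortality [Mc/mo]."""
    return kbb * B * (1.0 - B / p.B_max) - mu * B


def eta_rhs(eta: float, G_eta: float, k_XetaG: float, k_eta: float) -> float:
    """Replication-reserve balance: glucotoxic erosion vs spontaneous recovery."""
    return -k_XetaG * G_eta * eta + k_eta


def mu_of_t(t: float, p: ParameterSet) -> float:
    """Sigmoidally progressing excess beta-cell mortality [/mo].

    With the default all-zero plateau this returns 0 at all times; non-zero
    ``mu_max`` produces the rapid beta-cell loss of autoimmune diabetes.
    """
    if t < p.t_mu_start:
        return p.mu0
    x = (t - p.t_mu_start) ** p.nu_mu
    return p.mu0 + (p.mu_max - p.mu0) * x / ((p.t_mu50 - p.t_mu_start) ** p.nu_mu + x)


def natural_decay(
    t: float, base: float, f_min: float, t_start: float, t_50: float, nu: float
) -> float:
    """Hill-in-time decline from ``base`` toward ``base * f_min``.

    Constant at ``base`` until ``t_start``; at ``t_50`` the decline has run
    exactly half of its total extent ``base * (1 - f_min)``.
    """
    if not t_50 > t_start:
        raise ValueError(f"t_50 ({t_50}) must exceed t_start ({t_start})")
    if not (0 < f_min <= 1):
        raise ValueError(f"f_min must lie in (0, 1], got {f_min}")
    if t <= t_start:
        return base
    x = (t - t_start) ** nu
    return base * (1.0 - (1.0 - f_min) * x / ((t_50 - t_start) ** nu + x))


def linear_drift(
    t: float, start_value: float, end_value: float, p: ParameterSet
) -> float:
    """Linear lifetime drift between ``t0`` and ``t_end``."""
    if not (p.t0 <= t <= p.t_end):
        raise ValueError(f"t = {t} outside [{p.t0}, {p.t_end}]")
    return start_value + (t - p.t0) / (p.t_end - p.t0) * (end_value - start_value)


def natural_controls(t: float, p: ParameterSet) -> dict[str, float]:
    """Natural (untreated) control values at slow time ``t``.

    Returns the five therapy channels plus the drifting rates that no
    treatment acts upon (insulin elimination, glucotoxicity coefficient,
    excess mortality).
    """
    return {
        "k_XGI": natural_decay(
            t, p.k_XGI0max, p.f_kXGI_min, p.t_kXGI_start, p.t_kXGI50, p.nu_kXGI
        ),
        "lam_GI": natural_decay(
            t, p.lam_GI0, p.f_lamGI_min, p.t_lamGI_start, p.t_lamGI50, p.nu_lamGI
        ),
        "k_IB": natural_decay(
            t, p.k_IB0max, p.f_kIB_min, p.t_kIB_start, p.t_kIB50, p.nu_kIB
        ),
        "k_JS": p.k_JS0,
        "eta": linear_drift(
            t, p.k_eta_start, p.k_eta_start * p.k_eta_endprop, p
        ),
        "k_XI": linear_drift(t, p.k_XI_start, p.k_XI_end, p),
        "k_XetaG": p.k_XetaG0,
        "mu": mu_of_t(t, p),
    }


def psi_igluc(B: float, G: float, p: ParameterSet, k_IBmax: float | None = None) -> float:
    """Glucose-driven pancreatic insulin secretion [pmol/min].

    Linear in beta-cell mass, saturating Hill in the driving glycemia.
    """
    if k_IBmax is None:
        k_IBmax = p.k_IB0max
    g = G ** p.nu_IG
    return k_IBmax * B * g / (p.G_I50 ** p.nu_IG + g)


def fasting_insulin(
    B: float,
    G_f: float,
    p: ParameterSet,
    k_XI: float | None = None,
    k_IBmax: float | None = None,
) -> float:
    """Fast-equilibrium fasting insulinemia [pM]: secretion / elimination."""
    if k_XI is None:
        k_XI = p.k_XI_start
    return psi_igluc(B, G_f, p, k_IBmax) / (p.V_I * p.W * k_XI)


def slow_rhs(
    state: SlowState,
    daily,
    p: ParameterSet,
    controls: dict[str, float] | None = None,
) -> SlowDerivative:
    """Monthly derivatives given the day's summary for the same state.

    ``daily`` must expose ``G_f24``, ``G_B`` and ``G_eta`` (a
    :class:`~t2dsim.daily.DailySummary`).
    """
    c = controls or state.controls or natural_controls(state.t, p)
    kbb = k_BB(state.eta, daily.G_B, p)
    return SlowDerivative(
        dB=beta_cell_rhs(state.B, kbb, c.get("mu", 0.0), p),
        deta=eta_rhs(state.eta, daily.G_eta, c.get("k_XetaG", p.k_XetaG0), c["eta"]),
        dG_f=p.k_GG * (daily.G_f24 - state.G_f),
        dA=p.k_AG * daily.G_B - p.k_XA * state.A,
    )
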