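"""Model parameters, treatment specifications and scenario configuration.

All symbols of the progression model live in :class:`ParameterSet`, one field
per physiological constant, with the units given in the field metadata.  The
default construction is the calibrated baseline subject of the untreated
at-risk cohort; every value can be overridden individually, either
programmatically or from a YAML/JSON document (see :func:`load_parameters`).

Treatment arms are described by :class:`TreatmentSpec`: one
difference-of-exponentials effect per control variable (peripheral insulin
sensitivity ``k_XGI``, hepatic insulin sensitivity ``lam_GI``, gastric
emptying ``k_JS``, secretory ability ``k_IB`` and reserve recovery ``eta``).
The built-in library (:func:`builtin_treatment`) holds the four study arms:
no treatment, placebo, intensive lifestyle and metformin.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ParameterSet",
    "ControlEffect",
    "TreatmentSpec",
    "ScenarioConfig",
    "load_parameters",
    "builtin_treatment",
    "validate_scenario",
    "dump_defaults",
    "CONTROL_CHANNELS",
    "UNITS",
]

logger = logging.getLogger(__name__)

#: Control variables a therapy may act on.
CONTROL_CHANNELS = ("k_XGI", "lam_GI", "k_JS", "k_IB", "eta")

#: Units for every ParameterSet field (used by ``dump_defaults``).
UNITS: dict[str, str] = {
    "t0": "mo", "t_end": "mo",
    "B_max": "Mc", "B0": "Mc",
    "nu_BG": "#", "G_B50": "mM",
    "eta0": "/mo", "k_XetaG0": "/mo",
    "k_eta_start": "/mo^2", "k_eta_endprop": "#",
    "k_GG": "/mo", "G_f0": "mM",
    "k_XA": "/mo", "A0": "%", "k_AG": "%/mo/mM",
    "V_G": "L/kg", "V_I": "L/kg", "W": "kg",
    "k_XI_start": "/min", "k_XI_end": "/min",
    "k_XGI0max": "/min", "k_XGI00": "/min/pM",
    "f_kXGI_min": "#", "t_kXGI_start": "mo", "nu_kXGI": "#", "t_kXGI50": "mo",
    "lam_GI0": "/(uIU/ml)/mM",
    "f_lamGI_min": "#", "t_lamGI_start": "mo", "nu_lamGI": "#", "t_lamGI50": "mo",
    "k_IB0max": "pmol/min/Mc",
    "f_kIB_min": "#", "t_kIB_start": "mo", "nu_kIB": "#", "t_kIB50": "mo",
    "k_JS0": "/min",
    "tau0": "min", "tau_end": "min",
    "tau1": "min", "tau2": "min", "tau3": "min",
    "M1_gluc": "mmol", "M2_gluc": "mmol", "M3_gluc": "mmol",
    "k_Xgbrox_max": "mmol/kg/min", "G_brox50": "mM",
    "k_GJ": "/min", "f_GJ": "#", "k_XG": "/min",
    "k_GI_max": "mmol/min", "L_G50": "pM", "L0": "pM",
    "k_XL": "/min", "f_LG_min": "#", "lam_LG": "/mM",
    "f_IJ": "#", "J_G50": "mmol",
    "nu_IG": "#", "G_I50": "mM",
    "Cl_inulin": "L/kg/min", "F_urine": "L/kg/min",
    "D_U": "/z^2", "k_GU_max": "mmol/kg/min", "C_GU50": "mM",
    "lam_VZ": "/z", "lam_QZ": "/z",
    "I_f0": "pM", "I_KXGI50": "pM",
    "k_GL_max": "mmol/min", "k_LG_max": "pM/min",
    "kBB_min": "/mo",
    "mu0": "/mo", "mu_max": "/mo", "t_mu_start": "mo", "t_mu50": "mo", "nu_mu": "#",
    "tubule_T": "min", "N_z": "#", "slow_dt": "mo",
    "fast_rtol": "#", "fast_atol": "state units",
    "glucose_mg_per_mmol": "mg/mmol", "insulin_pM_per_uIU": "pM/(uIU/ml)",
    "tox_G1": "mM", "tox_T1": "#", "tox_G2": "mM", "tox_T2": "#", "tox_Tmax": "#",
}

_POSITIVE = (
    "B_max", "B0", "nu_BG", "G_B50", "k_XetaG0", "k_eta_start", "k_eta_endprop",
    "k_GG", "G_f0", "k_XA", "A0", "k_AG", "V_G", "V_I", "W",
    "k_XI_start", "k_XI_end", "k_XGI0max", "k_XGI00", "nu_kXGI",
    "lam_GI0", "nu_lamGI", "k_IB0max", "nu_kIB", "k_JS0",
    "M1_gluc", "M2_gluc", "M3_gluc", "k_Xgbrox_max", "G_brox50",
    "k_GJ", "k_XG", "k_GI_max", "L_G50", "L0", "k_XL", "lam_LG",
    "f_IJ", "J_G50", "nu_IG", "G_I50", "Cl_inulin", "F_urine",
    "k_GU_max", "C_GU50", "lam_VZ", "lam_QZ", "I_f0", "I_KXGI50",
    "k_GL_max", "k_LG_max", "tubule_T", "slow_dt", "fast_rtol", "fast_atol",
    "glucose_mg_per_mmol", "insulin_pM_per_uIU", "tox_Tmax",
)
_FRACTIONS = ("f_kXGI_min", "f_lamGI_min", "f_kIB_min", "f_LG_min", "f_GJ")
_DECAY_TRIPLES = (
    ("t_kXGI_start", "t_kXGI50"),
    ("t_lamGI_start", "t_lamGI50"),
    ("t_kIB_start", "t_kIB50"),
    ("t_mu_start", "t_mu50"),
)


class ParameterSet(BaseModel):
    """Complete parameter set of the fast-slow progression model.

    Defaults are the calibrated baseline subject.  Two printed values of the
    source calibration are internally inconsistent and are resolved here in
    favour of dynamical self-consistency (the baseline must be a stationary
    state of the model):

    * the peripheral uptake pair ``(k_XGI0max, I_KXGI50)`` defaults to
      ``(0.05 /min, 500 pM)``, the pair satisfying the defining identity
      ``k_XGI0max = I_KXGI50 * k_XGI00`` with ``k_XGI00 = 1e-4 /min/pM``;
    * the hepatic-suppression exponent is ``lam_GI * I[uIU/ml] * G[mM]``
      (insulinemia converted by ``insulin_pM_per_uIU``), under which the
      baseline fasting glycemia ``G_f0`` is a fixed point of the fast model.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # -- slow model -------------------------------------------------------
    t0: float = 0.0                    # start of slow integration [mo]
    t_end: float = 1080.0              # end of life [mo]
    B_max: float = 4000.0              # beta-cell carrying capacity [Mc]
    B0: float = 1000.0                 # baseline beta-cell population [Mc]
    nu_BG: float = 2.0                 # Hill exponent, replication stimulation
    G_B50: float = 9.0                 # half-max replication stimulation [mM]
    eta0: float = 0.04                 # baseline replication reserve [/mo]
    k_XetaG0: float = 0.02             # baseline glucotoxic reserve decay [/mo]
    k_eta_start: float = 0.00085       # pancreatic recovery rate at t0 [/mo^2]
    k_eta_endprop: float = 0.4         # recovery at t_end as fraction of start
    k_GG: float = 0.4                  # G_f relaxation toward G_f24 [/mo]
    G_f0: float = 4.2                  # baseline fasting glycemia [mM]
    k_XA: float = 0.4                  # HbA1c elimination [/mo]
    A0: float = 5.0                    # baseline HbA1c [%]
    k_AG: float = 0.395                # HbA1c production from glycemia [%/mo/mM]
    kBB_min: float = -0.0104           # minimum net replication rate [/mo]

    # excess mortality sigmoid (all-zero in the type 2 scenario)
    mu0: float = 0.0
    mu_max: float = 0.0
    t_mu_start: float = 600.0
    t_mu50: float = 700.0
    nu_mu: float = 2.0

    # -- volumes / subject ------------------------------------------------
    V_G: float = 0.19                  # glucose distribution volume [L/kg]
    V_I: float = 0.19                  # insulin distribution volume [L/kg]
    W: float = 70.0                    # body weight [kg]

    # -- natural time-courses of the control variables --------------------
    k_XI_start: float = 0.05           # insulin elimination at t0 [/min]
    k_XI_end: float = 0.045            # insulin elimination at t_end [/min]
    k_XGI0max: float = 0.05            # peripheral uptake maximum at t0 [/min]
    k_XGI00: float = 1.0e-4            # zero-insulin uptake slope [/min/pM]
    f_kXGI_min: float = 0.05
    t_kXGI_start: float = 216.0
    nu_kXGI: float = 3.0
    t_kXGI50: float = 800.0
    lam_GI0: float = 0.015             # hepatic insulin sensitivity [/(uIU/ml)/mM]
    f_lamGI_min: float = 0.05
    t_lamGI_start: float = 216.0
    nu_lamGI: float = 8.0
    t_lamGI50: float = 550.0
    k_IB0max: float = 0.5              # max secretion per Mc at t0 [pmol/min/Mc]
    f_kIB_min: float = 0.25
    t_kIB_start: float = 216.0
    nu_kIB: float = 2.5
    t_kIB50: float = 950.0
    k_JS0: float = 0.0235              # gastric emptying [/min]

    # -- daily model ------------------------------------------------------
    tau0: float = 360.0                # day start, minutes after midnight
    tau_end: float = 1800.0            # day end (next-day 06:00)
    tau1: float = 420.0                # breakfast [min]
    M1_gluc: float = 417.0             # breakfast glucose [mmol]
    tau2: float = 720.0                # lunch [min]
    M2_gluc: float = 280.0
    tau3: float = 1080.0               # dinner [min]
    M3_gluc: float = 280.0
    k_Xgbrox_max: float = 0.0059       # max brain glucose oxidation [mmol/kg/min]
    G_brox50: float = 0.5              # half-max brain oxidation [mM]
    k_GJ: float = 0.025                # intestinal absorption [/min]
    f_GJ: float = 0.9                  # fraction reaching circulation
    k_XG: float = 0.001                # insulin-independent uptake [/min]
    k_GI_max: float = 0.75             # max insulin-suppressible HGO [mmol/min]
    L_G50: float = 0.05                # glucagon half-effect on HGO [pM]
    L0: float = 15.0                   # fasting glucagon [pM]
    k_XL: float = 0.04                 # glucagon elimination [/min]
    f_LG_min: float = 0.15
    lam_LG: float = 0.55               # glucagon suppression by glycemia [/mM]
    f_IJ: float = 1.15                 # max incretin amplification [#]
    J_G50: float = 200.0               # half-max incretin effect [mmol]
    nu_IG: float = 3.0                 # secretion Hill exponent
    G_I50: float = 14.4                # half-max secretion glycemia [mM]
    I_f0: float = 19.8                 # tabulated baseline fasting insulin [pM]
    I_KXGI50: float = 500.0            # half-max peripheral uptake insulin [pM]
    k_GL_max: float = 0.0685           # max glucagon-driven production [mmol/min]
    k_LG_max: float = 2.56             # max glucagon secretion drive [pM/min]

    # -- nephron ----------------------------------------------------------
    Cl_inulin: float = 0.0018          # GFR [L/kg/min]
    F_urine: float = 0.00002           # urine flow [L/kg/min]
    D_U: float = 0.0                   # tubular glucose diffusion [/z^2]
    k_GU_max: float = 0.027            # max tubular reabsorption [mmol/kg/min]
    C_GU50: float = 19.0               # half-max reabsorption [mM]
    lam_VZ: float = 8.0                # water reabsorption decay [/z]
    lam_QZ: float = 7.0                # transporter density decay [/z]

    # -- implementation-owned ---------------------------------------------
    tubule_T: float = 5.0              # ultrafiltrate transit time [min]
    N_z: int = Field(default=101, ge=3)  # nephron grid nodes
    slow_dt: float = 1.0               # slow Euler step [mo]
    fast_rtol: float = 1.0e-6          # daily integrator relative tolerance
    fast_atol: float = 1.0e-8          # daily integrator absolute tolerance
    glucose_mg_per_mmol: float = 180.16
    insulin_pM_per_uIU: float = 6.0    # pM per uIU/ml; 1.0 = literal pM exponent
    tox_G1: float = 5.5                # toxicity anchor glycemias/values
    tox_T1: float = 1.0
    tox_G2: float = 30.0
    tox_T2: float = 3.5
    tox_Tmax: float = 4.0

    @model_validator(mode="after")
    def _check_invariants(self) -> "ParameterSet":
        for name in _POSITIVE:
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in _FRACTIONS:
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not self.t_end > self.t0:
            raise ValueError(f"t_end ({self.t_end}) must exceed t0 ({self.t0})")
        if self.tau_end - self.tau0 < 1440:
            raise ValueError(
                f"daily window tau_end - tau0 = {self.tau_end - self.tau0} "
                "min must cover at least 1440 min"
            )
        for start, half in _DECAY_TRIPLES:
            if not getattr(self, half) > getattr(self, start):
                raise ValueError(
                    f"{half} ({getattr(self, half)}) must exceed "
                    f"{start} ({getattr(self, start)})"
                )
        if self.B0 > self.B_max:
            raise ValueError(f"B0 ({self.B0}) must not exceed B_max ({self.B_max})")
        for tau in ("tau1", "tau2", "tau3"):
            v = getattr(self, tau)
            if not (self.tau0 <= v <= self.tau_end):
                raise ValueError(f"{tau} = {v} outside daily window")
        if self.D_U < 0:
            raise ValueError("D_U must be non-negative")
        if not (0 < self.tox_G1 < self.tox_G2):
            raise ValueError("toxicity anchor glycemias must be increasing and positive")
        if not (0 < self.tox_T1 < self.tox_T2 < self.tox_Tmax):
            raise ValueError("toxicity anchor values must increase and stay below tox_Tmax")
        return self

    # -- convenience ------------------------------------------------------
    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a validated copy with ``overrides`` applied."""
        data = self.model_dump()
        unknown = set(overrides) - set(data)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        data.update(overrides)
        return ParameterSet(**data)

    def to_dict(self) -> dict[str, float]:
        return self.model_dump()


class ControlEffect(BaseModel):
    """A single difference-of-exponentials therapy effect.

    ``Ampl`` is the peak proportional change of the control variable;
    ``alpha`` and ``beta`` are the onset and offset rates (per month).
    ``Ampl = 0`` disables the channel.
    """

    model_config = ConfigDict(extra="forbid")

    Ampl: float = 0.0
    alpha: float = 0.1
    beta: float = 0.009

    @model_validator(mode="after")
    def _check(self) -> "ControlEffect":
        if self.Ampl != 0.0 and not (self.alpha > self.beta > 0):
            raise ValueError(
                f"active effect requires alpha > beta > 0, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )
        return self


class TreatmentSpec(BaseModel):
    """Therapy arm: one effect curve per control channel, starting at t_thx."""

    model_config = ConfigDict(extra="forbid")

    name: str = "none"
    t_thx: float = 600.0               # therapy start [mo] (default: age 50)
    effects: dict[str, ControlEffect] = Field(default_factory=dict)
    application_strategy: str = "multiplicative"

    @model_validator(mode="after")
    def _check(self) -> "TreatmentSpec":
        unknown = set(self.effects) - set(CONTROL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown control channel(s): {sorted(unknown)}")
        if self.application_strategy not in ("multiplicative", "saturating"):
            raise ValueError(f"unknown strategy {self.application_strategy!r}")
        for ch in CONTROL_CHANNELS:
            self.effects.setdefault(ch, ControlEffect())
        return self


# Table of the four study arms: (channel -> (Ampl, alpha, beta)).
_BUILTIN_ARMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "none": {
        "k_XGI": (0.0, 0.1, 0.009),
        "lam_GI": (0.0, 0.3, 0.01),
        "k_JS": (0.0, 0.05, 0.002),
    },
    "placebo": {
        "k_XGI": (2.3, 0.03, 0.012),
        "lam_GI": (0.2, 0.3, 0.025),
        "k_JS": (0.05, 0.05, 0.002),
    },
    "lifestyle": {
        "k_XGI": (4.2, 0.1, 0.009),
        "lam_GI": (1.2, 0.5, 0.03),
        "k_JS": (-0.05, 0.05, 0.002),
    },
    "metformin": {
        "k_XGI": (2.3, 0.03, 0.012),
        "lam_GI": (1.2, 0.3, 0.022),
        "k_JS": (0.1, 0.05, 0.002),
    },
}


def builtin_treatment(name: str, t_thx: float = 600.0) -> TreatmentSpec:
    """Return one of the four built-in study arms.

    No arm carries an effect on insulin secretory ability (``k_IB``) or on
    the replication-reserve channel (``eta``): the study treatments were
    assumed to act only on insulin sensitivities and gastric emptying.
    """
    key = name.strip().lower()
    if key not in _BUILTIN_ARMS:
        raise KeyError(
            f"unknown treatment {name!r}; available: {sorted(_BUILTIN_ARMS)}"
        )
    effects = {
        ch: ControlEffect(Ampl=a, alpha=al, beta=be)
        for ch, (a, al, be) in _BUILTIN_ARMS[key].items()
    }
    return TreatmentSpec(name=key, t_thx=t_thx, effects=effects)


class ScenarioConfig(BaseModel):
    """Life-course scenario: what to simulate and what to record."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    overrides: dict[str, float] = Field(default_factory=dict)
    treatment: str | TreatmentSpec = "none"
    horizon: float = 1080.0            # slow months to simulate
    t_thx: float = 600.0               # therapy start [mo]
    ogtt_at: list[float] = Field(default_factory=list)   # slow times [mo]
    clamp_at: list[float] = Field(default_factory=list)
    seed: int | None = None            # fixture noise only
    output_dir: Path | None = None


def validate_scenario(
    config: ScenarioConfig | None, params: ParameterSet
) -> tuple[ScenarioConfig, TreatmentSpec]:
    """Normalize a scenario against a parameter set.

    Fills defaults, sorts recording grids, resolves the treatment name into a
    :class:`TreatmentSpec` with the configured ``t_thx``.
    """
    config = config or ScenarioConfig()
    if config.horizon <= 0:
        raise ValueError(f"horizon must be positive, got {config.horizon}")
    if config.horizon > params.t_end - params.t0:
        raise ValueError(
            f"horizon {config.horizon} mo exceeds the parameterized lifespan "
            f"t_end - t0 = {params.t_end - params.t0} mo"
        )
    for grid_name in ("ogtt_at", "clamp_at"):
        grid = sorted(getattr(config, grid_name))
        for t in grid:
            if not (params.t0 <= t <= params.t0 + config.horizon):
                raise ValueError(
                    f"{grid_name} time {t} mo outside simulated horizon "
                    f"[{params.t0}, {params.t0 + config.horizon}]"
                )
        setattr(config, grid_name, grid)
    if isinstance(config.treatment, TreatmentSpec):
        spec = config.treatment
    else:
        spec = builtin_treatment(config.treatment, t_thx=config.t_thx)
    return config, spec


def load_parameters(source: Mapping[str, Any] | str | Path | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    Parameters
    ----------
    source
        ``None`` for the defaults, a mapping of overrides, or a path to a
        YAML/JSON document with overrides.  Unknown keys are rejected.
    """
    if source is None:
        return ParameterSet()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        doc = yaml.safe_load(text) if not str(source).endswith(".json") else json.loads(text)
        if doc is None:
            doc = {}
        if not isinstance(doc, Mapping):
            raise ValueError(f"parameter document {source} must be a mapping")
        source = doc
    base = ParameterSet()
    for key, value in source.items():
        logger.info("parameter override: %s = %s", key, value)
    return base.replace(**dict(source))


def dump_defaults(stream=None) -> str:
    """Render the default parameter set as YAML with units as comments."""
    lines = []
    for name, value in ParameterSet().model_dump().items():
        unit = UNITS.get(name, "")
        comment = f"  # [{unit}]" if unit else ""
        lines.append(f"{name}: {value!r}{comment}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
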