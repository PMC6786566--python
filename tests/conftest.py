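"""Shared fixtures.

The expensive session fixtures (the untreated base life course and the
four one-year treatment branches from enrollment) are built lazily on first
use and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import t2dsim as t
from t2dsim.params import builtin_treatment


@pytest.fixture(scope="session")
def params() -> t.ParameterSet:
    return t.load_parameters()


@pytest.fixture(scope="session")
def grid(params):
    return t.build_grid(params)


@pytest.fixture(scope="session")
def baseline_state(params) -> t.SlowState:
    state = t.SlowState.initial(params)
    state.controls = t.natural_controls(state.t, params)
    return state


@pytest.fixture(scope="session")
def base_course(params):
    """Untreated life course from birth to 5 years past enrollment.

    OGTTs are recorded at enrollment (600 mo) and at 612 mo so that
    endpoint extraction and arm contrasts can reuse this single long run.
    """
    config = t.ScenarioConfig(
        treatment="none", horizon=660.0, t_thx=600.0, ogtt_at=[600.0, 612.0]
    )
    return t.run_scenario(config, params=params)


@pytest.fixture(scope="session")
def arm_branches(params, base_course):
    """One-year continuation of every treatment arm from the common 600-mo state.

    Before therapy start all arms coincide with the untreated course, so
    branching from its 600-month state is exact and avoids re-simulating
    the first 50 years four times.
    """
    start = base_course.state_at(600.0)
    branches = {}
    for arm in ("none", "placebo", "lifestyle", "metformin"):
        state = t.SlowState(
            t=start.t, B=start.B, eta=start.eta, G_f=start.G_f, A=start.A
        )
        config = t.ScenarioConfig(
            treatment=arm, horizon=612.0, t_thx=600.0, ogtt_at=[612.0]
        )
        branches[arm] = t.run_scenario(config, params=params, initial_state=state)
    return branches


@pytest.fixture(scope="session")
def enrollment_state(base_course) -> t.SlowState:
    return base_course.state_at(600.0)


@pytest.fixture(scope="session")
def baseline_day(params, grid, baseline_state):
    """One simulated day at the untreated baseline state."""
    inputs = t.fasting_inputs(
        baseline_state.B, baseline_state.G_f, baseline_state.controls, params,
        grid=grid,
    )
    return t.simulate_day(inputs, params, grid=grid)


def fasting_equilibrium_glycemia(params, grid, controls, B, lo=2.0, hi=8.0):
    """Glycemia at which the fasted fast model is stationary (root of dG).

    Insulin, glucagon and the tubule are at their G-conditional steady
    states; used to construct exact-equilibrium tests.
    """
    from scipy.optimize import brentq

    from t2dsim.daily import glucagon_steady, glucose_rhs
    from t2dsim.nephron import steady_state, urine_rate
    from t2dsim.slow import fasting_insulin

    def dG(G):
        I = fasting_insulin(B, G, params, k_XI=controls["k_XI"], k_IBmax=controls["k_IB"])
        L = glucagon_steady(G, params)
        ur = urine_rate(steady_state(G, grid), params)
        return glucose_rhs(G, I, L, 0.0, ur, params,
                           k_XGImax=controls["k_XGI"], lam_GI=controls["lam_GI"])

    return brentq(dG, lo, hi, xtol=1e-12)


@pytest.fixture(scope="session")
def equilibrium_glycemia(params, grid, baseline_state):
    return fasting_equilibrium_glycemia(
        params, grid, baseline_state.controls, baseline_state.B
    )
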