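import numpy as np
import pytest

from p2y12sim.config import load_parameters
from p2y12sim.dosing import DoseEvent, Drug, Regimen, TimeGrid
from p2y12sim.runner import run_regimen


@pytest.fixture(scope="session")
def params():
    """The shipped calibrated parameter bundle."""
    return load_parameters()


@pytest.fixture(scope="session")
def grid72():
    return TimeGrid(0.0, 72.0, 0.1)


@pytest.fixture(scope="session")
def simulate(params, grid72):
    """Run a regimen given as (drug, time_h, amount_mg) triples.

    Results are cached per regimen across the session; the closed-form PK
    fast path is used (it agrees with the ODE route to solver tolerance,
    which is itself under test in the PK suite).
    """
    cache = {}

    def _run(*doses, grid=None, fast=True):
        key = (doses, None if grid is None else (grid.start_h, grid.end_h, grid.step_h), fast)
        if key not in cache:
            regimen = Regimen(
                tuple(DoseEvent(Drug(d), float(t), float(a)) for d, t, a in doses)
            )
            cache[key] = run_regimen(regimen, params, grid or grid72, fast=fast)
        return cache[key]

    return _run


@pytest.fixture(scope="session")
def placebo_dose():
    return ("placebo", 0.0, 0.0)


@pytest.fixture(scope="session")
def sel_dose():
    return ("selatogrel", 0.0, 16.0)
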