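"""Calibration constraints, determinism, pseudo-observations, recovery."""

import numpy as np
import pytest

from p2y12sim.config import default_parameters_path, load_parameters
from p2y12sim.dosing import DoseEvent, Drug, Regimen, TimeGrid
from p2y12sim.reference import (
    calibrate,
    CalibrationConstraint,
    constraint_set,
    evaluate_constraints,
    generate_pseudo_observations,
    initial_guess,
    recover_binding_parameters,
)
from p2y12sim.runner import run_regimen


def test_constraint_set_contents():
    cs = constraint_set()
    assert len(cs) >= 12
    by_label = {c.label: c for c in cs}
    assert by_label["selatogrel_max_ipa"].target >= 85.0
    assert by_label["clopidogrel_metabolite_half_life"].target == 0.5
    assert all(c.source for c in cs)
    # interval/bound constraints are hard unless explicitly softened
    hard = [c for c in cs if c.kind != "point" and not c.soft]
    assert len(hard) >= 8


def test_shipped_parameters_satisfy_hard_constraints(params):
    report = evaluate_constraints(constraint_set(), params)
    violated = [k for k, r in report.items() if r["hard"] and not r["ok"]]
    assert violated == []


def test_calibration_reproduces_shipped_file():
    """Re-running the calibrator with the shipped seed and budget must
    reproduce the shipped parameter file bit-for-bit, and the best-so-far
    objective trace must be monotone non-increasing."""
    shipped = load_parameters()
    prov = shipped.provenance
    result = calibrate(
        seed=prov["calibration_seed"],
        n_starts=prov["n_starts"],
        maxfev=prov["maxfev"],
    )
    assert result.params.canonical_yaml() == default_parameters_path().read_text()
    trace = np.asarray(result.objective_trace)
    assert np.all(np.diff(trace) <= 0.0)
    assert result.hard_violations == []


def test_calibration_fails_loudly_on_impossible_constraint():
    impossible = constraint_set() + [
        CalibrationConstraint(
            label="impossible_ceiling",
            statistic="max_ipa",
            regimen=(("selatogrel", 0.0, 16.0),),
            horizon_h=24.0,
            target=200.0,
            kind="ge",
        )
    ]
    with pytest.raises(RuntimeError, match="impossible_ceiling"):
        calibrate(
            constraints=impossible, seed=1, n_starts=1, maxfev=2, start=initial_guess()
        )


@pytest.fixture(scope="module")
def sel_trajectory(params):
    grid = TimeGrid(0.0, 24.0, 0.1)
    reg = Regimen((DoseEvent(Drug.SELATOGREL, 0.0, 16.0),))
    return reg, grid, run_regimen(reg, params, grid, fast=True)


def test_pseudo_observations_noiseless_exact(sel_trajectory, params):
    _, _, res = sel_trajectory
    times = [1.0, 6.0, 12.0, 23.0]
    obs = generate_pseudo_observations(res, times, noise_sd=0.0, seed=7, pdlink=params.pdlink)
    for (t, pru, ipa) in obs:
        assert pru == pytest.approx(np.interp(t, res.times, res.pru), abs=1e-9)
        assert ipa == pytest.approx(np.interp(t, res.times, res.ipa), abs=1e-6)


def test_pseudo_observations_truncated_and_reproducible(sel_trajectory):
    _, _, res = sel_trajectory
    times = np.linspace(0.0, 24.0, 49)
    a = generate_pseudo_observations(res, times, noise_sd=500.0, seed=11)
    b = generate_pseudo_observations(res, times, noise_sd=500.0, seed=11)
    assert a == b
    pru = np.array([o[1] for o in a])
    assert np.all(pru >= 0.0) and np.all(pru <= 200.0)
    with pytest.raises(ValueError, match="span"):
        generate_pseudo_observations(res, [30.0], 1.0, seed=1)
    with pytest.raises(ValueError, match="noise_sd"):
        generate_pseudo_observations(res, [1.0], -1.0, seed=1)


def test_pseudo_observation_mean_unbiased(sel_trajectory):
    """Replicate noisy samples at a mid-range time: the mean PRU sits
    within 3 standard errors of the noiseless value (away from the
    truncation bounds)."""
    _, _, res = sel_trajectory
    t0, sd, n = 12.0, 10.0, 1000
    truth = float(np.interp(t0, res.times, res.pru))
    draws = [
        generate_pseudo_observations(res, [t0], noise_sd=sd, seed=s)[0][1]
        for s in range(n)
    ]
    se = sd / np.sqrt(n)
    assert abs(np.mean(draws) - truth) < 3.0 * se


def test_binding_parameter_recovery_within_1pct(params):
    """Noiseless pseudo-observations of a calibrated trajectory identify
    the generating binding parameters."""
    grid = TimeGrid(0.0, 36.0, 0.1)
    reg = Regimen(
        (
            DoseEvent(Drug.SELATOGREL, 0.0, 16.0),
            DoseEvent(Drug.CLOPIDOGREL, 12.0, 600.0),
        )
    )
    res = run_regimen(reg, params, grid, fast=True)
    times = np.arange(0.5, 36.0, 1.5)
    obs = generate_pseudo_observations(res, times, noise_sd=0.0, seed=3)
    keys = (("selatogrel", "binding", "k_on"), ("clopidogrel", "binding", "k_on"))
    fitted = recover_binding_parameters(obs, params, reg, grid, keys=keys)
    truth = {
        keys[0]: params.binding[Drug.SELATOGREL].k_on,
        keys[1]: params.binding[Drug.CLOPIDOGREL].k_on,
    }
    for k in keys:
        assert abs(fitted[k] - truth[k]) / truth[k] < 0.01
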