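"""Pharmacokinetics: ODE solutions against closed forms and linearity."""

import numpy as np
import pytest

from p2y12sim.dosing import DoseEvent, Drug, Regimen, TimeGrid
from p2y12sim.pk import (
    ConcentrationProfile,
    DrugPK,
    PKParameterSet,
    analytic_profile,
    bateman_concentration,
    simulate_pk,
    superpose,
    two_compartment_sc_concentration,
)

GRID = TimeGrid(0.0, 24.0, 0.1)


def rel_err(a, b):
    denom = max(np.max(np.abs(b)), 1e-30)
    return np.max(np.abs(a - b)) / denom


def test_empty_regimen_gives_zero_profiles(params):
    profiles = simulate_pk(Regimen(()), params.pk, GRID)
    assert profiles == {}
    placebo = simulate_pk(
        Regimen((DoseEvent(Drug.PLACEBO, 0.0, 0.0),)), params.pk, GRID
    )
    assert np.all(placebo[Drug.PLACEBO].values == 0.0)


def test_one_compartment_matches_bateman_closed_form():
    """Single oral dose, no lag: ODE equals the analytic Bateman solution."""
    pk = PKParameterSet(
        {Drug.TICAGRELOR: DrugPK(model="one_compartment_oral", ka=1.3, lag_h=0.0, V_c=2.0, CL=0.4)}
    )
    reg = Regimen((DoseEvent(Drug.TICAGRELOR, 0.0, 90.0),))
    prof = simulate_pk(reg, pk, GRID)[Drug.TICAGRELOR]
    expected = bateman_concentration(GRID.times, 90.0, 1.3, 0.4 / 2.0, volume=2.0)
    assert rel_err(prof.values, expected) < 1e-6


def test_metabolite_matches_scaled_bateman_with_lag():
    pk = PKParameterSet(
        {Drug.CLOPIDOGREL: DrugPK(model="prodrug_metabolite", ka=0.9, lag_h=0.5, f_m=0.3, k_me=1.4)}
    )
    reg = Regimen((DoseEvent(Drug.CLOPIDOGREL, 4.0, 600.0),))
    prof = simulate_pk(reg, pk, GRID)[Drug.CLOPIDOGREL]
    expected = bateman_concentration(GRID.times - 4.5, 600.0, 0.9, 1.4, scale=0.3)
    assert rel_err(prof.values, expected) < 1e-6
    assert np.all(prof.values[GRID.times <= 4.0] == 0.0)


def test_two_compartment_matches_closed_form(params):
    pk = params.pk[Drug.SELATOGREL]
    reg = Regimen((DoseEvent(Drug.SELATOGREL, 0.0, 16.0),))
    prof = simulate_pk(reg, params.pk, GRID)[Drug.SELATOGREL]
    expected = two_compartment_sc_concentration(GRID.times, 16.0, pk)
    assert rel_err(prof.values, expected) < 1e-6


def test_selatogrel_tmax_within_published_window(params):
    """Calibrated 16 mg s.c. peaks between 0.5 and 0.75 h."""
    fine = np.arange(0.0, 3.0, 0.001)
    conc = two_compartment_sc_concentration(fine, 16.0, params.pk[Drug.SELATOGREL])
    tmax = fine[np.argmax(conc)]
    assert 0.5 <= tmax <= 0.75


def test_dose_proportionality(params):
    reg = Regimen(
        (
            DoseEvent(Drug.CLOPIDOGREL, 2.0, 300.0),
            DoseEvent(Drug.CLOPIDOGREL, 10.0, 75.0),
        )
    )
    p1 = simulate_pk(reg, params.pk, GRID)[Drug.CLOPIDOGREL]
    p3 = simulate_pk(reg.scaled(3.0), params.pk, GRID)[Drug.CLOPIDOGREL]
    assert rel_err(p3.values, 3.0 * p1.values) < 1e-6


def test_time_shift_equivariance(params):
    """Shifting every dose by a grid multiple shifts the profile exactly."""
    reg = Regimen((DoseEvent(Drug.PRASUGREL, 1.0, 60.0),))
    base = simulate_pk(reg, params.pk, GRID)[Drug.PRASUGREL]
    shifted = simulate_pk(reg.shifted(5.0), params.pk, GRID)[Drug.PRASUGREL]
    k = round(5.0 / GRID.step_h)
    assert rel_err(shifted.values[k:], base.values[:-k]) < 1e-9


def test_superposition_of_shifted_single_doses(params):
    """Two-dose profile equals the sum of shifted single-dose profiles."""
    two = Regimen(
        (DoseEvent(Drug.TICAGRELOR, 0.0, 90.0), DoseEvent(Drug.TICAGRELOR, 12.0, 90.0))
    )
    grid = TimeGrid(0.0, 24.0, 0.1)
    p_two = simulate_pk(two, params.pk, grid)[Drug.TICAGRELOR]
    p_a = simulate_pk(
        Regimen((DoseEvent(Drug.TICAGRELOR, 0.0, 90.0),)), params.pk, grid
    )[Drug.TICAGRELOR]
    p_b = simulate_pk(
        Regimen((DoseEvent(Drug.TICAGRELOR, 12.0, 90.0),)), params.pk, grid
    )[Drug.TICAGRELOR]
    assert rel_err(superpose(p_a, p_b).values, p_two.values) < 1e-6


def test_superpose_identity_and_grid_mismatch():
    t = np.linspace(0, 10, 101)
    a = ConcentrationProfile("x", t, np.exp(-t))
    zero = ConcentrationProfile("x", t, np.zeros_like(t))
    assert np.array_equal(superpose(a, zero).values, a.values)
    other = ConcentrationProfile("x", np.linspace(0, 10, 51), np.zeros(51))
    with pytest.raises(ValueError, match="grid"):
        superpose(a, other)


def test_analytic_profile_matches_ode_for_multidose(params):
    doses = (
        DoseEvent(Drug.CLOPIDOGREL, 4.0, 600.0),
        DoseEvent(Drug.CLOPIDOGREL, 16.0, 75.0),
    )
    ode = simulate_pk(Regimen(doses), params.pk, GRID)[Drug.CLOPIDOGREL]
    closed = analytic_profile(doses, params.pk[Drug.CLOPIDOGREL], GRID.times)
    assert rel_err(ode.values, closed) < 1e-6


def test_errors_for_bad_inputs(params):
    with pytest.raises(ValueError, match="outside the simulation grid"):
        simulate_pk(
            Regimen((DoseEvent(Drug.TICAGRELOR, 100.0, 90.0),)), params.pk, GRID
        )
    no_tica = PKParameterSet(
        {Drug.SELATOGREL: params.pk[Drug.SELATOGREL]}
    )
    with pytest.raises(ValueError, match="no PK parameters"):
        simulate_pk(Regimen((DoseEvent(Drug.TICAGRELOR, 0.0, 90.0),)), no_tica, GRID)


def test_profiles_nonnegative_everywhere(params):
    reg = Regimen(
        (
            DoseEvent(Drug.SELATOGREL, 0.0, 16.0),
            DoseEvent(Drug.CLOPIDOGREL, 4.0, 600.0),
            DoseEvent(Drug.TICAGRELOR, 16.0, 180.0),
        )
    )
    for prof in simulate_pk(reg, params.pk, GRID).values():
        assert np.all(prof.values >= 0.0)


def test_dose_event_validation():
    with pytest.raises(ValueError, match="placebo"):
        DoseEvent(Drug.CLOPIDOGREL, 0.0, 0.0)
    with pytest.raises(ValueError, match="placebo"):
        DoseEvent(Drug.PLACEBO, 0.0, 10.0)
    with pytest.raises(ValueError, match="route"):
        DoseEvent(Drug.SELATOGREL, 0.0, 16.0, route="oral")
    with pytest.raises(ValueError, match="non-negative"):
        DoseEvent(Drug.TICAGRELOR, -1.0, 90.0)
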