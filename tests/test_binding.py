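"""Receptor-pool dynamics: baseline, turnover, equilibria, interactions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from p2y12sim.binding import (
    BindingParameterSet,
    DrugBinding,
    ReceptorState,
    SystemParameters,
    receptor_rhs,
    simulate_occupancy,
)
from p2y12sim.dosing import DoseEvent, Drug, Regimen, TimeGrid
from p2y12sim.pk import ConcentrationProfile


def test_baseline_is_a_fixed_point(params):
    state = ReceptorState(R_free=1.0)
    deriv = receptor_rhs(state, 0.0, {}, params.binding, params.system)
    assert np.all(deriv == 0.0)


def test_placebo_regimen_stays_at_baseline(simulate, placebo_dose):
    res = simulate(placebo_dose)
    assert np.all(np.abs(res.receptor.active_fraction - 1.0) < 1e-6)
    assert np.all(np.abs(res.ipa) < 1e-4)


def test_turnover_recovery_half_time(params):
    """After a knockdown to R0/2 with no drug, the deficit halves in ln2/k_out."""
    sp = params.system
    sol = solve_ivp(
        lambda t, y: receptor_rhs(y, t, {}, params.binding, sp),
        (0.0, 3.0 * np.log(2.0) / sp.k_out),
        [0.5, 0.0, 0.0, 0.0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    # R(t) = 1 - 0.5 exp(-k_out t); deficit halves at ln2 / k_out
    t_half = np.log(2.0) / sp.k_out
    assert abs(sol.sol(t_half)[0] - 0.75) < 1e-6
    fine = np.linspace(0, sol.t[-1], 2000)
    expected = 1.0 - 0.5 * np.exp(-sp.k_out * fine)
    assert np.max(np.abs(sol.sol(fine)[0] - expected)) < 1e-6


def test_reversible_equilibrium_matches_mass_action(params):
    """Constant selatogrel exposure, negligible turnover: B -> C/(C + k_off/k_on)."""
    grid = TimeGrid(0.0, 10.0, 0.1)
    sel = params.binding[Drug.SELATOGREL]
    sp = SystemParameters(k_out=1e-8)
    c_const = 0.15
    profiles = {
        Drug.SELATOGREL: ConcentrationProfile(
            "selatogrel", grid.times, np.full_like(grid.times, c_const)
        )
    }
    reg = Regimen((DoseEvent(Drug.SELATOGREL, 0.0, 16.0),))
    traj = simulate_occupancy(reg, profiles, params.binding, sp, grid)
    kd = sel.k_off / sel.k_on
    expected = c_const / (c_const + kd)
    assert abs(traj.B_sel[-1] - expected) < 1e-5


def test_negative_concentration_rejected(params):
    with pytest.raises(ValueError, match="negative concentration"):
        receptor_rhs(
            ReceptorState(R_free=1.0),
            0.0,
            {Drug.SELATOGREL: -0.1},
            params.binding,
            params.system,
        )


def test_states_bounded_and_pool_conserved(simulate, sel_dose):
    """Heavy multi-drug scenario keeps all states in [0, 1] and the
    orthosteric pool (free + bound) at its baseline total."""
    res = simulate(
        sel_dose,
        ("clopidogrel", 4.0, 600.0),
        ("ticagrelor", 16.0, 180.0),
        ("prasugrel", 40.0, 60.0),
    )
    r = res.receptor
    for arr in (r.R_free, r.B_sel, r.B_irr_clo, r.B_irr_pra, r.theta_tica):
        assert np.all(arr >= -1e-6) and np.all(arr <= 1.0 + 1e-6)
    total = r.R_free + r.B_sel + r.B_irr_clo + r.B_irr_pra
    assert np.max(np.abs(total - 1.0)) < 1e-6


def test_monotone_dose_response(simulate, placebo_dose):
    low = simulate(placebo_dose, ("clopidogrel", 0.0, 300.0))
    high = simulate(placebo_dose, ("clopidogrel", 0.0, 600.0))
    assert np.all(high.ipa >= low.ipa - 1e-9)
    assert high.ipa.max() > low.ipa.max()


def test_ticagrelor_term_unaffected_by_selatogrel(simulate, sel_dose):
    """The allosteric occupancy is identical with and without selatogrel
    pretreatment (no pharmacodynamic interaction, by construction)."""
    alone = simulate(("ticagrelor", 4.0, 90.0), ("ticagrelor", 16.0, 90.0))
    with_sel = simulate(
        sel_dose, ("ticagrelor", 4.0, 90.0), ("ticagrelor", 16.0, 90.0)
    )
    assert np.array_equal(alone.receptor.theta_tica, with_sel.receptor.theta_tica)


def test_selatogrel_blunts_irreversible_binding(simulate, sel_dose, placebo_dose):
    """Competition: receptors occupied by selatogrel escape the short-lived
    clopidogrel metabolite, so the irreversible pool at 24 h is strictly
    smaller than after placebo."""
    for t_load in (4.0, 12.0):
        sel = simulate(sel_dose, ("clopidogrel", t_load, 600.0))
        pla = simulate(placebo_dose, ("clopidogrel", t_load, 600.0))
        i24 = np.searchsorted(sel.times, 24.0)
        assert sel.receptor.B_irr_clo[i24] < pla.receptor.B_irr_clo[i24]


def test_binding_parameter_validation():
    with pytest.raises(ValueError, match="k_off == 0"):
        DrugBinding(mode="competitive_irreversible", k_on=0.1, k_off=0.2)
    with pytest.raises(ValueError, match="k_on > 0"):
        DrugBinding(mode="competitive_reversible", k_on=0.0, k_off=1.0)
    with pytest.raises(ValueError, match="K_T"):
        DrugBinding(mode="noncompetitive_reversible", K_T=0.0)
    with pytest.raises(ValueError, match="R0"):
        SystemParameters(k_out=0.004, R0=2.0)
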