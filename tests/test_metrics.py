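"""Trajectory metrics against analytic and dense-grid brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p2y12sim.metrics import (
    IpaTrajectory,
    first_time_above,
    interval_metrics,
    min_ipa_in_window,
    time_above_threshold,
)


def brute_force_time_above(traj, start, end, threshold, dt=0.001):
    """Independent oracle: count dense samples of the linear interpolant."""
    t = np.arange(start, end, dt) + dt / 2.0
    y = np.interp(t, traj.times, traj.ipa)
    return float(np.sum(y > threshold) * dt)


def _const(value, hours=12.0):
    t = np.linspace(0.0, hours, int(hours / 0.1) + 1)
    return IpaTrajectory(t, np.full_like(t, float(value)))


def test_constant_above_threshold():
    m = interval_metrics(_const(90.0), [(0.0, 12.0, 1)], "x", "y")[0]
    assert m.max_ipa == 90.0
    assert m.hours_above == pytest.approx(12.0, abs=1e-9)
    assert m.pct_above == pytest.approx(100.0, abs=1e-9)


def test_constant_below_threshold():
    m = interval_metrics(_const(50.0, 24.0), [(0.0, 24.0, 1)])[0]
    assert m.max_ipa == 50.0
    assert m.hours_above == 0.0
    assert m.pct_above == 0.0


def test_triangular_crossings_analytic():
    """60 -> 100 -> 60 over 12 h: crossings of 80 at t = 3 and t = 9."""
    t = np.linspace(0.0, 12.0, 121)
    y = np.where(t <= 6.0, 60.0 + 40.0 * t / 6.0, 100.0 - 40.0 * (t - 6.0) / 6.0)
    traj = IpaTrajectory(t, y)
    hours = time_above_threshold(traj, 0.0, 12.0, 80.0)
    assert hours == pytest.approx(6.0, abs=1e-9)
    assert abs(hours - brute_force_time_above(traj, 0.0, 12.0, 80.0)) < 0.05


def test_partial_window_cuts_segments():
    t = np.linspace(0.0, 12.0, 121)
    y = np.where(t <= 6.0, 60.0 + 40.0 * t / 6.0, 100.0 - 40.0 * (t - 6.0) / 6.0)
    traj = IpaTrajectory(t, y)
    # window (4, 9.5]: above 80 on (4, 9) entirely except the first segment
    assert time_above_threshold(traj, 4.0, 9.5, 80.0) == pytest.approx(5.0, abs=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=40),
    st.floats(min_value=5.0, max_value=95.0),
)
def test_time_above_matches_brute_force(values, threshold):
    """Randomised piecewise-linear trajectories: interpolated crossing
    integration agrees with a 0.001 h dense-grid count."""
    t = np.linspace(0.0, 2.0 * (len(values) - 1), len(values))
    traj = IpaTrajectory(t, np.array(values))
    ours = time_above_threshold(traj, t[0], t[-1], threshold)
    brute = brute_force_time_above(traj, t[0], t[-1], threshold)
    assert abs(ours - brute) < 0.05


def test_grid_convergence():
    """Metrics on the 0.1 h grid and a 10x finer grid agree within 0.05 h."""
    for step in (0.1,):
        t_coarse = np.arange(0.0, 24.0 + step / 2, step)
        t_fine = np.arange(0.0, 24.0 + 0.005, 0.01)
        f = lambda t: 50.0 + 45.0 * np.sin(2.0 * np.pi * t / 14.0)
        coarse = time_above_threshold(IpaTrajectory(t_coarse, f(t_coarse)), 0, 24, 80.0)
        fine = time_above_threshold(IpaTrajectory(t_fine, f(t_fine)), 0, 24, 80.0)
        assert abs(coarse - fine) < 0.05


def test_pct_above_shift_invariant():
    t = np.linspace(0.0, 12.0, 121)
    y = np.where(t <= 6.0, 60.0 + 40.0 * t / 6.0, 100.0 - 40.0 * (t - 6.0) / 6.0)
    m0 = interval_metrics(IpaTrajectory(t, y), [(0.0, 12.0, 1)])[0]
    m8 = interval_metrics(IpaTrajectory(t + 8.0, y), [(8.0, 20.0, 1)])[0]
    assert m0.pct_above == pytest.approx(m8.pct_above, abs=1e-9)


def test_min_in_window():
    traj = _const(42.0)
    assert min_ipa_in_window(traj, (2.0, 9.0)) == 42.0
    with pytest.raises(ValueError, match="empty"):
        min_ipa_in_window(traj, (9.0, 2.0))
    with pytest.raises(ValueError, match="span"):
        min_ipa_in_window(traj, (2.0, 99.0))


def test_first_time_above():
    t = np.linspace(0.0, 10.0, 101)
    assert first_time_above(IpaTrajectory(t, np.zeros_like(t)), 80.0) is None
    # linear ramp 0 -> 100 over 10 h crosses 80 at exactly 8 h
    ramp = IpaTrajectory(t, 10.0 * t)
    assert first_time_above(ramp, 80.0) == pytest.approx(8.0, abs=1e-9)
    # crossing strictly between grid points
    ramp2 = IpaTrajectory(t, 10.03 * t)
    assert first_time_above(ramp2, 80.0) == pytest.approx(80.0 / 10.03, abs=1e-9)
    with pytest.raises(ValueError, match="threshold"):
        first_time_above(ramp, 0.0)


def test_interval_outside_span_rejected():
    with pytest.raises(ValueError, match="span"):
        interval_metrics(_const(90.0), [(0.0, 120.0, 1)])
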