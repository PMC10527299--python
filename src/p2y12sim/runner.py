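"""End-to-end orchestration: regimen -> PK -> occupancy -> IPA/PRU.

Composes :func:`p2y12sim.pk.simulate_pk`,
:func:`p2y12sim.binding.simulate_occupancy` and the PD links into a
:class:`SimulationResult`, and derives the maintenance-period summary
table and the 18-24 h "gap" report. All outputs embed the parameter-file
hash so results are traceable to the exact configuration that produced
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import ReceptorTrajectory, simulate_occupancy
from .config import ModelParameters, load_parameters
from .dosing import DoseEvent, Drug, Regimen, TimeGrid
from .metrics import (
    IntervalMetrics,
    IpaTrajectory,
    interval_metrics,
    min_ipa_in_window,
)
from .pdlink import ipa_from_active_fraction, pru_from_active_fraction
from .pk import ConcentrationProfile, analytic_profile, simulate_pk
from .scenarios import (
    ARMS,
    SCENARIO_IDS,
    Scenario,
    build_scenario,
    dosing_intervals,
)

__all__ = [
    "SimulationResult",
    "run_regimen",
    "run_scenario",
    "table2",
    "gap_report",
    "headline_predictions",
]

#: the transient-dip assessment window (h)
GAP_WINDOW = (18.0, 24.0)
GAP_SCENARIOS = ("2A", "2B", "4A", "4B")


@dataclass(frozen=True)
class SimulationResult:
    """Dense 0.1 h-grid trajectories for one simulated regimen."""

    scenario_id: str
    arm: str
    grid: TimeGrid
    profiles: dict[Drug, ConcentrationProfile]
    receptor: ReceptorTrajectory
    ipa: np.ndarray
    pru: np.ndarray
    params_hash: str
    version: str = __version__

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    @property
    def ipa_trajectory(self) -> IpaTrajectory:
        return IpaTrajectory(self.times, self.ipa)

    def to_frame(self) -> pd.DataFrame:
        df = self.receptor.to_frame()
        for drug, prof in self.profiles.items():
            if drug is not Drug.PLACEBO:
                df[f"conc_{prof.species}"] = prof.values
        df["IPA"] = self.ipa
        df["PRU"] = self.pru
        df.attrs["params_hash"] = self.params_hash
        return df

    def save_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = (
            f"# p2y12sim {self.version} scenario={self.scenario_id or '-'} "
            f"arm={self.arm or '-'} params_sha256={self.params_hash}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")


def run_regimen(
    regimen: Regimen,
    params: ModelParameters,
    grid: TimeGrid,
    scenario_id: str = "",
    arm: str = "",
    fast: bool = False,
) -> SimulationResult:
    """Simulate an arbitrary regimen.

    ``fast=True`` replaces the ODE pharmacokinetics with the equivalent
    closed-form superposition profiles (the two agree to solver
    tolerance); the receptor pool is always integrated numerically.
    """
    if fast:
        profiles = {
            drug: ConcentrationProfile(
                species=drug.value,
                times=grid.times,
                values=analytic_profile(regimen.for_drug(drug), params.pk[drug], grid.times),
            )
            for drug in regimen.drugs()
            if drug in params.pk
        }
    else:
        profiles = simulate_pk(regimen, params.pk, grid)
    receptor = simulate_occupancy(regimen, profiles, params.binding, params.system, grid)
    a = np.clip(receptor.active_fraction, 0.0, 1.0)
    ipa = ipa_from_active_fraction(a)
    pru = pru_from_active_fraction(a, params.pdlink)
    return SimulationResult(
        scenario_id=scenario_id,
        arm=arm,
        grid=grid,
        profiles=profiles,
        receptor=receptor,
        ipa=np.asarray(ipa),
        pru=np.asarray(pru),
        params_hash=params.sha256(),
    )


def run_scenario(
    scenario_id: str,
    arm: str = "selatogrel",
    params: ModelParameters | None = None,
    fast: bool = False,
) -> SimulationResult:
    """Run one registry scenario end to end."""
    params = params or load_parameters()
    sc = build_scenario(scenario_id, arm)
    try:
        return run_regimen(
            sc.regimen, params, sc.grid, scenario_id=sc.id, arm=arm, fast=fast
        )
    except Exception as exc:
        raise RuntimeError(f"scenario {scenario_id} ({arm} arm) failed: {exc}") from exc


def _treatment_label(sc: Scenario) -> str:
    parts = []
    for e in sc.events:
        if e.role.value == "initial":
            parts.append(f"{e.amount_mg:g} mg {e.drug.value} (0 h)" if e.amount_mg else "placebo (0 h)")
        elif e.role.value == "loading":
            parts.append(f"{e.amount_mg:g} mg {e.drug.value} ({e.time_h:g} h)")
    from .scenarios import TAU

    freq = "b.i.d." if TAU[sc.maintenance_drug] == 12.0 else "o.d."
    md = next(e for e in sc.events if e.role.value == "maintenance")
    parts.append(f"{md.amount_mg:g} mg {sc.maintenance_drug.value} {freq}")
    return " + ".join(parts)


def scenario_metrics(
    result: SimulationResult, scenario: Scenario
) -> list[IntervalMetrics]:
    """Per-dosing-interval metrics of one simulated scenario."""
    return interval_metrics(
        result.ipa_trajectory,
        dosing_intervals(scenario),
        scenario_id=scenario.id,
        arm=scenario.arm,
    )


def table2(
    params: ModelParameters | None = None,
    arms: tuple[str, ...] = ARMS,
    fast: bool = False,
) -> pd.DataFrame:
    """Maintenance-period summary for every scenario and arm.

    One row per dosing interval: maximum IPA, hours with IPA > 80 %, and
    the percentage of the interval above 80 %, rounded to one decimal.
    """
    params = params or load_parameters()
    rows = []
    for sid in SCENARIO_IDS:
        for arm in arms:
            sc = build_scenario(sid, arm)
            res = run_regimen(sc.regimen, params, sc.grid, sid, arm, fast=fast)
            for m in scenario_metrics(res, sc):
                rows.append(
                    {
                        "scenario": sid,
                        "arm": arm,
                        "treatment_label": _treatment_label(sc),
                        "dose_index": m.dose_index,
                        "max_ipa": round(m.max_ipa, 1),
                        "hours_above": round(m.hours_above, 1),
                        "interval_h": round(m.interval_h, 1),
                        "pct_above": round(m.pct_above, 1),
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["params_hash"] = params.sha256()
    return df


def headline_predictions(
    params: ModelParameters | None = None, fast: bool = False
) -> dict[str, dict]:
    """Recompute the study's headline quantities from scratch.

    Returns a mapping of descriptive names to ``{"value": ..., "n": ...}``
    where ``n`` is the number of grid points the quantity was derived
    from. Every value is produced by running the full simulation pipeline
    at the shipped (or given) calibrated parameter set.
    """
    params = params or load_parameters()
    grid = TimeGrid(0.0, 72.0, 0.1)
    out: dict[str, dict] = {}

    def record(name: str, value: float, n: int) -> None:
        out[name] = {"value": round(float(value), 1), "n": int(n)}

    def custom(*doses: tuple[str, float, float]) -> SimulationResult:
        reg = Regimen(
            tuple(DoseEvent(Drug(d), t, a) for d, t, a in doses)
        )
        return run_regimen(reg, params, grid, fast=fast)

    sel16 = ("selatogrel", 0.0, 16.0)
    placebo = ("placebo", 0.0, 0.0)

    # single-dose selatogrel: peak effect over the first 24 h
    res = custom(sel16)
    first24 = res.times <= 24.0
    record("selatogrel_16mg_max_ipa_0_24h", res.ipa[first24].max(), first24.sum())

    # prasugrel loading 4.5 h after selatogrel: effect remaining at 24 h
    res = custom(sel16, ("prasugrel", 4.5, 60.0))
    record("prasugrel_after_selatogrel_ipa_at_24h",
           float(np.interp(24.0, res.times, res.ipa)), len(res.times))

    # clopidogrel 600 mg loading after placebo: peak effect
    res = custom(placebo, ("clopidogrel", 4.0, 600.0))
    record("clopidogrel_600mg_after_placebo_peak_ipa", res.ipa.max(), len(res.times))

    # the 18-24 h dip when clopidogrel loading follows at 12 h
    res = custom(sel16, ("clopidogrel", 12.0, 600.0))
    record("gap_18_24h_min_ipa_selatogrel_arm",
           min_ipa_in_window(res.ipa_trajectory, GAP_WINDOW), len(res.times))
    res = custom(placebo, ("clopidogrel", 12.0, 600.0))
    record("gap_18_24h_min_ipa_placebo_arm",
           min_ipa_in_window(res.ipa_trajectory, GAP_WINDOW), len(res.times))

    # clopidogrel-only maintenance (scenario 5), first interval
    sc5 = build_scenario("5", "selatogrel")
    res5 = run_regimen(sc5.regimen, params, sc5.grid, "5", "selatogrel", fast=fast)
    m5 = interval_metrics(res5.ipa_trajectory, dosing_intervals(sc5), "5", "selatogrel")
    record("scenario5_first_maintenance_max_ipa", m5[0].max_ipa, len(res5.times))
    record("scenario5_first_maintenance_pct_above_80", m5[0].pct_above, len(res5.times))

    # prasugrel loading-dose interval of scenario 3B
    sc3b = build_scenario("3B", "selatogrel")
    res3b = run_regimen(sc3b.regimen, params, sc3b.grid, "3B", "selatogrel", fast=fast)
    m3b = interval_metrics(res3b.ipa_trajectory, dosing_intervals(sc3b), "3B", "selatogrel")
    record("scenario3B_loading_interval_max_ipa", m3b[0].max_ipa, len(res3b.times))

    # clopidogrel-only maintenance with 12 h loading (scenario 6), first interval
    sc6 = build_scenario("6", "selatogrel")
    res6 = run_regimen(sc6.regimen, params, sc6.grid, "6", "selatogrel", fast=fast)
    m6 = interval_metrics(res6.ipa_trajectory, dosing_intervals(sc6), "6", "selatogrel")
    record("scenario6_first_maintenance_max_ipa", m6[0].max_ipa, len(res6.times))

    # ticagrelor maintenance floor from 25 h across scenarios 1A/2A, both arms
    floor = math.inf
    n_pts = 0
    for sid in ("1A", "2A"):
        for arm in ARMS:
            sc = build_scenario(sid, arm)
            r = run_regimen(sc.regimen, params, sc.grid, sid, arm, fast=fast)
            floor = min(floor, min_ipa_in_window(r.ipa_trajectory, (25.0, 72.0)))
            n_pts += len(r.times)
    record("ticagrelor_maintenance_min_ipa_25_72h", floor, n_pts)
    return out


def gap_report(
    params: ModelParameters | None = None, fast: bool = False
) -> pd.DataFrame:
    """Minimum IPA in the 18-24 h window for the 12 h-loading scenarios.

    Quantifies the interval where the selatogrel arm is predicted to dip
    below the placebo arm before the first maintenance dose.
    """
    params = params or load_parameters()
    rows = []
    for sid in GAP_SCENARIOS:
        for arm in ARMS:
            sc = build_scenario(sid, arm)
            res = run_regimen(sc.regimen, params, sc.grid, sid, arm, fast=fast)
            m = min_ipa_in_window(res.ipa_trajectory, GAP_WINDOW)
            rows.append(
                {
                    "scenario": sid,
                    "arm": arm,
                    "window_start_h": GAP_WINDOW[0],
                    "window_end_h": GAP_WINDOW[1],
                    "min_ipa": round(m, 1),
                    "min_ipa_pct": int(round(m)),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["params_hash"] = params.sha256()
    return df
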