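"""Registry of the ten simulated switching scenarios.

Every scenario starts with selatogrel 16 mg s.c. (or placebo) at time 0,
followed by a clopidogrel 600 mg loading dose at 4 h or 12 h, and then
maintenance therapy with ticagrelor (90 mg b.i.d.), prasugrel (10 mg
o.d.) or clopidogrel (75 mg o.d.), with or without a ticagrelor 180 mg /
prasugrel 60 mg loading dose. Maintenance dosing is extended to the 72 h
simulation horizon; dosing intervals are half-open ``(t_dose, t_dose+tau]``
truncated at the horizon.

Scenario definitions can also be loaded from a YAML/JSON config file with
the same schema, so regimens beyond the built-in registry can be declared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import yaml

from .dosing import DoseEvent, DoseRole, Drug, Regimen, TimeGrid

__all__ = [
    "Scenario",
    "SCENARIO_IDS",
    "ARMS",
    "build_scenario",
    "dosing_intervals",
    "all_scenarios",
    "load_scenarios",
]

SCENARIO_IDS = ("1A", "1B", "2A", "2B", "3A", "3B", "4A", "4B", "5", "6")
ARMS = ("selatogrel", "placebo")

HORIZON_H = 72.0
GRID_STEP_H = 0.1

#: Dosing interval of each maintenance drug (h): ticagrelor b.i.d.,
#: prasugrel and clopidogrel o.d.
TAU = {Drug.TICAGRELOR: 12.0, Drug.PRASUGREL: 24.0, Drug.CLOPIDOGREL: 24.0}

# (clopidogrel LD time, maintenance drug, LD amount or None, first
#  maintenance-phase dose time, maintenance amount)
_REGISTRY: dict[str, tuple[float, Drug, float | None, float, float]] = {
    "1A": (4.0, Drug.TICAGRELOR, None, 16.0, 90.0),
    "1B": (4.0, Drug.PRASUGREL, None, 16.0, 10.0),
    "2A": (12.0, Drug.TICAGRELOR, None, 24.0, 90.0),
    "2B": (12.0, Drug.PRASUGREL, None, 24.0, 10.0),
    "3A": (4.0, Drug.TICAGRELOR, 180.0, 16.0, 90.0),
    "3B": (4.0, Drug.PRASUGREL, 60.0, 16.0, 10.0),
    "4A": (12.0, Drug.TICAGRELOR, 180.0, 24.0, 90.0),
    "4B": (12.0, Drug.PRASUGREL, 60.0, 24.0, 10.0),
    "5": (4.0, Drug.CLOPIDOGREL, None, 16.0, 75.0),
    "6": (12.0, Drug.CLOPIDOGREL, None, 24.0, 75.0),
}


@dataclass(frozen=True)
class Scenario:
    """One simulated treatment scenario (a regimen plus its grid spec)."""

    id: str
    arm: Literal["selatogrel", "placebo"]
    events: tuple[DoseEvent, ...]
    maintenance_drug: Drug
    horizon_h: float = HORIZON_H
    grid_step_h: float = GRID_STEP_H

    @property
    def regimen(self) -> Regimen:
        return Regimen(self.events)

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(0.0, self.horizon_h, self.grid_step_h)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "arm": self.arm,
            "horizon_h": self.horizon_h,
            "grid_step_h": self.grid_step_h,
            "maintenance_drug": self.maintenance_drug.value,
            "events": [
                {
                    "drug": e.drug.value,
                    "time_h": e.time_h,
                    "amount_mg": e.amount_mg,
                    "route": e.route.value,
                    "role": e.role.value,
                }
                for e in self.events
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "Scenario":
        return Scenario(
            id=str(d["id"]),
            arm=d["arm"],
            events=tuple(
                DoseEvent(
                    drug=Drug(e["drug"]),
                    time_h=float(e["time_h"]),
                    amount_mg=float(e["amount_mg"]),
                    route=e.get("route"),
                    role=e.get("role", "maintenance"),
                )
                for e in d["events"]
            ),
            maintenance_drug=Drug(d["maintenance_drug"]),
            horizon_h=float(d.get("horizon_h", HORIZON_H)),
            grid_step_h=float(d.get("grid_step_h", GRID_STEP_H)),
        )


def build_scenario(scenario_id: str, arm: str = "selatogrel") -> Scenario:
    """Construct a registry scenario; maintenance doses run to the horizon."""
    scenario_id = str(scenario_id)
    if scenario_id not in _REGISTRY:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}"
        )
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; valid arms: {', '.join(ARMS)}")
    clo_ld_time, mdrug, ld_amount, first_md_time, md_amount = _REGISTRY[scenario_id]

    events: list[DoseEvent] = []
    if arm == "selatogrel":
        events.append(DoseEvent(Drug.SELATOGREL, 0.0, 16.0, role=DoseRole.INITIAL))
    else:
        events.append(DoseEvent(Drug.PLACEBO, 0.0, 0.0, role=DoseRole.INITIAL))
    events.append(DoseEvent(Drug.CLOPIDOGREL, clo_ld_time, 600.0, role=DoseRole.LOADING))

    t = first_md_time
    if ld_amount is not None:
        events.append(DoseEvent(mdrug, t, ld_amount, role=DoseRole.LOADING))
        t += TAU[mdrug]
    while t <= HORIZON_H:
        events.append(DoseEvent(mdrug, t, md_amount, role=DoseRole.MAINTENANCE))
        t += TAU[mdrug]

    return Scenario(
        id=scenario_id, arm=arm, events=tuple(events), maintenance_drug=mdrug
    )


def dosing_intervals(scenario: Scenario) -> list[tuple[float, float, int]]:
    """Half-open dosing intervals ``(start, end, dose_index)``.

    Index 0 is the loading-dose-only interval (from the ticagrelor or
    prasugrel loading dose to the first maintenance dose) where the
    scenario has one; maintenance doses are indexed from 1. Intervals are
    truncated at the horizon and empty intervals dropped.
    """
    tau = TAU[scenario.maintenance_drug]
    # the clopidogrel 600 mg loading dose opens no scored interval; the
    # ticagrelor/prasugrel loading dose opens the index-0 "LD only" row
    doses = [
        e
        for e in scenario.events
        if e.drug == scenario.maintenance_drug
        and not (e.drug == Drug.CLOPIDOGREL and e.role == DoseRole.LOADING)
    ]
    doses.sort(key=lambda e: e.time_h)
    out: list[tuple[float, float, int]] = []
    md_index = 0
    for e in doses:
        end = min(e.time_h + tau, scenario.horizon_h)
        if end <= e.time_h:
            continue
        if e.role == DoseRole.LOADING:
            out.append((e.time_h, end, 0))
        else:
            md_index += 1
            out.append((e.time_h, end, md_index))
    return out


def all_scenarios() -> list[Scenario]:
    """The full registry: 10 scenario ids x 2 arms."""
    return [build_scenario(sid, arm) for sid in SCENARIO_IDS for arm in ARMS]


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Load scenario definitions from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, dict):
        data = data.get("scenarios", [data])
    return [Scenario.from_dict(d) for d in data]
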