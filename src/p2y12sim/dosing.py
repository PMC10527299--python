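"""Dose events, regimens, and the master simulation time grid.

Times are in hours relative to time 0 = selatogrel/placebo administration.
Amounts are in mg. A placebo administration is represented as a
:class:`DoseEvent` with ``amount_mg = 0`` so that active and placebo arms
share identical code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Drug",
    "Route",
    "DoseRole",
    "DoseEvent",
    "Regimen",
    "TimeGrid",
]


class Drug(str, Enum):
    SELATOGREL = "selatogrel"
    CLOPIDOGREL = "clopidogrel"
    PRASUGREL = "prasugrel"
    TICAGRELOR = "ticagrelor"
    PLACEBO = "placebo"


class Route(str, Enum):
    SUBCUTANEOUS = "subcutaneous"
    ORAL = "oral"


class DoseRole(str, Enum):
    INITIAL = "initial"
    LOADING = "loading"
    MAINTENANCE = "maintenance"


#: Route each drug is administered by. Selatogrel is a subcutaneous
#: injection; the oral antagonists are tablets. Placebo mirrors the
#: selatogrel injection.
DRUG_ROUTE = {
    Drug.SELATOGREL: Route.SUBCUTANEOUS,
    Drug.PLACEBO: Route.SUBCUTANEOUS,
    Drug.CLOPIDOGREL: Route.ORAL,
    Drug.PRASUGREL: Route.ORAL,
    Drug.TICAGRELOR: Route.ORAL,
}


@dataclass(frozen=True)
class DoseEvent:
    """A single drug administration.

    Invariants: ``amount_mg == 0`` iff the drug is placebo; selatogrel is
    subcutaneous and every other active drug oral.
    """

    drug: Drug
    time_h: float
    amount_mg: float
    route: Route | None = None
    role: DoseRole = DoseRole.MAINTENANCE

    def __post_init__(self) -> None:
        drug = Drug(self.drug)
        object.__setattr__(self, "drug", drug)
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise ValueError(f"dose time must be finite and non-negative, got {self.time_h}")
        if self.amount_mg < 0:
            raise ValueError(f"dose amount must be non-negative, got {self.amount_mg}")
        if (self.amount_mg == 0) != (drug is Drug.PLACEBO):
            raise ValueError("amount_mg == 0 if and only if drug is placebo")
        route = Route(self.route) if self.route is not None else DRUG_ROUTE[drug]
        if route is not DRUG_ROUTE[drug]:
            raise ValueError(f"{drug.value} must be given by the {DRUG_ROUTE[drug].value} route")
        object.__setattr__(self, "route", route)
        object.__setattr__(self, "role", DoseRole(self.role))


@dataclass(frozen=True)
class Regimen:
    """An ordered, immutable schedule of dose events."""

    events: tuple[DoseEvent, ...] = ()

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: (e.time_h, e.drug.value)))
        object.__setattr__(self, "events", events)

    def __iter__(self) -> Iterator[DoseEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def drugs(self) -> tuple[Drug, ...]:
        seen: list[Drug] = []
        for e in self.events:
            if e.drug not in seen:
                seen.append(e.drug)
        return tuple(seen)

    def for_drug(self, drug: Drug) -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events if e.drug == drug)

    def shifted(self, delta_h: float) -> "Regimen":
        """Shift every dose time by ``delta_h`` hours."""
        return Regimen(
            tuple(
                DoseEvent(e.drug, e.time_h + delta_h, e.amount_mg, e.route, e.role)
                for e in self.events
            )
        )

    def scaled(self, factor: float) -> "Regimen":
        """Scale every dose amount by ``factor`` (placebo doses stay zero)."""
        return Regimen(
            tuple(
                DoseEvent(e.drug, e.time_h, e.amount_mg * factor, e.route, e.role)
                for e in self.events
            )
        )

    @staticmethod
    def from_events(events: Iterable[DoseEvent]) -> "Regimen":
        return Regimen(tuple(events))


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation grid ``[start, start + n*step]`` in hours."""

    start_h: float = 0.0
    end_h: float = 72.0
    step_h: float = 0.1
    times: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("grid end must be after start")
        if self.step_h <= 0:
            raise ValueError("grid step must be positive")
        n = round((self.end_h - self.start_h) / self.step_h)
        if abs(self.start_h + n * self.step_h - self.end_h) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")
        object.__setattr__(
            self, "times", np.linspace(self.start_h, self.end_h, n + 1)
        )

    def __len__(self) -> int:
        return len(self.times)

    def covers(self, t: float) -> bool:
        return self.start_h - 1e-12 <= t <= self.end_h + 1e-12
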