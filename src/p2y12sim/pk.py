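"""Compartmental pharmacokinetics of the P2Y12 antagonists.

One structural model per drug, all linear (dose-proportional):

* selatogrel — subcutaneous depot feeding a two-compartment disposition
  model (central + peripheral); the parent drug is the binding species.
* clopidogrel, prasugrel — oral prodrugs with a lumped active-metabolite
  compartment: first-order formation (fraction ``f_m`` of the absorbed
  dose) from the absorption depot and first-order elimination ``k_me``.
  The active metabolite is the binding species.
* ticagrelor — one-compartment oral model; the parent is the binding
  species (the active metabolite's contribution is absorbed into the
  parent potency).

Concentrations are kept in arbitrary internal units (central volumes are
normalised); only ratios of concentration to the binding constants are
observable downstream.

:func:`simulate_pk` integrates the compartment ODEs with a stiff-capable
adaptive solver, restarting at every dose time so that absorption-depot
impulses are not smoothed over. Closed-form solutions of the same linear
systems (:func:`bateman_concentration`,
:func:`two_compartment_sc_concentration`, :func:`analytic_profile`) are
provided both as independent oracles and as a fast path for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import DoseEvent, Drug, Regimen, TimeGrid

__all__ = [
    "DrugPK",
    "PKParameterSet",
    "ConcentrationProfile",
    "simulate_pk",
    "superpose",
    "analytic_profile",
    "bateman_concentration",
    "two_compartment_sc_concentration",
]

#: ODE solver tolerances; dose times are hard restart points.
RTOL = 1e-8
ATOL = 1e-10

#: Binding species simulated for each drug.
SPECIES = {
    Drug.SELATOGREL: "selatogrel",
    Drug.CLOPIDOGREL: "clopidogrel_active_metabolite",
    Drug.PRASUGREL: "prasugrel_active_metabolite",
    Drug.TICAGRELOR: "ticagrelor",
    Drug.PLACEBO: "placebo",
}


@dataclass(frozen=True)
class DrugPK:
    """Absorption/disposition constants for one drug.

    ``model`` selects the structural model: ``two_compartment_sc``,
    ``prodrug_metabolite``, ``one_compartment_oral`` or ``none`` (placebo).
    Unused fields for a given model may be left at their defaults.
    """

    model: str
    ka: float = 1.0  # first-order absorption rate (1/h)
    lag_h: float = 0.0  # absorption lag (h)
    V_c: float = 1.0  # central volume (arbitrary units)
    CL: float = 0.0  # clearance (volume/h)
    Q: float = 0.0  # inter-compartmental clearance (volume/h)
    V_p: float = 1.0  # peripheral volume
    f_m: float = 1.0  # fraction converted to active metabolite
    k_me: float = 0.0  # active-metabolite elimination rate (1/h)

    def __post_init__(self) -> None:
        if self.model not in {
            "two_compartment_sc",
            "prodrug_metabolite",
            "one_compartment_oral",
            "none",
        }:
            raise ValueError(f"unknown PK model {self.model!r}")
        if self.model == "none":
            return
        if self.ka <= 0 or self.V_c <= 0:
            raise ValueError("absorption rate and central volume must be positive")
        if self.lag_h < 0:
            raise ValueError("absorption lag must be non-negative")
        if self.model == "two_compartment_sc" and (
            self.CL <= 0 or self.Q <= 0 or self.V_p <= 0
        ):
            raise ValueError("two-compartment model needs positive CL, Q, V_p")
        if self.model == "one_compartment_oral" and self.CL <= 0:
            raise ValueError("one-compartment model needs positive CL")
        if self.model == "prodrug_metabolite":
            if not 0 < self.f_m <= 1:
                raise ValueError("metabolite fraction f_m must be in (0, 1]")
            if self.k_me <= 0:
                raise ValueError("metabolite elimination rate must be positive")


class PKParameterSet(dict):
    """Mapping ``Drug -> DrugPK`` with a placebo entry always present."""

    def __init__(self, entries: Mapping[Drug | str, DrugPK] | None = None):
        super().__init__()
        self[Drug.PLACEBO] = DrugPK(model="none")
        if entries:
            for drug, pk in entries.items():
                self[Drug(drug)] = pk


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration of one binding species on the master time grid."""

    species: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape:
            raise ValueError("times and values must have identical shape")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation onto arbitrary times within the grid."""
        return np.interp(t, self.times, self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "species": self.species, "concentration": self.values}
        )


def superpose(
    profile_a: ConcentrationProfile, profile_b: ConcentrationProfile
) -> ConcentrationProfile:
    """Pointwise sum of two profiles on identical grids (linear PK)."""
    if profile_a.times.shape != profile_b.times.shape or not np.array_equal(
        profile_a.times, profile_b.times
    ):
        raise ValueError("profiles must share an identical time grid")
    return ConcentrationProfile(
        species=profile_a.species,
        times=profile_a.times,
        values=profile_a.values + profile_b.values,
    )


# ---------------------------------------------------------------------------
# Structural models: state-space matrices and observation rows
# ---------------------------------------------------------------------------


def _system(pk: DrugPK) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, c) with dy/dt = A @ y and concentration = c @ y.

    The first state is always the absorption depot receiving dose impulses.
    """
    if pk.model == "two_compartment_sc":
        k10 = pk.CL / pk.V_c
        k12 = pk.Q / pk.V_c
        k21 = pk.Q / pk.V_p
        A = np.array(
            [
                [-pk.ka, 0.0, 0.0],
                [pk.ka, -(k10 + k12), k21],
                [0.0, k12, -k21],
            ]
        )
        c = np.array([0.0, 1.0 / pk.V_c, 0.0])
    elif pk.model == "prodrug_metabolite":
        A = np.array([[-pk.ka, 0.0], [pk.f_m * pk.ka, -pk.k_me]])
        c = np.array([0.0, 1.0 / pk.V_c])
    elif pk.model == "one_compartment_oral":
        ke = pk.CL / pk.V_c
        A = np.array([[-pk.ka, 0.0], [pk.ka, -ke]])
        c = np.array([0.0, 1.0 / pk.V_c])
    else:  # placebo
        A = np.zeros((1, 1))
        c = np.zeros(1)
    return A, c


def _single_drug_profile(
    doses: tuple[DoseEvent, ...], pk: DrugPK, grid: TimeGrid
) -> np.ndarray:
    """Integrate one drug's compartment system over the grid."""
    times = grid.times
    out = np.zeros_like(times)
    if pk.model == "none" or not doses:
        return out
    A, c = _system(pk)
    # effective input times include the absorption lag; exact for linear
    # first-order absorption (the depot simply starts emptying later)
    inputs = sorted((d.time_h + pk.lag_h, d.amount_mg) for d in doses)
    boundaries = sorted({t for t, _ in inputs if t < times[-1]} | {times[-1]})
    y = np.zeros(A.shape[0])
    t_cur = times[0]
    dose_idx = 0
    # doses at/before grid start are injected immediately
    while dose_idx < len(inputs) and inputs[dose_idx][0] <= t_cur + 1e-12:
        y[0] += inputs[dose_idx][1]
        dose_idx += 1
    out[0] = c @ y
    for t_next in boundaries:
        if t_next <= t_cur + 1e-12:
            continue
        mask = (times > t_cur + 1e-12) & (times <= t_next + 1e-12)
        # evaluate at grid points inside the segment and at its end so the
        # state is carried across the dose-time restart
        t_eval = np.append(times[mask], t_next)
        t_eval = t_eval[np.insert(np.diff(t_eval) > 1e-12, 0, True)]
        sol = solve_ivp(
            lambda t, yy: A @ yy,
            (t_cur, t_next),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=RTOL,
            atol=ATOL,
            jac=lambda t, yy: A,
        )
        if not sol.success:
            raise RuntimeError(f"PK integration failed on [{t_cur}, {t_next}]: {sol.message}")
        out[mask] = (c @ sol.y)[: int(mask.sum())]
        y = sol.y[:, -1].copy()
        t_cur = t_next
        while dose_idx < len(inputs) and inputs[dose_idx][0] <= t_cur + 1e-12:
            y[0] += inputs[dose_idx][1]
            dose_idx += 1
    return np.maximum(out, 0.0)


def simulate_pk(
    regimen: Regimen, params: PKParameterSet, grid: TimeGrid
) -> dict[Drug, ConcentrationProfile]:
    """Concentration-time profile of the binding species of each drug.

    Raises if a dose time falls outside the grid or a dosed drug has no
    parameter entry.
    """
    for e in regimen:
        if not grid.covers(e.time_h):
            raise ValueError(
                f"dose time {e.time_h} h is outside the simulation grid "
                f"[{grid.start_h}, {grid.end_h}] h"
            )
        if e.drug not in params:
            raise ValueError(f"no PK parameters for drug {e.drug.value!r}")
    profiles: dict[Drug, ConcentrationProfile] = {}
    for drug in regimen.drugs():
        values = _single_drug_profile(regimen.for_drug(drug), params[drug], grid)
        profiles[drug] = ConcentrationProfile(SPECIES[drug], grid.times, values)
    return profiles


# ---------------------------------------------------------------------------
# Closed-form solutions (oracles and calibration fast path)
# ---------------------------------------------------------------------------


def bateman_concentration(
    t: np.ndarray | float,
    dose: float,
    ka: float,
    kel: float,
    volume: float = 1.0,
    scale: float = 1.0,
) -> np.ndarray:
    """First-order absorption into a one-compartment system.

    ``C(t) = scale * D * ka / (V (ka - kel)) * (exp(-kel t) - exp(-ka t))``
    for ``t >= 0`` and zero before. ``scale`` carries a metabolite
    conversion fraction where applicable. The ``ka == kel`` limit is
    handled by its analytic form ``scale*D*ka*t*exp(-ka t)/V``.
    """
    t = np.asarray(t, dtype=float)
    pos = t > 0
    out = np.zeros_like(t)
    tp = t[pos]
    if abs(ka - kel) < 1e-12:
        out[pos] = scale * dose * ka * tp * np.exp(-ka * tp) / volume
    else:
        out[pos] = (
            scale
            * dose
            * ka
            / (volume * (ka - kel))
            * (np.exp(-kel * tp) - np.exp(-ka * tp))
        )
    return out


def _two_compartment_exponents(pk: DrugPK) -> tuple[float, float]:
    k10 = pk.CL / pk.V_c
    k12 = pk.Q / pk.V_c
    k21 = pk.Q / pk.V_p
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(s * s - 4.0 * p)
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    return lam1, lam2


def two_compartment_sc_concentration(
    t: np.ndarray | float, dose: float, pk: DrugPK
) -> np.ndarray:
    """Closed-form central concentration after one subcutaneous dose at t=0.

    Standard triexponential solution of first-order absorption into a
    two-compartment disposition model.
    """
    t = np.asarray(t, dtype=float)
    k21 = pk.Q / pk.V_p
    lam1, lam2 = _two_compartment_exponents(pk)
    ka = pk.ka
    coef_a = (k21 - ka) / ((lam1 - ka) * (lam2 - ka))
    coef_1 = (k21 - lam1) / ((ka - lam1) * (lam2 - lam1))
    coef_2 = (k21 - lam2) / ((ka - lam2) * (lam1 - lam2))
    pos = t > 0
    out = np.zeros_like(t)
    tp = t[pos]
    out[pos] = (
        dose
        * ka
        / pk.V_c
        * (
            coef_a * np.exp(-ka * tp)
            + coef_1 * np.exp(-lam1 * tp)
            + coef_2 * np.exp(-lam2 * tp)
        )
    )
    return out


def _single_dose_closed_form(t: np.ndarray, dose: float, pk: DrugPK) -> np.ndarray:
    if pk.model == "two_compartment_sc":
        return two_compartment_sc_concentration(t, dose, pk)
    if pk.model == "prodrug_metabolite":
        return bateman_concentration(t, dose, pk.ka, pk.k_me, pk.V_c, pk.f_m)
    if pk.model == "one_compartment_oral":
        return bateman_concentration(t, dose, pk.ka, pk.CL / pk.V_c, pk.V_c)
    return np.zeros_like(np.asarray(t, dtype=float))


def analytic_profile(
    doses: tuple[DoseEvent, ...] | Regimen,
    pk: DrugPK,
    times: np.ndarray,
) -> np.ndarray:
    """Exact multi-dose profile by superposition of closed-form solutions."""
    if isinstance(doses, Regimen):
        doses = doses.events
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for d in doses:
        out += _single_dose_closed_form(times - d.time_h - pk.lag_h, d.amount_mg, pk)
    return out
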