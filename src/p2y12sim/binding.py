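"""P2Y12 receptor-pool kinetics under competing antagonists.

The free functional receptor pool turns over with first-order appearance
``k_in`` and disappearance ``k_out`` (platelet renewal); at baseline the
pool sits at ``R0 = 1`` with ``k_in = k_out * R0``. Three binding modes
act on it:

* competitive reversible (selatogrel): mass-action association to the ADP
  site with dissociation ``k_off``; bound complexes are degraded with the
  receptor pool at ``k_out``.
* competitive irreversible (the active metabolites of clopidogrel and
  prasugrel): association with ``k_off = 0``; irreversibly bound receptor
  is removed only by turnover.
* non-competitive reversible (ticagrelor): binding at a site distinct from
  the ADP site, treated as an instantaneous-equilibrium occupancy
  ``theta = C / (C + K_T)`` that multiplies the active fraction. This
  separable term reproduces, by construction, the observed absence of a
  pharmacodynamic interaction between ticagrelor and selatogrel.

The active receptor fraction available for ADP signalling is
``a = (R_free / R0) * (1 - theta)``.

With the baseline normalisation the total orthosteric pool
``R_free + B_sel + B_clo + B_pra`` is an invariant of the dynamics
(its time derivative is ``k_out * (1 - total)``, zero at 1), which keeps
every state in [0, 1] up to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import Drug, Regimen, TimeGrid
from .pk import ConcentrationProfile

__all__ = [
    "BindingMode",
    "DrugBinding",
    "BindingParameterSet",
    "SystemParameters",
    "ReceptorState",
    "ReceptorTrajectory",
    "receptor_rhs",
    "simulate_occupancy",
]

RTOL = 1e-10
ATOL = 1e-12

COMPETITIVE_REVERSIBLE = "competitive_reversible"
COMPETITIVE_IRREVERSIBLE = "competitive_irreversible"
NONCOMPETITIVE_REVERSIBLE = "noncompetitive_reversible"

BindingMode = str


@dataclass(frozen=True)
class DrugBinding:
    """Receptor-binding constants for one drug.

    ``k_on``/``k_off`` apply to the kinetic (competitive) modes; ``K_T``
    is the equilibrium constant of the non-competitive allosteric term.
    """

    mode: BindingMode
    k_on: float = 0.0  # association rate, 1/(conc*h)
    k_off: float = 0.0  # dissociation rate, 1/h (0 for irreversible)
    K_T: float = 0.0  # allosteric equilibrium constant, conc units

    def __post_init__(self) -> None:
        if self.mode == COMPETITIVE_REVERSIBLE:
            if self.k_on <= 0 or self.k_off <= 0:
                raise ValueError("reversible competitive binding needs k_on > 0, k_off > 0")
        elif self.mode == COMPETITIVE_IRREVERSIBLE:
            if self.k_on <= 0:
                raise ValueError("irreversible binding needs k_on > 0")
            if self.k_off != 0.0:
                raise ValueError("irreversible binding requires k_off == 0 exactly")
        elif self.mode == NONCOMPETITIVE_REVERSIBLE:
            if self.K_T <= 0:
                raise ValueError("non-competitive binding needs K_T > 0")
        elif self.mode != "none":
            raise ValueError(f"unknown binding mode {self.mode!r}")


class BindingParameterSet(dict):
    """Mapping ``Drug -> DrugBinding`` with a placebo entry always present."""

    def __init__(self, entries: Mapping[Drug | str, DrugBinding] | None = None):
        super().__init__()
        self[Drug.PLACEBO] = DrugBinding(mode="none")
        if entries:
            for drug, b in entries.items():
                self[Drug(drug)] = b


@dataclass(frozen=True)
class SystemParameters:
    """Receptor-pool turnover and the reference subject.

    ``k_in`` is fixed to ``k_out * R0`` so the drug-free pool is at steady
    state. The reference subject weighs 70 kg with a baseline platelet
    reactivity of 200 PRU; the weight is recorded but unused (the model
    simulates a single typical subject).
    """

    k_out: float
    R0: float = 1.0
    PRU0: float = 200.0
    weight_kg: float = 70.0

    def __post_init__(self) -> None:
        if self.k_out <= 0:
            raise ValueError("receptor turnover rate k_out must be positive")
        if self.R0 != 1.0:
            raise ValueError("baseline free-receptor pool is normalised to R0 = 1")

    @property
    def k_in(self) -> float:
        return self.k_out * self.R0


@dataclass(frozen=True)
class ReceptorState:
    """Receptor-pool state at one instant (all fractions of baseline)."""

    R_free: float
    B_sel: float = 0.0
    B_irr_clo: float = 0.0
    B_irr_pra: float = 0.0
    theta_tica: float = 0.0

    @property
    def active_fraction(self) -> float:
        return self.R_free * (1.0 - self.theta_tica)

    def as_vector(self) -> np.ndarray:
        return np.array([self.R_free, self.B_sel, self.B_irr_clo, self.B_irr_pra])


@dataclass(frozen=True)
class ReceptorTrajectory:
    """Receptor states on the master grid plus the algebraic tica term."""

    times: np.ndarray
    R_free: np.ndarray
    B_sel: np.ndarray
    B_irr_clo: np.ndarray
    B_irr_pra: np.ndarray
    theta_tica: np.ndarray
    active_fraction: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "active_fraction", self.R_free * (1.0 - self.theta_tica)
        )

    def state_at(self, index: int) -> ReceptorState:
        return ReceptorState(
            R_free=float(self.R_free[index]),
            B_sel=float(self.B_sel[index]),
            B_irr_clo=float(self.B_irr_clo[index]),
            B_irr_pra=float(self.B_irr_pra[index]),
            theta_tica=float(self.theta_tica[index]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "R_free": self.R_free,
                "B_sel": self.B_sel,
                "B_irr_clo": self.B_irr_clo,
                "B_irr_pra": self.B_irr_pra,
                "theta_tica": self.theta_tica,
                "a": self.active_fraction,
            }
        )


def theta_noncompetitive(conc: np.ndarray | float, K_T: float) -> np.ndarray:
    """Instantaneous-equilibrium allosteric occupancy C / (C + K_T)."""
    conc = np.asarray(conc, dtype=float)
    return conc / (conc + K_T)


def receptor_rhs(
    state: ReceptorState | np.ndarray,
    t: float,
    conc: Mapping[Drug, float],
    bp: BindingParameterSet,
    sp: SystemParameters,
) -> np.ndarray:
    """Time derivatives of (R_free, B_sel, B_irr_clo, B_irr_pra).

    ``conc`` maps each drug to its binding-species concentration at ``t``.
    The ticagrelor term is algebraic and does not appear here.
    """
    for drug, c in conc.items():
        if c < 0:
            raise ValueError(f"negative concentration for {Drug(drug).value} at t={t}")
    y = state.as_vector() if isinstance(state, ReceptorState) else np.asarray(state, float)
    r, b_sel, b_clo, b_pra = y

    def _c(drug: Drug) -> float:
        return float(conc.get(drug, 0.0))

    sel = bp.get(Drug.SELATOGREL, DrugBinding(mode="none"))
    clo = bp.get(Drug.CLOPIDOGREL, DrugBinding(mode="none"))
    pra = bp.get(Drug.PRASUGREL, DrugBinding(mode="none"))

    on_sel = sel.k_on * _c(Drug.SELATOGREL) if sel.mode != "none" else 0.0
    on_clo = clo.k_on * _c(Drug.CLOPIDOGREL) if clo.mode != "none" else 0.0
    on_pra = pra.k_on * _c(Drug.PRASUGREL) if pra.mode != "none" else 0.0
    k_off_sel = sel.k_off if sel.mode != "none" else 0.0

    dr = (
        sp.k_in
        - sp.k_out * r
        - (on_sel + on_clo + on_pra) * r
        + k_off_sel * b_sel
    )
    db_sel = on_sel * r - (k_off_sel + sp.k_out) * b_sel
    db_clo = on_clo * r - sp.k_out * b_clo
    db_pra = on_pra * r - sp.k_out * b_pra
    return np.array([dr, db_sel, db_clo, db_pra])


def simulate_occupancy(
    regimen: Regimen,
    profiles: Mapping[Drug, ConcentrationProfile],
    bp: BindingParameterSet,
    sp: SystemParameters,
    grid: TimeGrid,
) -> ReceptorTrajectory:
    """Integrate the receptor pool over the grid under the given exposures.

    Concentration forcing is linearly interpolated from the gridded
    profiles; integration restarts at every dose time (irreversible
    binding of a short-lived metabolite makes the system stiff around
    loading doses).
    """
    times = grid.times
    for drug, prof in profiles.items():
        if prof.times.shape != times.shape or not np.allclose(prof.times, times):
            raise ValueError(f"profile for {Drug(drug).value} is not on the master grid")
        if np.any(prof.values < -1e-12):
            raise ValueError(f"negative concentration in profile for {Drug(drug).value}")

    kinetic = []  # (state index, k_on, k_off, values)
    for idx, drug in enumerate((Drug.SELATOGREL, Drug.CLOPIDOGREL, Drug.PRASUGREL)):
        b = bp.get(drug)
        if b is not None and b.mode != "none" and drug in profiles:
            kinetic.append((idx + 1, b.k_on, b.k_off, profiles[drug].values))

    y0 = np.array([sp.R0, 0.0, 0.0, 0.0])
    n = len(times)
    out = np.zeros((4, n))
    out[:, 0] = y0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        r = y[0]
        dy = np.empty(4)
        dr = sp.k_in - sp.k_out * r
        dy[1:] = 0.0
        for idx, k_on, k_off, values in kinetic:
            c = np.interp(t, times, values)
            on = k_on * c
            dy[idx] = on * r - (k_off + sp.k_out) * y[idx]
            dr += -on * r + k_off * y[idx]
        dy[0] = dr
        return dy

    restarts = sorted({e.time_h for e in regimen if times[0] < e.time_h < times[-1]})
    boundaries = restarts + [times[-1]]
    t_cur = times[0]
    y = y0.copy()
    for t_next in boundaries:
        if t_next <= t_cur + 1e-12:
            continue
        mask = (times > t_cur + 1e-12) & (times <= t_next + 1e-12)
        t_eval = np.append(times[mask], t_next)
        t_eval = t_eval[np.insert(np.diff(t_eval) > 1e-12, 0, True)]
        sol = solve_ivp(
            rhs,
            (t_cur, t_next),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=RTOL,
            atol=ATOL,
            # at baseline the rhs vanishes identically; without a step cap
            # the solver can grow its step and miss a short metabolite
            # pulse entirely
            max_step=0.5,
        )
        if not sol.success:
            raise RuntimeError(
                f"receptor-pool integration failed on [{t_cur:.3f}, {t_next:.3f}] h: "
                f"{sol.message}"
            )
        out[:, mask] = sol.y[:, : int(mask.sum())]
        y = sol.y[:, -1].copy()
        t_cur = t_next

    tica = bp.get(Drug.TICAGRELOR)
    if tica is not None and tica.mode != "none" and Drug.TICAGRELOR in profiles:
        theta = theta_noncompetitive(profiles[Drug.TICAGRELOR].values, tica.K_T)
    else:
        theta = np.zeros(n)

    return ReceptorTrajectory(
        times=times,
        R_free=out[0],
        B_sel=out[1],
        B_irr_clo=out[2],
        B_irr_pra=out[3],
        theta_tica=theta,
    )
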