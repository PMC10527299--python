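"""Links from the active receptor fraction to the observable PD scales.

Two readouts are carried throughout: inhibition of platelet aggregation
(IPA, percent) and VerifyNow-style platelet reaction units (PRU). IPA is
linear in the blocked active fraction, ``IPA = 100 * (1 - a)``. PRU is a
power link ``PRU = PRU0 * a ** gamma`` anchored at the two published
correspondences: an untreated subject has PRU 200 (a = 1), and the
therapeutic target PRU < 100 coincides with IPA > 80 % (a = 0.2). The
exponent follows analytically,

    gamma = ln(0.5) / ln(0.2) ~= 0.4307,

so the two scales are consistent by construction: IPA > 80 iff PRU < 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PDLinkParameters",
    "ipa_from_active_fraction",
    "pru_from_active_fraction",
    "active_fraction_from_ipa",
    "active_fraction_from_pru",
]

#: tolerance allowed on the active fraction outside [0, 1] (solver slack)
_EPS = 1e-6


@dataclass(frozen=True)
class PDLinkParameters:
    PRU0: float = 200.0
    gamma_pru: float = field(default=math.log(0.5) / math.log(0.2))

    def __post_init__(self) -> None:
        if self.PRU0 <= 0 or self.gamma_pru <= 0:
            raise ValueError("PRU0 and gamma_pru must be positive")


def _check_fraction(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < -_EPS) or np.any(a > 1.0 + _EPS):
        bad = a[(a < -_EPS) | (a > 1.0 + _EPS)]
        raise ValueError(f"active fraction outside [0, 1]: {bad[:3]}")
    return np.clip(a, 0.0, 1.0)


def ipa_from_active_fraction(a: np.ndarray | float) -> np.ndarray | float:
    """Inhibition of platelet aggregation, percent: ``100 * (1 - a)``."""
    scalar = np.isscalar(a)
    ipa = 100.0 * (1.0 - _check_fraction(a))
    return float(ipa) if scalar else ipa


def pru_from_active_fraction(
    a: np.ndarray | float, params: PDLinkParameters | None = None
) -> np.ndarray | float:
    """Platelet reaction units: ``PRU0 * a ** gamma``."""
    p = params or PDLinkParameters()
    scalar = np.isscalar(a)
    pru = p.PRU0 * _check_fraction(a) ** p.gamma_pru
    return float(pru) if scalar else pru


def active_fraction_from_ipa(ipa: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`ipa_from_active_fraction`."""
    scalar = np.isscalar(ipa)
    a = 1.0 - np.asarray(ipa, dtype=float) / 100.0
    return float(a) if scalar else a


def active_fraction_from_pru(
    pru: np.ndarray | float, params: PDLinkParameters | None = None
) -> np.ndarray | float:
    """Inverse of :func:`pru_from_active_fraction`."""
    p = params or PDLinkParameters()
    scalar = np.isscalar(pru)
    a = (np.asarray(pru, dtype=float) / p.PRU0) ** (1.0 / p.gamma_pru)
    return float(a) if scalar else a
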