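"""Identification of three-term hyperelastic coefficients from uniaxial data.

The closed-form uniaxial nominal stress is linear in the coefficients
(C10, C01, C20), so unweighted least squares on a stress-stretch curve
reduces to a linear problem with basis functions

    phi_10(lam) = 2 (lam - lam^-2)
    phi_01(lam) = 2 (1 - lam^-3)
    phi_20(lam) = 4 (lam - lam^-2)(lam^2 + 2/lam - 3)

Terms excluded from the fit are structural zeros in the returned
parameter set (single-term tissue records keep exact zeros elsewhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constitutive import HyperelasticParams, uniaxial_nominal_stress

__all__ = ["FitError", "FitResult", "StressStretchCurve", "fit_three_term"]

logger = logging.getLogger(__name__)

_TERMS = ("c10", "c01", "c20")


class FitError(ValueError):
    """Raised when a coefficient fit is underdetermined or ill-posed."""


@dataclass(frozen=True)
class StressStretchCurve:
    """A uniaxial nominal stress-stretch curve (stress in MPa)."""

    stretch: np.ndarray
    nominal_stress: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretch, dtype=float)
        p = np.asarray(self.nominal_stress, dtype=float)
        if lam.ndim != 1 or lam.shape != p.shape:
            raise ValueError("stretch and stress must be equal-length 1-D arrays")
        if lam.size < 4:
            raise ValueError(f"need at least 4 points, got {lam.size}")
        if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(p))):
            raise ValueError("curve contains non-finite values")
        if np.any(np.diff(lam) <= 0.0):
            raise ValueError("stretches must be strictly increasing")
        if lam[0] <= 0.0:
            raise ValueError("stretches must be positive")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "nominal_stress", p)

    @property
    def n_points(self) -> int:
        return int(self.stretch.size)


@dataclass(frozen=True)
class FitResult:
    params: HyperelasticParams
    residual_rms: float
    n_points: int
    terms_used: tuple[str, ...] = field(default=_TERMS)


def _basis(lam: np.ndarray) -> dict[str, np.ndarray]:
    base = lam - lam**-2
    return {
        "c10": 2.0 * base,
        "c01": 2.0 * (1.0 - lam**-3),
        "c20": 4.0 * base * (lam**2 + 2.0 / lam - 3.0),
    }


def fit_three_term(
    curve: StressStretchCurve,
    terms: tuple[str, ...] = _TERMS,
    name: str = "fitted",
) -> FitResult:
    """Least-squares coefficients of the uniaxial model on *curve*.

    *terms* selects the free coefficients; the others are fixed at zero.
    Coefficients are unconstrained in sign, but a negative result is
    logged as a warning (it usually signals an unsuitable term subset).
    """
    terms = tuple(terms)
    if not terms:
        raise FitError("at least one term must be selected")
    unknown = [t for t in terms if t not in _TERMS]
    if unknown:
        raise FitError(f"unknown terms {unknown}; choose from {_TERMS}")
    if curve.n_points < len(terms):
        raise FitError(
            f"underdetermined fit: {curve.n_points} points for {len(terms)} terms"
        )

    basis = _basis(curve.stretch)
    design = np.column_stack([basis[t] for t in terms])
    coeffs, *_ = np.linalg.lstsq(design, curve.nominal_stress, rcond=None)

    values = dict.fromkeys(_TERMS, 0.0)
    for term, value in zip(terms, coeffs):
        values[term] = float(value)
        if value < 0.0:
            logger.warning(
                "fitted %s = %.6g is negative (source=%r)", term, value, curve.source
            )

    params = HyperelasticParams(name=name, **values)
    residual = curve.nominal_stress - uniaxial_nominal_stress(params, curve.stretch)
    rms = float(np.sqrt(np.mean(residual**2)))
    return FitResult(
        params=params, residual_rms=rms, n_points=curve.n_points, terms_used=terms
    )
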