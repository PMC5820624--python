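"""Finite-strain isotropic incompressible hyperelasticity.

Single soft-tissue constituents are described by a three-term polynomial
(Mooney-Rivlin type) strain-energy function of the first two principal
invariants of the right Cauchy-Green tensor ``C``::

    W(I1, I2) = C10 (I1 - 3) + C01 (I2 - 3) + C20 (I1 - 3)^2

Composite tissues (the endopelvic fascia: elastin-collagen fibre compound,
adipose tissue and passive smooth muscle) are homogenized with the Voigt
isostrain mixture rule: every constituent sees the same deformation and the
effective energy is the volume-fraction-weighted sum of the constituent
energies.  Incompressibility is enforced with an indeterminate hydrostatic
pressure ``p`` that is fixed per deformation state by a traction boundary
condition (lateral traction-free faces for uniaxial tension).

Stress measures follow the standard finite-strain chain: second
Piola-Kirchhoff ``S = 2 dW/dC - p C^{-1}``, first Piola-Kirchhoff
``P = F S``, and Cauchy ``sigma = J^{-1} F S F^T``.

All stresses are in MPa; stretches and invariants are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CompositionError",
    "DeformationState",
    "HyperelasticParams",
    "InvalidDeformationError",
    "MixtureComposition",
    "StressResult",
    "VoigtMixture",
    "apply_impairment",
    "cauchy_stress",
    "invariants",
    "mixture_energy",
    "pk2_stress",
    "strain_energy",
    "stress_free_pressure",
    "uniaxial_deformation_gradient",
    "uniaxial_nominal_stress",
]


class InvalidDeformationError(ValueError):
    """Raised for kinematically inadmissible states (J <= 0, bad C)."""


class CompositionError(ValueError):
    """Raised when mixture volume fractions are inconsistent."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperelasticParams:
    """Three-term polynomial coefficients of one constituent (MPa).

    A zero coefficient denotes an absent term; single-term materials
    (e.g. a purely C01 fascia) are represented with structural zeros.
    """

    name: str
    c10: float = 0.0
    c01: float = 0.0
    c20: float = 0.0

    def __post_init__(self) -> None:
        for label in ("c10", "c01", "c20"):
            value = getattr(self, label)
            if not np.isfinite(value):
                raise ValueError(f"{self.name}: coefficient {label} must be finite")

    def scaled(self, factor: float, name: str | None = None) -> "HyperelasticParams":
        """Return a copy with every coefficient multiplied by *factor*."""
        return replace(
            self,
            name=name if name is not None else self.name,
            c10=self.c10 * factor,
            c01=self.c01 * factor,
            c20=self.c20 * factor,
        )

    # --- energy and invariant derivatives -----------------------------------

    def strain_energy(self, i1, i2):
        """W(I1, I2) in MPa; accepts scalars or arrays."""
        e1 = np.asarray(i1) - 3.0
        e2 = np.asarray(i2) - 3.0
        return self.c10 * e1 + self.c01 * e2 + self.c20 * e1 * e1

    def energy_derivatives(self, i1, i2):
        """(dW/dI1, dW/dI2) at the given invariants."""
        e1 = np.asarray(i1) - 3.0
        w1 = self.c10 + 2.0 * self.c20 * e1
        w2 = self.c01 * np.ones_like(np.asarray(i2, dtype=float))
        return w1, w2


@dataclass(frozen=True)
class MixtureComposition:
    """Volume fractions of the fascia constituents (fibre compound,
    adipose, smooth muscle); must lie in [0, 1] and sum to one."""

    f_fas: float
    f_ad: float
    f_sm: float

    _SUM_TOL = 1e-12

    def __post_init__(self) -> None:
        fractions = (self.f_fas, self.f_ad, self.f_sm)
        if any(not np.isfinite(f) or f < 0.0 or f > 1.0 for f in fractions):
            raise CompositionError(f"volume fractions must lie in [0, 1]: {fractions}")
        if abs(sum(fractions) - 1.0) > self._SUM_TOL:
            raise CompositionError(
                f"volume fractions must sum to 1 within {self._SUM_TOL}: "
                f"sum={sum(fractions)!r}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_fas, self.f_ad, self.f_sm)


#: Endopelvic fascia composition: 10% elastin-collagen fibre compound,
#: 85% adipose tissue, 5% smooth muscle.
DEFAULT_FASCIA_COMPOSITION = MixtureComposition(f_fas=0.10, f_ad=0.85, f_sm=0.05)


@dataclass(frozen=True)
class VoigtMixture:
    """Voigt (isostrain) mixture of hyperelastic phases.

    All phases share the same deformation; the effective strain energy and
    all its invariant derivatives are volume-fraction-weighted sums, so a
    mixture exposes the same interface as a single constituent.
    """

    phases: tuple[tuple[float, HyperelasticParams], ...]

    @classmethod
    def from_composition(
        cls,
        composition: MixtureComposition,
        fas: HyperelasticParams,
        ad: HyperelasticParams,
        sm: HyperelasticParams,
    ) -> "VoigtMixture":
        return cls(
            phases=(
                (composition.f_fas, fas),
                (composition.f_ad, ad),
                (composition.f_sm, sm),
            )
        )

    @classmethod
    def single(cls, params: HyperelasticParams) -> "VoigtMixture":
        """A degenerate one-phase mixture (fraction 1)."""
        return cls(phases=((1.0, params),))

    def strain_energy(self, i1, i2):
        return sum(f * p.strain_energy(i1, i2) for f, p in self.phases)

    def energy_derivatives(self, i1, i2):
        w1 = w2 = 0.0
        for f, p in self.phases:
            d1, d2 = p.energy_derivatives(i1, i2)
            w1 = w1 + f * d1
            w2 = w2 + f * d2
        return w1, w2

    def scaled(self, factor: float) -> "VoigtMixture":
        return VoigtMixture(
            phases=tuple((f, p.scaled(factor)) for f, p in self.phases)
        )


Material = HyperelasticParams | VoigtMixture


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


def invariants(c: np.ndarray) -> tuple[float, float, float]:
    """Principal invariants (I1, I2, I3) of a right Cauchy-Green tensor.

    I1 = tr C, I2 = ((tr C)^2 - tr C^2) / 2, I3 = det C.  Raises
    :class:`InvalidDeformationError` if ``c`` is not symmetric positive
    definite (no real deformation gradient could have produced it).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (3, 3):
        raise InvalidDeformationError(f"C must be 3x3, got shape {c.shape}")
    if not np.allclose(c, c.T, rtol=0.0, atol=1e-10 * max(1.0, np.abs(c).max())):
        raise InvalidDeformationError("C must be symmetric")
    eigvals = np.linalg.eigvalsh(c)
    if eigvals[0] <= 0.0:
        raise InvalidDeformationError(
            f"C must be positive definite (eigenvalues {eigvals})"
        )
    i1 = float(np.trace(c))
    i2 = 0.5 * float(np.trace(c) ** 2 - np.trace(c @ c))
    i3 = float(np.linalg.det(c))
    return i1, i2, i3


@dataclass(frozen=True)
class DeformationState:
    """A deformation gradient with its derived strain measures."""

    F: np.ndarray
    C: np.ndarray
    B: np.ndarray
    J: float
    I1: float
    I2: float
    I3: float

    _ISOCHORIC_TOL = 1e-8

    @classmethod
    def from_deformation_gradient(cls, f: np.ndarray) -> "DeformationState":
        f = np.asarray(f, dtype=float)
        if f.shape != (3, 3):
            raise InvalidDeformationError(f"F must be 3x3, got shape {f.shape}")
        j = float(np.linalg.det(f))
        if j <= 0.0:
            raise InvalidDeformationError(f"det F must be positive, got {j}")
        c = f.T @ f
        i1, i2, i3 = invariants(c)
        return cls(F=f, C=c, B=f @ f.T, J=j, I1=i1, I2=i2, I3=i3)

    def require_isochoric(self) -> None:
        if abs(self.J - 1.0) > self._ISOCHORIC_TOL:
            raise InvalidDeformationError(
                f"incompressible evaluation requires J = 1, got J = {self.J!r}"
            )


def uniaxial_deformation_gradient(stretch: float) -> DeformationState:
    """Isochoric uniaxial state F = diag(lambda, lambda^-1/2, lambda^-1/2)."""
    if stretch <= 0.0:
        raise InvalidDeformationError(f"stretch must be positive, got {stretch}")
    lat = stretch**-0.5
    return DeformationState.from_deformation_gradient(np.diag([stretch, lat, lat]))


# ---------------------------------------------------------------------------
# energies and stresses
# ---------------------------------------------------------------------------


def strain_energy(material: Material, i1, i2):
    """Strain energy density W(I1, I2) in MPa."""
    return material.strain_energy(i1, i2)


def mixture_energy(
    composition: MixtureComposition,
    fas: HyperelasticParams,
    ad: HyperelasticParams,
    sm: HyperelasticParams,
    c: np.ndarray,
) -> float:
    """Voigt mixture energy at a shared right Cauchy-Green tensor *c*."""
    i1, i2, _ = invariants(c)
    mixture = VoigtMixture.from_composition(composition, fas=fas, ad=ad, sm=sm)
    return float(mixture.strain_energy(i1, i2))


@dataclass(frozen=True)
class StressResult:
    """Stress measures of one deformation state (all MPa)."""

    S: np.ndarray  # second Piola-Kirchhoff
    P: np.ndarray  # first Piola-Kirchhoff (nominal)
    sigma: np.ndarray  # Cauchy
    p: float  # hydrostatic pressure multiplier


def stress_free_pressure(material: Material) -> float:
    """Pressure multiplier that makes the reference configuration stress-free.

    Solving S(C = I) = 0 gives p = 2 (dW/dI1 + 2 dW/dI2) evaluated at
    I1 = I2 = 3.
    """
    w1, w2 = material.energy_derivatives(3.0, 3.0)
    return float(2.0 * (w1 + 2.0 * w2))


def pk2_stress(material: Material, c: np.ndarray, p: float) -> np.ndarray:
    """Second Piola-Kirchhoff stress of an incompressible material.

    S = 2 [(dW/dI1 + I1 dW/dI2) I - (dW/dI2) C] - p C^{-1}; for a Voigt
    mixture the derivative terms are the volume-fraction-weighted sums.
    """
    c = np.asarray(c, dtype=float)
    i1, i2, _ = invariants(c)
    w1, w2 = material.energy_derivatives(i1, i2)
    c_inv = np.linalg.inv(c)
    return 2.0 * ((w1 + i1 * w2) * np.eye(3) - w2 * c) - p * c_inv


def cauchy_stress(s: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Push the second Piola-Kirchhoff stress forward: sigma = J^-1 F S F^T."""
    f = np.asarray(f, dtype=float)
    j = float(np.linalg.det(f))
    if j <= 0.0:
        raise InvalidDeformationError(f"det F must be positive, got {j}")
    return (f @ np.asarray(s, dtype=float) @ f.T) / j


def evaluate_stress_state(material: Material, f: np.ndarray, p: float) -> StressResult:
    """All three stress measures at deformation gradient *f* and pressure *p*."""
    state = DeformationState.from_deformation_gradient(f)
    s = pk2_stress(material, state.C, p)
    return StressResult(S=s, P=state.F @ s, sigma=cauchy_stress(s, state.F), p=p)


def uniaxial_nominal_stress(material: Material, stretch):
    """Closed-form axial nominal (first Piola-Kirchhoff) stress, MPa.

    Incompressible uniaxial tension, lambda_2 = lambda_3 = lambda^-1/2,
    hydrostatic pressure eliminated by the traction-free lateral faces:

        P = sum_i f_i [ 2 C10 (lam - lam^-2) + 2 C01 (1 - lam^-3)
                        + 4 C20 (lam - lam^-2)(lam^2 + 2/lam - 3) ]

    Vectorized over *stretch*.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidDeformationError("stretch must be positive")
    phases = (
        material.phases
        if isinstance(material, VoigtMixture)
        else ((1.0, material),)
    )
    total = np.zeros_like(lam)
    base = lam - lam**-2
    e1 = lam**2 + 2.0 / lam - 3.0  # I1 - 3 of the isochoric uniaxial state
    for fraction, params in phases:
        total = total + fraction * (
            2.0 * params.c10 * base
            + 2.0 * params.c01 * (1.0 - lam**-3)
            + 4.0 * params.c20 * base * e1
        )
    if np.isscalar(stretch):
        return float(total)
    return total


def uniaxial_nominal_stress_slope(material: Material, stretch):
    """dP/d(lambda) of the closed-form uniaxial nominal stress (MPa).

    Used as the axial material tangent of ligament truss elements.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidDeformationError("stretch must be positive")
    phases = (
        material.phases
        if isinstance(material, VoigtMixture)
        else ((1.0, material),)
    )
    base = lam - lam**-2
    dbase = 1.0 + 2.0 * lam**-3
    e1 = lam**2 + 2.0 / lam - 3.0
    de1 = 2.0 * lam - 2.0 * lam**-2
    total = np.zeros_like(lam)
    for fraction, params in phases:
        total = total + fraction * (
            2.0 * params.c10 * dbase
            + 6.0 * params.c01 * lam**-4
            + 4.0 * params.c20 * (dbase * e1 + base * de1)
        )
    if np.isscalar(stretch):
        return float(total)
    return total


# ---------------------------------------------------------------------------
# impairment
# ---------------------------------------------------------------------------

MAX_IMPAIRMENT = 0.95


def apply_impairment(
    params: HyperelasticParams, impairment: float
) -> HyperelasticParams:
    """Weaken a tissue by scaling every coefficient by (1 - impairment).

    Impairment models the stiffness loss of lax connective tissue
    (collagen degradation); the admissible range is [0, 0.95], i.e. the
    stiffness multiplier never falls below 0.05.
    """
    if not (0.0 <= impairment <= MAX_IMPAIRMENT):
        raise ValueError(
            f"impairment must lie in [0, {MAX_IMPAIRMENT}], got {impairment}"
        )
    return params.scaled(1.0 - impairment)
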