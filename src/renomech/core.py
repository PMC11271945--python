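"""Constitutive core: kinematics, strain energy, elastic stresses and damage.

All quantities use a fixed unit system: stress and moduli in MPa, time in
seconds, lengths in millimetres, strains dimensionless.

The material model splits the strain energy into a distortional part --
a cubic Yeoh polynomial in (I1_bar - 3) softened by a damage factor
``phi(c) = 1 + ln(1 - c)`` -- and a volumetric part ``K/2 (Je - 1)^2``
written in the elastic volume ratio ``Je = J / (1 + c)``, where the void
volume fraction ``c`` accounts for damage-produced (or fluid-loss) volume.
Damage grows with the octahedral shear strain of the isochoric deformation
and is amplified/suppressed by the pressure through ``exp(alpha * P)``.

Everything here is evaluated in principal axes: the loading programmes of
interest (uniaxial tension, ramp-hold relaxation, confined compression) are
coaxial, so stress and strain share a fixed eigenbasis and tensors reduce to
triples of principal values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    DamageValidityWarning,
    InvalidInputError,
    InvalidStateError,
)

__all__ = [
    "KinematicState",
    "HyperelasticCoefficients",
    "DamageParameters",
    "DamageState",
    "OCTAHEDRAL_PREFACTOR",
    "compute_invariants",
    "distortional_energy",
    "volumetric_energy",
    "damage_softening_factor",
    "elastic_pressure",
    "elastic_deviatoric_stress",
    "octahedral_shear_strain",
    "damage_growth_increment",
    "initial_shear_modulus",
    "moduli_from_shear",
]

#: Scale factor applied to sqrt(2*I1b^2 - 6*I2b) in the octahedral shear
#: strain.  The radicand equals sum_{i<j} (lb_i^2 - lb_j^2)^2 for isochoric
#: principal stretches lb_i, which is convention-free; the prefactor merely
#: rescales the damage coefficient beta.  1/6 is the package default;
#: pass another value (e.g. 1/3) to select a different convention.
OCTAHEDRAL_PREFACTOR: float = 1.0 / 6.0

#: Threshold on c above which phi(c) = 1 + ln(1-c) turns negative.
PHI_VALIDITY_BOUND: float = 1.0 - math.exp(-1.0)


@dataclass
class KinematicState:
    """Principal-axis deformation state at a material point.

    Attributes
    ----------
    principal_stretches : ndarray, shape (3,)
        Total principal stretches ``lambda_i`` (> 0).
    J : float
        Total volume ratio, ``lambda_1 * lambda_2 * lambda_3``.
    I1_bar, I2_bar : float
        First and second invariants of the isochoric right Cauchy-Green
        tensor ``C_bar = J**(-2/3) C``; both equal 3 in the undeformed state.
    Je : float or None
        Elastic volume ratio ``J / (1 + c)``.  ``None`` until a caller that
        tracks damage fills it in.
    """

    principal_stretches: np.ndarray
    J: float
    I1_bar: float
    I2_bar: float
    Je: float | None = None

    def with_damage(self, c: float) -> "KinematicState":
        """Return a copy with ``Je`` filled in from the void fraction ``c``."""
        if not 0.0 <= c < 1.0:
            raise InvalidStateError(f"void volume fraction c={c} outside [0, 1)")
        return KinematicState(
            principal_stretches=self.principal_stretches,
            J=self.J,
            I1_bar=self.I1_bar,
            I2_bar=self.I2_bar,
            Je=self.J / (1.0 + c),
        )


@dataclass
class HyperelasticCoefficients:
    """Yeoh coefficients plus the (fixed) Poisson ratio.

    ``C10, C20, C30`` are the cubic Yeoh coefficients in MPa.  ``mu`` is the
    initial Poisson ratio used only to derive the initial bulk modulus from
    the initial shear modulus ``G0 = 2 (C10 + C20 + C30)``; the default 0.495
    renders the tissue effectively incompressible before damage begins.
    """

    C10: float
    C20: float = 0.0
    C30: float = 0.0
    mu: float = 0.495
    #: Initial bulk modulus (MPa); derived in ``__post_init__``.
    K0: float = field(init=False)

    def __post_init__(self) -> None:
        G0 = initial_shear_modulus(self)
        _, self.K0 = moduli_from_shear(G0, self.mu)

    @property
    def G0(self) -> float:
        return initial_shear_modulus(self)


@dataclass(frozen=True)
class DamageParameters:
    """Constants of the void-growth law ``cdot = gamma_dot * exp(alpha P)``,
    ``gamma = beta * Igamma**n``.

    alpha : pressure sensitivity (1/MPa); positive pressure (tension)
        accelerates growth, compressive pressure suppresses it.
    beta : growth coefficient (dimensionless).
    n_exp : growth exponent (dimensionless).
    """

    alpha: float = 0.0
    beta: float = 3.0e-4
    n_exp: float = 2.0

    def __post_init__(self) -> None:
        if self.beta < 0.0:
            raise ConfigurationError(f"beta must be >= 0, got {self.beta}")
        if self.n_exp <= 0.0:
            raise ConfigurationError(f"n_exp must be > 0, got {self.n_exp}")


@dataclass
class DamageState:
    """Void volume fraction ``c`` and the accumulated distortion ``gamma``."""

    c: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c < 1.0:
            raise InvalidStateError(f"c={self.c} outside [0, 1)")


def compute_invariants(stretches) -> KinematicState:
    """Kinematic state from three principal stretches.

    The isochoric invariants are computed from the volume-preserving
    stretches ``lb_i = lambda_i * J**(-1/3)``, so they are unchanged by a
    pure dilatation.
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,):
        raise InvalidInputError(f"expected 3 principal stretches, got shape {lam.shape}")
    if not np.all(lam > 0.0):
        raise InvalidInputError(f"principal stretches must be positive, got {lam}")
    J = float(lam[0] * lam[1] * lam[2])
    lb2 = lam * lam * J ** (-2.0 / 3.0)  # squared isochoric stretches
    I1_bar = float(lb2.sum())
    I2_bar = float(lb2[0] * lb2[1] + lb2[1] * lb2[2] + lb2[0] * lb2[2])
    return KinematicState(principal_stretches=lam, J=J, I1_bar=I1_bar, I2_bar=I2_bar)


def _dpsi_dI1(I1_bar: float, coeffs: HyperelasticCoefficients) -> float:
    """Derivative of the Yeoh distortional energy w.r.t. I1_bar."""
    x = I1_bar - 3.0
    return coeffs.C10 + 2.0 * coeffs.C20 * x + 3.0 * coeffs.C30 * x * x


def distortional_energy(state: KinematicState, coeffs: HyperelasticCoefficients) -> float:
    """Yeoh distortional energy density (MPa), without the damage factor."""
    x = state.I1_bar - 3.0
    return coeffs.C10 * x + coeffs.C20 * x**2 + coeffs.C30 * x**3


def volumetric_energy(Je: float, K: float) -> float:
    """Volumetric energy density ``K/2 (Je - 1)^2`` (MPa)."""
    if Je <= 0.0:
        raise InvalidInputError(f"Je must be positive, got {Je}")
    if K <= 0.0:
        raise InvalidInputError(f"bulk modulus must be positive, got {K}")
    return 0.5 * K * (Je - 1.0) ** 2


def damage_softening_factor(c: float) -> float:
    """Distortional softening factor ``phi(c) = 1 + ln(1 - c)``.

    Defined for ``0 <= c < 1``; monotone decreasing, equal to 1 at c = 0 and
    negative for ``c > 1 - exp(-1)`` (a :class:`DamageValidityWarning` is
    issued there -- the law is only physical for small void fractions).
    """
    if not 0.0 <= c < 1.0:
        raise InvalidInputError(f"c={c} outside the domain [0, 1) of phi")
    phi = 1.0 + math.log1p(-c)
    if phi < 0.0:
        warnings.warn(
            f"void fraction c={c:.4g} exceeds {PHI_VALIDITY_BOUND:.4g}: "
            "softening factor is negative and the energy loses positivity",
            DamageValidityWarning,
            stacklevel=2,
        )
    return phi


def elastic_pressure(state: KinematicState, c: float, K: float) -> float:
    """Elastic pressure ``d(vol. energy)/dJ = K (Je - 1) / (1 + c)`` (MPa).

    The derivative is taken through ``Je = J / (1 + c)`` with ``c`` frozen
    (staggered damage update), so damage-produced volume carries no elastic
    pressure.
    """
    if state.Je is None:
        state = state.with_damage(c)
    elif abs(state.Je * (1.0 + c) - state.J) > 1e-9 * max(1.0, state.J):
        raise InvalidStateError(
            f"inconsistent (J, Je, c) = ({state.J}, {state.Je}, {c}): J != Je*(1+c)"
        )
    return K * (state.Je - 1.0) / (1.0 + c)


def elastic_deviatoric_stress(
    state: KinematicState, c: float, coeffs: HyperelasticCoefficients
) -> np.ndarray:
    """Principal components of the elastic Cauchy stress deviator (MPa).

    For the Yeoh energy (distortional part a function of I1_bar only) the
    deviatoric Cauchy stress in principal axes is

        ``s_i = phi(c) * (2/J) * dW/dI1_bar * (lb_i^2 - I1_bar / 3)``

    with ``lb_i`` the isochoric stretches.  The components are traceless and
    scale linearly with the softening factor ``phi(c)``.
    """
    phi = damage_softening_factor(c)
    lam = state.principal_stretches
    lb2 = lam * lam * state.J ** (-2.0 / 3.0)
    dpsi = _dpsi_dI1(state.I1_bar, coeffs)
    return phi * (2.0 / state.J) * dpsi * (lb2 - state.I1_bar / 3.0)


def octahedral_shear_strain(
    state: KinematicState, prefactor: float = OCTAHEDRAL_PREFACTOR
) -> float:
    """Scalar distortion measure ``prefactor * sqrt(2 I1b^2 - 6 I2b)``.

    The radicand equals ``sum_{i<j} (lb_i^2 - lb_j^2)^2`` and vanishes iff
    the isochoric stretch is a pure rotation/identity.  Tiny negative
    radicands from round-off are clipped to zero.
    """
    radicand = 2.0 * state.I1_bar**2 - 6.0 * state.I2_bar
    if radicand < 0.0:
        if radicand < -1e-12:
            raise InvalidStateError(
                f"negative radicand {radicand} in octahedral shear strain; "
                "invariants are inconsistent"
            )
        radicand = 0.0
    return prefactor * math.sqrt(radicand)


def damage_growth_increment(
    Igamma_old: float,
    Igamma_new: float,
    pressure: float,
    params: DamageParameters,
) -> float:
    """Increment of the void volume fraction over one step.

    Integrates ``cdot = gamma_dot * exp(alpha P)`` with
    ``gamma = beta * Igamma**n`` between two consecutive values of the
    octahedral shear strain, holding the pressure at its step value
    (staggered coupling).  Increments are clipped at zero so damage never
    heals on unloading; with ``alpha = 0`` the integrated ``c(t)`` equals
    ``beta * Igamma(t)**n`` exactly on monotone paths.
    """
    d_gamma = params.beta * (
        Igamma_new ** params.n_exp - Igamma_old ** params.n_exp
    )
    if d_gamma <= 0.0:
        return 0.0
    return d_gamma * math.exp(params.alpha * pressure)


def initial_shear_modulus(coeffs: HyperelasticCoefficients) -> float:
    """Initial shear modulus ``G0 = 2 (C10 + C20 + C30)`` (MPa)."""
    G0 = 2.0 * (coeffs.C10 + coeffs.C20 + coeffs.C30)
    if G0 <= 0.0:
        raise ConfigurationError(
            f"initial shear modulus 2*(C10+C20+C30) = {G0} must be positive"
        )
    return G0


def moduli_from_shear(G: float, mu: float) -> tuple[float, float]:
    """Young's and bulk moduli from the shear modulus and Poisson ratio.

    ``E = 2 (1 + mu) G`` and ``K = 2 G (1 + mu) / (3 (1 - 2 mu))``.
    """
    if not 0.0 < mu < 0.5:
        raise ConfigurationError(
            f"Poisson ratio must lie in (0, 0.5) for a finite bulk modulus, got {mu}"
        )
    E = 2.0 * (1.0 + mu) * G
    K = 2.0 * G * (1.0 + mu) / (3.0 * (1.0 - 2.0 * mu))
    return E, K
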