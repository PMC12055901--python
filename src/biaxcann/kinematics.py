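"""Incompressible planar-biaxial kinematics.

A square tissue patch stretched along two orthogonal in-plane axes (axial and
circumferential) with negligible shear is described by a diagonal deformation
gradient ``F = diag{lam_ax, lam_cir, lam_thick}``.  Perfect incompressibility
(J = det F = 1) fixes the thickness stretch to ``1 / (lam_ax * lam_cir)``, so
the deformation state is fully determined by the two in-plane stretches.

A single family of collagen fibers at an in-plane angle ``alpha`` from the
axial direction (reference unit vector ``n0 = [cos a, sin a, 0]``) introduces
the anisotropic invariants I4 and I5 next to the isotropic I1 and I2:

    I1 = lam1^2 + lam2^2 + (lam1 lam2)^-2
    I2 = lam1^-2 + lam2^-2 + (lam1 lam2)^2
    I4 = lam1^2 cos^2 a + lam2^2 sin^2 a
    I5 = lam1^4 cos^2 a + lam2^4 sin^2 a

With the plane-stress condition P33 = 0 the hydrostatic pressure of the
incompressibility constraint is eliminated analytically, and the two in-plane
engineering (first Piola-Kirchhoff) stresses become linear combinations of the
four energy derivatives d(psi)/dI with purely geometric coefficients.  Those
coefficients are the *total* stretch-derivatives of the invariants along the
incompressible biaxial manifold, which is what makes the central-difference
check of stress against energy possible.

Arterial tissue carries two fiber families placed symmetrically about the
circumferential axis with identical properties; their effect is folded in by
doubling the I4 and I5 stress contributions (``two_fiber_families=True``, the
default throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DomainError",
    "DeformationState",
    "FiberOrientation",
    "InvariantSet",
    "normalize_angle_deg",
    "compute_invariants",
    "invariants_arrays",
    "invariant_derivative_arrays",
    "stress_coefficients",
    "hydrostatic_pressure",
    "assemble_biaxial_stress",
    "thickness_stress",
]

FIBER_MODES = ("fixed", "fitted")


class DomainError(ValueError):
    """Raised for kinematically inadmissible inputs (non-positive stretches)."""


def _check_positive(*stretches) -> None:
    for lam in stretches:
        arr = np.asarray(lam, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
            raise DomainError("stretches must be finite and strictly positive")


def normalize_angle_deg(alpha_deg: float) -> float:
    """Reflect an angle into [0, 90] degrees.

    The fiber direction enters only through cos^2 and sin^2, which are
    invariant under alpha -> -alpha and alpha -> 180 - alpha, so every angle
    has a unique representative in [0, 90].
    """
    a = np.asarray(alpha_deg, dtype=float) % 180.0
    a = np.where(a > 90.0, 180.0 - a, a)
    return float(a) if a.ndim == 0 else a


@dataclass(frozen=True)
class DeformationState:
    """Biaxial stretch state; thickness stretch follows from J = 1."""

    lambda_ax: float
    lambda_cir: float

    def __post_init__(self) -> None:
        _check_positive(self.lambda_ax, self.lambda_cir)

    @property
    def lambda_thick(self) -> float:
        return 1.0 / (self.lambda_ax * self.lambda_cir)


@dataclass(frozen=True)
class FiberOrientation:
    """In-plane fiber angle (degrees from the axial direction) and its status.

    ``mode='fixed'`` keeps the angle at its value during fitting;
    ``mode='fitted'`` marks it as a trainable parameter.  The stored angle is
    always normalized into [0, 90] degrees: 0 = purely axial fiber,
    90 = purely circumferential.
    """

    alpha_deg: float
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in FIBER_MODES:
            raise ValueError(f"mode must be one of {FIBER_MODES}, got {self.mode!r}")
        object.__setattr__(self, "alpha_deg", normalize_angle_deg(self.alpha_deg))

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha_deg)


@dataclass(frozen=True)
class InvariantSet:
    """The four invariants and their total stretch-derivatives.

    Derivatives are taken along the incompressible biaxial manifold (thickness
    stretch eliminated), so e.g. ``dI1_dl1 = 2 lam1 - 2 lam1^-3 lam2^-2``.
    These are exactly the geometric coefficients of the plane-stress
    engineering stresses.
    """

    I1: float
    I2: float
    I4: float
    I5: float
    dI1_dl1: float
    dI1_dl2: float
    dI2_dl1: float
    dI2_dl2: float
    dI4_dl1: float
    dI4_dl2: float
    dI5_dl1: float
    dI5_dl2: float


def invariants_arrays(lam_ax, lam_cir, alpha_rad):
    """Vectorized I1, I2, I4, I5 for arrays of biaxial stretches."""
    _check_positive(lam_ax, lam_cir)
    l1 = np.asarray(lam_ax, dtype=float)
    l2 = np.asarray(lam_cir, dtype=float)
    c2 = math.cos(alpha_rad) ** 2
    s2 = math.sin(alpha_rad) ** 2
    prod2 = (l1 * l2) ** 2
    i1 = l1**2 + l2**2 + 1.0 / prod2
    i2 = l1**-2 + l2**-2 + prod2
    # anchored form of c2*l1^2 + s2*l2^2: exact (= 1) at the reference state,
    # where c2 + s2 would otherwise round away from one
    i4 = l2**2 + c2 * (l1**2 - l2**2)
    i5 = l2**4 + c2 * (l1**4 - l2**4)
    return i1, i2, i4, i5


def invariant_derivative_arrays(lam_ax, lam_cir, alpha_rad):
    """Total stretch-derivatives of (I1, I2, I4, I5) w.r.t. (lam_ax, lam_cir).

    Returns an array of shape ``(..., 2, 4)``: axis -2 is the stretch
    direction (axial, circumferential), axis -1 the invariant.
    """
    _check_positive(lam_ax, lam_cir)
    l1 = np.asarray(lam_ax, dtype=float)
    l2 = np.asarray(lam_cir, dtype=float)
    c2 = math.cos(alpha_rad) ** 2
    s2 = math.sin(alpha_rad) ** 2
    out = np.empty(np.broadcast(l1, l2).shape + (2, 4))
    out[..., 0, 0] = 2.0 * (l1 - l1**-3 * l2**-2)
    out[..., 1, 0] = 2.0 * (l2 - l2**-3 * l1**-2)
    out[..., 0, 1] = 2.0 * (l1 * l2**2 - l1**-3)
    out[..., 1, 1] = 2.0 * (l1**2 * l2 - l2**-3)
    out[..., 0, 2] = 2.0 * l1 * c2
    out[..., 1, 2] = 2.0 * l2 * s2
    out[..., 0, 3] = 4.0 * l1**3 * c2
    out[..., 1, 3] = 4.0 * l2**3 * s2
    return out


def stress_coefficients(lam_ax, lam_cir, alpha_rad, two_fiber_families: bool = True):
    """Geometric coefficients mapping energy derivatives to (P_ax, P_cir).

    Shape ``(..., 2, 4)``.  With ``two_fiber_families`` the anisotropic (I4,
    I5) columns are doubled, accounting for the second, symmetric fiber family
    with identical properties.
    """
    coeff = invariant_derivative_arrays(lam_ax, lam_cir, alpha_rad)
    if two_fiber_families:
        coeff = coeff.copy()
        coeff[..., 2:] *= 2.0
    return coeff


def compute_invariants(state: DeformationState, fiber: FiberOrientation) -> InvariantSet:
    """Invariants and their total stretch-derivatives for a single state."""
    i1, i2, i4, i5 = invariants_arrays(state.lambda_ax, state.lambda_cir, fiber.alpha_rad)
    d = invariant_derivative_arrays(state.lambda_ax, state.lambda_cir, fiber.alpha_rad)
    return InvariantSet(
        I1=float(i1), I2=float(i2), I4=float(i4), I5=float(i5),
        dI1_dl1=float(d[0, 0]), dI1_dl2=float(d[1, 0]),
        dI2_dl1=float(d[0, 1]), dI2_dl2=float(d[1, 1]),
        dI4_dl1=float(d[0, 2]), dI4_dl2=float(d[1, 2]),
        dI5_dl1=float(d[0, 3]), dI5_dl2=float(d[1, 3]),
    )


def hydrostatic_pressure(state: DeformationState, dpsi_dI1: float, dpsi_dI2: float) -> float:
    """Lagrange pressure eliminating the thickness stress.

    p = 2 (lam1 lam2)^-2 dpsi/dI1 + 2 (lam1^-2 + lam2^-2) dpsi/dI2

    The anisotropic invariants do not enter: the fiber lies in-plane, so I4
    and I5 are independent of the thickness stretch.
    """
    l1, l2 = state.lambda_ax, state.lambda_cir
    return 2.0 * (l1 * l2) ** -2 * dpsi_dI1 + 2.0 * (l1**-2 + l2**-2) * dpsi_dI2


def assemble_biaxial_stress(
    state: DeformationState,
    fiber: FiberOrientation,
    dpsi,
    two_fiber_families: bool = True,
):
    """In-plane engineering stresses (P_ax, P_cir) in kPa.

    ``dpsi`` is the 4-vector of energy derivatives (dpsi/dI1, dpsi/dI2,
    dpsi/dI4, dpsi/dI5), all evaluated at ``state``.  The hydrostatic pressure
    is already eliminated through the plane-stress condition, so the implied
    thickness stress is identically zero (see :func:`thickness_stress`).
    """
    dpsi = np.asarray(dpsi, dtype=float)
    if dpsi.shape != (4,):
        raise ValueError("dpsi must be a length-4 vector of energy derivatives")
    coeff = stress_coefficients(
        state.lambda_ax, state.lambda_cir, fiber.alpha_rad, two_fiber_families
    )
    p = coeff @ dpsi
    return float(p[0]), float(p[1])


def thickness_stress(state: DeformationState, dpsi_dI1: float, dpsi_dI2: float) -> float:
    """P33 reconstructed the long way, for verification.

    Computes P33 = dpsi/dI1 * dI1/dF33 + dpsi/dI2 * dI2/dF33 - p / lam_thick
    with the pressure from :func:`hydrostatic_pressure`; analytically zero.
    """
    l1, l2 = state.lambda_ax, state.lambda_cir
    l3 = state.lambda_thick
    p = hydrostatic_pressure(state, dpsi_dI1, dpsi_dI2)
    dI1_dF33 = 2.0 * l3
    dI2_dF33 = 2.0 * (l1 / l2 + l2 / l1)
    return dpsi_dI1 * dI1_dF33 + dpsi_dI2 * dI2_dF33 - p / l3
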