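"""The 16-term invariant-based strain-energy network and its named variants.

The energy is a sparse, additively polyconvex sum over the four invariants
(I1, I2, I4, I5), two powers (linear, quadratic in the shifted invariant) and
two activations (identity, exponential):

    psi = sum over blocks x in {I1-3, I2-3, I4-1, I5-1} of
          w*a wa x  +  wb [exp(w*b x) - 1]  +  w*c wc x^2  +  wd [exp(w*d x^2) - 1]

Each of the 16 terms carries an inner weight ``w*`` (dimensionless) and an
outer weight ``w`` (kPa); all 32 weights are constrained non-negative, which
together with the -3 / -1 shifts guarantees psi = 0 and a convex, monotone
response in the undeformed state.  For identity-activation terms only the
product ``w* w`` is identifiable, and reporting uses the product.

Two classical sub-models are single masks of this network:

* HGO (Holzapfel-Gasser-Ogden): terms {1, 12}, i.e. a linear neo-Hookean I1
  term plus an exponential-quadratic I4 fiber term, with the weight-parameter
  dictionary c1 = 2 w1* w1, k1 = 2 w12* w12, k2 = w12*.
* Reduced two-term artery model: terms {2, 15}, an exponential I1 term plus a
  quadratic I5 term, psi = a1 [exp(a2 [I1-3]) - 1] + b [I5-1]^2 with
  a1 = w2, a2 = w2*, b = w15* w15.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .kinematics import (
    FiberOrientation,
    InvariantSet,
    invariants_arrays,
    stress_coefficients,
)

__all__ = [
    "TermSpec",
    "TERM_TABLE",
    "N_TERMS",
    "TermWeights",
    "ModelSpec",
    "HgoParameters",
    "ReducedParameters",
    "strain_energy",
    "energy_derivatives",
    "predict_stress",
    "map_hgo_weights_to_parameters",
    "map_hgo_parameters_to_weights",
    "map_reduced_weights_to_parameters",
    "map_reduced_parameters_to_weights",
    "term_stress_contributions",
    "save_model",
    "load_model",
]

N_TERMS = 16
INVARIANT_NAMES = ("I1", "I2", "I4", "I5")
REFERENCE_VALUES = {"I1": 3.0, "I2": 3.0, "I4": 1.0, "I5": 1.0}


@dataclass(frozen=True)
class TermSpec:
    """One node of the energy network, in the canonical 1..16 ordering."""

    index: int  # 1-based
    invariant: str  # I1 | I2 | I4 | I5
    power: int  # 1 | 2
    activation: str  # identity | exp

    @property
    def label(self) -> str:
        x = f"[{self.invariant}-{int(REFERENCE_VALUES[self.invariant])}]"
        body = x if self.power == 1 else f"{x}^2"
        return body if self.activation == "identity" else f"exp({body})"


def _build_term_table() -> tuple[TermSpec, ...]:
    terms = []
    idx = 1
    for inv in INVARIANT_NAMES:
        for power, activation in ((1, "identity"), (1, "exp"), (2, "identity"), (2, "exp")):
            terms.append(TermSpec(index=idx, invariant=inv, power=power, activation=activation))
            idx += 1
    return tuple(terms)


TERM_TABLE: tuple[TermSpec, ...] = _build_term_table()
# term -> invariant column (0..3), power, and exp flag, as arrays for vector math
_TERM_INV = np.array([INVARIANT_NAMES.index(t.invariant) for t in TERM_TABLE])
_TERM_POW = np.array([t.power for t in TERM_TABLE])
_TERM_EXP = np.array([t.activation == "exp" for t in TERM_TABLE])
# odd anisotropic terms: linear in I4 or I5; nonzero stress at the reference state
_ODD_ANISO = np.array([t.invariant in ("I4", "I5") and t.power == 1 for t in TERM_TABLE])


@dataclass
class TermWeights:
    """Non-negative inner/outer weights for all 16 terms, plus the fiber angle."""

    w_star: np.ndarray
    w: np.ndarray
    fiber: FiberOrientation = field(default_factory=lambda: FiberOrientation(70.0))

    def __post_init__(self) -> None:
        self.w_star = np.asarray(self.w_star, dtype=float).reshape(N_TERMS).copy()
        self.w = np.asarray(self.w, dtype=float).reshape(N_TERMS).copy()
        if np.any(self.w_star < 0) or np.any(self.w < 0):
            raise ValueError("all term weights must be non-negative")

    @classmethod
    def zeros(cls, fiber: FiberOrientation | None = None) -> "TermWeights":
        fiber = fiber if fiber is not None else FiberOrientation(70.0)
        return cls(np.zeros(N_TERMS), np.zeros(N_TERMS), fiber)

    def products(self) -> np.ndarray:
        """Identifiable per-term magnitudes w* . w (kPa)."""
        return self.w_star * self.w

    def with_fiber(self, fiber: FiberOrientation) -> "TermWeights":
        return TermWeights(self.w_star, self.w, fiber)


@dataclass(frozen=True)
class ModelSpec:
    """Which of the 16 terms participate, and a variant tag."""

    active_mask: tuple
    variant: str = "custom"

    def __post_init__(self) -> None:
        mask = tuple(bool(b) for b in self.active_mask)
        if len(mask) != N_TERMS:
            raise ValueError(f"active_mask must have {N_TERMS} entries")
        object.__setattr__(self, "active_mask", mask)

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls((True,) * N_TERMS, "full")

    @classmethod
    def hgo(cls) -> "ModelSpec":
        return cls.from_indices([1, 12], "hgo")

    @classmethod
    def reduced(cls) -> "ModelSpec":
        return cls.from_indices([2, 15], "reduced")

    @classmethod
    def from_indices(cls, indices: Iterable[int], variant: str = "custom") -> "ModelSpec":
        idx = set(indices)
        if not idx <= set(range(1, N_TERMS + 1)):
            raise ValueError("term indices must lie in 1..16")
        return cls(tuple(i + 1 in idx for i in range(N_TERMS)), variant)

    @property
    def active_indices(self) -> tuple:
        return tuple(i + 1 for i in range(N_TERMS) if self.active_mask[i])

    def mask_array(self) -> np.ndarray:
        return np.asarray(self.active_mask, dtype=float)

    @property
    def n_submodels(self) -> int:
        """Number of on/off term combinations the full network spans."""
        return 2 ** N_TERMS


@dataclass(frozen=True)
class HgoParameters:
    """Classical HGO material parameters (kPa, kPa, dimensionless, degrees)."""

    c1: float
    k1: float
    k2: float
    alpha_deg: float


@dataclass(frozen=True)
class ReducedParameters:
    """Reduced two-term artery model: psi = a1[exp(a2[I1-3])-1] + b[I5-1]^2."""

    a1: float
    a2: float
    b: float
    alpha_deg: float


# ---------------------------------------------------------------------------
# vectorized term evaluation
# ---------------------------------------------------------------------------

def shifted_invariants(lam_ax, lam_cir, alpha_rad) -> np.ndarray:
    """(I1-3, I2-3, I4-1, I5-1) stacked along the last axis, shape (..., 4)."""
    i1, i2, i4, i5 = invariants_arrays(lam_ax, lam_cir, alpha_rad)
    return np.stack([i1 - 3.0, i2 - 3.0, i4 - 1.0, i5 - 1.0], axis=-1)


def _clamped_exp(arg, exp_clamp):
    if exp_clamp is not None:
        arg = np.minimum(arg, exp_clamp)
    return np.exp(arg)


def term_energies(x4: np.ndarray, w_star, w, mask=None, exp_clamp=None) -> np.ndarray:
    """Per-term energy, shape (..., 16).  ``x4`` holds the shifted invariants."""
    y = x4[..., _TERM_INV] ** _TERM_POW  # (..., 16)
    e = _clamped_exp(w_star * y, exp_clamp)
    vals = np.where(_TERM_EXP, w * (e - 1.0), w_star * w * y)
    if mask is not None:
        vals = vals * mask
    return vals


def term_stress_factors(x4: np.ndarray, w_star, w, mask=None, exp_clamp=None) -> np.ndarray:
    """d(psi_t)/dI for each term, shape (..., 16)."""
    x = x4[..., _TERM_INV]
    y = x ** _TERM_POW
    e = _clamped_exp(w_star * y, exp_clamp)
    lin = np.where(_TERM_EXP, w * w_star * e, w_star * w)
    quad = np.where(_TERM_EXP, 2.0 * w * w_star * x * e, 2.0 * w_star * w * x)
    vals = np.where(_TERM_POW == 1, lin, quad)
    if mask is not None:
        vals = vals * mask
    return vals


def term_stress_factor_weight_grads(x4, w_star, w, mask=None, exp_clamp=None):
    """Gradients of each term's stress factor w.r.t. its own (w*, w).

    Returns ``(d_dwstar, d_dw)``, each of shape (..., 16).  Used by the
    training engine to assemble analytic loss gradients.
    """
    x = x4[..., _TERM_INV]
    y = x ** _TERM_POW
    e = _clamped_exp(w_star * y, exp_clamp)
    d_dw = np.where(
        _TERM_POW == 1,
        np.where(_TERM_EXP, w_star * e, w_star),
        np.where(_TERM_EXP, 2.0 * w_star * x * e, 2.0 * w_star * x),
    )
    d_dws = np.where(
        _TERM_POW == 1,
        np.where(_TERM_EXP, w * e * (1.0 + w_star * y), w),
        np.where(_TERM_EXP, 2.0 * w * x * e * (1.0 + w_star * y), 2.0 * w * x),
    )
    if mask is not None:
        d_dw = d_dw * mask
        d_dws = d_dws * mask
    return d_dws, d_dw


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _invariant_x4(inv: InvariantSet) -> np.ndarray:
    return np.array([inv.I1 - 3.0, inv.I2 - 3.0, inv.I4 - 1.0, inv.I5 - 1.0])


def strain_energy(
    inv: InvariantSet, weights: TermWeights, mask: ModelSpec | None = None,
    exp_clamp: float | None = None,
) -> float:
    """Total strain-energy density (kPa); exactly zero at the reference state."""
    m = mask.mask_array() if mask is not None else None
    vals = term_energies(_invariant_x4(inv), weights.w_star, weights.w, m, exp_clamp)
    return float(vals.sum())


def energy_derivatives(
    inv: InvariantSet, weights: TermWeights, mask: ModelSpec | None = None,
    exp_clamp: float | None = None,
) -> np.ndarray:
    """(dpsi/dI1, dpsi/dI2, dpsi/dI4, dpsi/dI5) in kPa."""
    m = mask.mask_array() if mask is not None else None
    d = term_stress_factors(_invariant_x4(inv), weights.w_star, weights.w, m, exp_clamp)
    out = np.zeros(4)
    np.add.at(out, _TERM_INV, d)
    return out


def _active_product_mask(weights: TermWeights, mask: ModelSpec | None) -> np.ndarray:
    m = np.ones(N_TERMS) if mask is None else mask.mask_array()
    return m * weights.products()


def _warn_odd_aniso(weights: TermWeights, mask: ModelSpec | None) -> None:
    prods = _active_product_mask(weights, mask)
    if np.any(prods[_ODD_ANISO] > 0):
        warnings.warn(
            "linear I4/I5 terms carry weight: the model predicts nonzero "
            "stress at the undeformed reference state",
            stacklevel=3,
        )


def predict_stress(
    lam_ax,
    lam_cir,
    weights: TermWeights,
    mask: ModelSpec | None = None,
    two_fiber_families: bool = True,
    exp_clamp: float | None = None,
    warn_reference_stress: bool = True,
):
    """Engineering stresses (P_ax, P_cir) in kPa, vectorized over stretches."""
    if warn_reference_stress:
        _warn_odd_aniso(weights, mask)
    alpha = weights.fiber.alpha_rad
    x4 = shifted_invariants(lam_ax, lam_cir, alpha)
    m = mask.mask_array() if mask is not None else None
    d = term_stress_factors(x4, weights.w_star, weights.w, m, exp_clamp)  # (..., 16)
    coeff = stress_coefficients(lam_ax, lam_cir, alpha, two_fiber_families)  # (..., 2, 4)
    p = np.einsum("...dt,...t->...d", coeff[..., _TERM_INV], d)
    return p[..., 0], p[..., 1]


def term_stress_contributions(
    lam_ax, lam_cir, weights: TermWeights, mask: ModelSpec | None = None,
    two_fiber_families: bool = True, exp_clamp: float | None = None,
) -> np.ndarray:
    """Per-term additive stress contributions, shape (..., 2, 16).

    Summing over the last axis reproduces ``predict_stress``; used for the
    active-term bookkeeping of model discovery.
    """
    alpha = weights.fiber.alpha_rad
    x4 = shifted_invariants(lam_ax, lam_cir, alpha)
    m = mask.mask_array() if mask is not None else None
    d = term_stress_factors(x4, weights.w_star, weights.w, m, exp_clamp)
    coeff = stress_coefficients(lam_ax, lam_cir, alpha, two_fiber_families)
    return coeff[..., _TERM_INV] * d[..., None, :]


# ---------------------------------------------------------------------------
# classical-model weight dictionaries
# ---------------------------------------------------------------------------

def map_hgo_weights_to_parameters(weights: TermWeights) -> HgoParameters:
    """c1 = 2 w1* w1,  k1 = 2 w12* w12,  k2 = w12*.

    A vanishing inner weight w12* makes the fiber term degenerate (the
    exponential collapses to a constant); reported as k1 = k2 = 0.
    """
    w_star, w = weights.w_star, weights.w
    c1 = 2.0 * w_star[0] * w[0]
    if w_star[11] == 0.0:
        k1 = k2 = 0.0
    else:
        k1 = 2.0 * w_star[11] * w[11]
        k2 = w_star[11]
    return HgoParameters(c1=c1, k1=k1, k2=k2, alpha_deg=weights.fiber.alpha_deg)


def map_hgo_parameters_to_weights(params: HgoParameters, mode: str = "fixed") -> TermWeights:
    """Inverse dictionary; w1* is unidentifiable and pinned to 1."""
    if params.k2 <= 0 and params.k1 > 0:
        raise ValueError("k2 must be positive when k1 > 0")
    w_star = np.zeros(N_TERMS)
    w = np.zeros(N_TERMS)
    w_star[0] = 1.0
    w[0] = params.c1 / 2.0
    if params.k1 > 0:
        w_star[11] = params.k2
        w[11] = params.k1 / (2.0 * params.k2)
    return TermWeights(w_star, w, FiberOrientation(params.alpha_deg, mode))


def map_reduced_weights_to_parameters(weights: TermWeights) -> ReducedParameters:
    """a1 = w2 (kPa), a2 = w2* (dimensionless), b = w15* w15 (kPa)."""
    return ReducedParameters(
        a1=weights.w[1],
        a2=weights.w_star[1],
        b=weights.w_star[14] * weights.w[14],
        alpha_deg=weights.fiber.alpha_deg,
    )


def map_reduced_parameters_to_weights(params: ReducedParameters, mode: str = "fixed") -> TermWeights:
    """Inverse dictionary; the (w15*, w15) split is unidentifiable, w15* = 1."""
    w_star = np.zeros(N_TERMS)
    w = np.zeros(N_TERMS)
    w_star[1] = params.a2
    w[1] = params.a1
    w_star[14] = 1.0
    w[14] = params.b
    return TermWeights(w_star, w, FiberOrientation(params.alpha_deg, mode))


# ---------------------------------------------------------------------------
# model file I/O
# ---------------------------------------------------------------------------

def save_model(
    path: str | Path,
    weights: TermWeights,
    spec: ModelSpec,
    two_fiber_families: bool = True,
) -> None:
    """Write a model as a structured JSON file (weights in kPa, angle in deg)."""
    payload = {
        "variant": spec.variant,
        "active_mask": list(spec.active_mask),
        "w_star": weights.w_star.tolist(),
        "w_kPa": weights.w.tolist(),
        "alpha_deg": weights.fiber.alpha_deg,
        "fiber_mode": weights.fiber.mode,
        "two_fiber_families": bool(two_fiber_families),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path):
    """Read a model file; returns (TermWeights, ModelSpec, two_fiber_families)."""
    payload = json.loads(Path(path).read_text())
    spec = ModelSpec(tuple(payload["active_mask"]), payload.get("variant", "custom"))
    fiber = FiberOrientation(payload["alpha_deg"], payload.get("fiber_mode", "fixed"))
    weights = TermWeights(payload["w_star"], payload["w_kPa"], fiber)
    return weights, spec, bool(payload.get("two_fiber_families", True))
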