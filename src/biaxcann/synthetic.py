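"""Synthetic planar-biaxial cohorts emulating an ovine pulmonary-artery study.

The generator reproduces the statistical structure of a displacement-driven
biaxial protocol on n = 8 artery patches: three actuator stretch ratios
(axial:circumferential 2:1, 1:1, 1:2), two measured directions, engineering
stresses in kPa, a preload of about 5 kPa at the recorded curve origin,
sample-to-sample heterogeneity, and multiplicative measurement noise.

Ground truth is any model of the 16-term network; the default is the reduced
two-term artery model (exponential I1 term + quadratic I5 term) at a fiber
angle of 70 degrees, with magnitudes in the range reported for real pulmonary
tissue.  Heterogeneity multiplies each sample's identifiable weight products
by a lognormal factor while keeping the active-term set shared across the
cohort — the regime that cross-sample feature selection assumes.

Actuator stretches map to tissue stretches through a constant gain
(``dic_slip``): strain localizes in the imaged central region of the sample,
so tissue strains exceed the nominal actuator strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kinematics import FiberOrientation
from .model import (
    ModelSpec,
    TermWeights,
    map_reduced_parameters_to_weights,
    predict_stress,
)

__all__ = [
    "RATIOS",
    "CurveBlock",
    "BiaxialSample",
    "GroundTruth",
    "SyntheticConfig",
    "default_ground_truth",
    "generate_sample",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
]

RATIOS = ("2:1", "1:1", "1:2")
# fraction of the maximum actuator strain applied per direction
_RATIO_FRACTIONS = {"2:1": (1.0, 0.5), "1:1": (1.0, 1.0), "1:2": (0.5, 1.0)}

_COLUMNS = [
    "sample_id", "animal_id", "location", "ratio",
    "lambda_ax", "lambda_cir", "P_ax_kPa", "P_circ_kPa",
]


class DatasetError(ValueError):
    """Raised for malformed or incomplete curve files."""


@dataclass
class CurveBlock:
    """One (ratio) block of stretch/stress curves, monotone in actuator stretch."""

    lambda_ax: np.ndarray
    lambda_cir: np.ndarray
    P_ax: np.ndarray
    P_cir: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lambda_ax", "lambda_cir", "P_ax", "P_cir"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.lambda_ax)
        if not all(len(getattr(self, f)) == n for f in ("lambda_cir", "P_ax", "P_cir")):
            raise DatasetError("curve arrays must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.lambda_ax)


@dataclass
class BiaxialSample:
    """Per-sample biaxial curves, one block per actuator ratio.

    ``truth_weights`` carries the (jittered) generating model when the sample
    is synthetic; it is metadata for recovery studies and is not serialized.
    """

    sample_id: str
    curves: dict
    animal_id: str = ""
    location: str = ""
    truth_weights: object = None

    def __post_init__(self) -> None:
        missing = [r for r in RATIOS if r not in self.curves]
        if missing:
            raise DatasetError(
                f"sample {self.sample_id!r} is missing ratio block(s) {missing}"
            )

    def block(self, ratio: str) -> CurveBlock:
        return self.curves[ratio]

    def max_stress(self, ratio: str | None = None, direction: str | None = None) -> float:
        """Maximum observed engineering stress, optionally per block."""
        ratios = [ratio] if ratio is not None else list(RATIOS)
        vals = []
        for r in ratios:
            b = self.curves[r]
            if direction in (None, "ax"):
                vals.append(np.max(np.abs(b.P_ax)))
            if direction in (None, "circ"):
                vals.append(np.max(np.abs(b.P_cir)))
        return float(max(vals))

    @property
    def n_points(self) -> int:
        return sum(b.n_points for b in self.curves.values())


@dataclass
class GroundTruth:
    """Generating model for synthetic cohorts."""

    weights: TermWeights
    spec: ModelSpec
    two_fiber_families: bool = True


def default_ground_truth() -> GroundTruth:
    """Reduced two-term truth at alpha = 70 deg with artery-scale magnitudes.

    The cohort generator shares one truth across samples and jitters only the
    per-sample magnitudes, so its defaults follow the cohort-level (combined)
    reduced fit of pulmonary-artery biaxial data: a1 = 8.48 kPa, a2 = 0.424,
    b = 0.222 * 0.112 kPa.  This gives peak stresses of a few tens of kPa at
    ~50% tissue strain with a clearly exponential isotropic response.
    """
    from .model import ReducedParameters

    params = ReducedParameters(a1=8.48, a2=0.424, b=0.222 * 0.112, alpha_deg=70.0)
    weights = map_reduced_parameters_to_weights(params)
    return GroundTruth(weights=weights, spec=ModelSpec.reduced())


@dataclass
class SyntheticConfig:
    """Cohort-generation settings; defaults emulate the study protocol."""

    ground_truth: GroundTruth = field(default_factory=default_ground_truth)
    n_samples: int = 8
    points_per_ratio: int = 15
    max_actuator_stretch: float = 1.30
    ratios: tuple = RATIOS
    noise_sd: float = 0.03  # multiplicative lognormal sigma on stresses
    heterogeneity_sd: float = 0.2  # per-sample lognormal sigma on weight products
    preload_stress: float = 5.0  # kPa at the recorded curve origin
    dic_slip: float = 1.7  # tissue strain per unit actuator strain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.heterogeneity_sd < 0:
            raise ValueError("noise and heterogeneity sigmas must be non-negative")
        bad = [r for r in self.ratios if r not in _RATIO_FRACTIONS]
        if bad:
            raise DatasetError(f"unknown ratio spec(s): {bad}")
        if self.points_per_ratio < 2:
            raise ValueError("need at least 2 points per ratio")


def _tissue_stretch(actuator: np.ndarray, dic_slip: float) -> np.ndarray:
    return 1.0 + dic_slip * (actuator - 1.0)


def _jittered_weights(truth: GroundTruth, rng: np.random.Generator, sigma: float) -> TermWeights:
    """Per-sample lognormal jitter on the identifiable products (outer weights)."""
    w = truth.weights.w.copy()
    mask = truth.spec.mask_array().astype(bool)
    if sigma > 0:
        w[mask] *= rng.lognormal(mean=0.0, sigma=sigma, size=int(mask.sum()))
    return TermWeights(truth.weights.w_star, w, truth.weights.fiber)


def _preload_offset(
    weights: TermWeights, truth: GroundTruth, cfg: SyntheticConfig
) -> float:
    """Actuator stretch on the 1:1 path where mean true stress hits the preload.

    The study re-zeroes its curves at a small tensile preload reached along a
    1:1 actuator offset that is shared by all three ratios; the synthetic
    analog starts every recorded curve at that crossing.  Returns 1.0 when the
    preload is zero or never reached.
    """
    if cfg.preload_stress <= 0:
        return 1.0

    def mean_stress(act: float) -> float:
        lam = _tissue_stretch(np.asarray([act]), cfg.dic_slip)
        p_ax, p_cir = predict_stress(
            lam, lam, weights, truth.spec, truth.two_fiber_families,
            warn_reference_stress=False,
        )
        return 0.5 * float(p_ax[0] + p_cir[0])

    lo, hi = 1.0, cfg.max_actuator_stretch
    if mean_stress(hi) <= cfg.preload_stress:
        return 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_stress(mid) < cfg.preload_stress:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_sample(config: SyntheticConfig, sample_index: int) -> BiaxialSample:
    """Generate one synthetic biaxial sample (deterministic in (seed, index))."""
    if not 0 <= sample_index:
        raise ValueError("sample_index must be non-negative")
    rng = np.random.default_rng([config.seed, sample_index])
    truth = config.ground_truth
    weights = _jittered_weights(truth, rng, config.heterogeneity_sd)
    act_start = _preload_offset(weights, truth, config)

    curves: dict[str, CurveBlock] = {}
    strain_max = config.max_actuator_stretch - 1.0
    for ratio in config.ratios:
        f_ax, f_cir = _RATIO_FRACTIONS[ratio]
        t = np.linspace(0.0, 1.0, config.points_per_ratio)
        act_ax = act_start + t * (1.0 + f_ax * strain_max - act_start)
        act_cir = act_start + t * (1.0 + f_cir * strain_max - act_start)
        lam_ax = _tissue_stretch(act_ax, config.dic_slip)
        lam_cir = _tissue_stretch(act_cir, config.dic_slip)
        p_ax, p_cir = predict_stress(
            lam_ax, lam_cir, weights, truth.spec, truth.two_fiber_families,
            warn_reference_stress=False,
        )
        if config.noise_sd > 0:
            p_ax = p_ax * rng.lognormal(0.0, config.noise_sd, size=p_ax.shape)
            p_cir = p_cir * rng.lognormal(0.0, config.noise_sd, size=p_cir.shape)
        curves[ratio] = CurveBlock(lam_ax, lam_cir, p_ax, p_cir)

    animal = f"A{sample_index // 2 + 1}"
    location = "A" if sample_index % 2 == 0 else "B"
    return BiaxialSample(
        sample_id=f"S{sample_index + 1}", curves=curves,
        animal_id=animal, location=location, truth_weights=weights,
    )


def generate_cohort(config: SyntheticConfig) -> list:
    """n independent samples sharing the truth, with per-sample jitter."""
    if config.n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    return [generate_sample(config, i) for i in range(config.n_samples)]


# ---------------------------------------------------------------------------
# curve file I/O (CSV, one row per loading point)
# ---------------------------------------------------------------------------

def write_dataset(cohort: Iterable[BiaxialSample], path: str | Path) -> None:
    rows = []
    for sample in cohort:
        for ratio, b in sample.curves.items():
            for i in range(b.n_points):
                rows.append(
                    (sample.sample_id, sample.animal_id, sample.location, ratio,
                     b.lambda_ax[i], b.lambda_cir[i], b.P_ax[i], b.P_cir[i])
                )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> list:
    """Read and validate a curve file; returns the cohort as a sample list."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise DatasetError(f"malformed curve file {path}: {exc}") from exc
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"curve file {path} is missing columns {missing_cols}")
    numeric = ["lambda_ax", "lambda_cir", "P_ax_kPa", "P_circ_kPa"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise DatasetError(
                f"non-numeric value in column {col!r} at file line {bad[0] + 2}"
            )
        df[col] = vals
    if (df[["P_ax_kPa", "P_circ_kPa"]] < 0).any().any():
        row = int(df.index[(df[["P_ax_kPa", "P_circ_kPa"]] < 0).any(axis=1)][0])
        raise DatasetError(f"negative stress value at file line {row + 2}")

    cohort = []
    for sample_id, g in df.groupby("sample_id", sort=False):
        curves = {}
        for ratio, gr in g.groupby("ratio", sort=False):
            curves[str(ratio)] = CurveBlock(
                gr["lambda_ax"].to_numpy(), gr["lambda_cir"].to_numpy(),
                gr["P_ax_kPa"].to_numpy(), gr["P_circ_kPa"].to_numpy(),
            )
        cohort.append(
            BiaxialSample(
                sample_id=str(sample_id), curves=curves,
                animal_id=str(g["animal_id"].iloc[0]),
                location=str(g["location"].iloc[0]),
            )
        )
    return cohort
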