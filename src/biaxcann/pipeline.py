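"""Orchestration of the model-discovery experiments.

Four building blocks, mirroring the study design the package emulates:

* :func:`discover_sample` — fit the full 16-term network to one sample under
  one of four regimes (L1 regularization off/on x fiber angle fixed/fitted).
* :func:`cross_sample_discovery` — fit one weight set against a whole cohort
  (each sample normalized by its own block maxima) to select a universal
  active-term set, with an optional second pass that freezes that set and
  refits per-sample magnitudes.
* :func:`fixed_angle_sweep` — train one network per (sample, fixed angle)
  over an 11-angle grid and aggregate term-prevalence histograms and per-cell
  mean R^2.
* :func:`compare_reduced_vs_hgo` — fit the reduced two-term model and the
  constrained HGO model per (sample, fixed angle) and compare their mean R^2
  heat maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import FiberOrientation
from .model import ModelSpec, N_TERMS, TERM_TABLE, TermWeights
from .synthetic import BiaxialSample, RATIOS
from .training import (
    ANGLE_GRID_DEG,
    FitResult,
    LossConfig,
    OptimizerConfig,
    active_terms,
    train,
)

__all__ = [
    "DiscoveryRegime",
    "TermPrevalence",
    "SweepResult",
    "CrossSampleResult",
    "ModelComparison",
    "discover_sample",
    "cross_sample_discovery",
    "fixed_angle_sweep",
    "compare_reduced_vs_hgo",
]

SAMPLE_ALPHA_REG = 0.01
CROSS_SAMPLE_ALPHA_REG = 0.001


@dataclass(frozen=True)
class DiscoveryRegime:
    """One of the four learning variations: {off, l1} x {fixed, fitted}."""

    regularization: str = "off"  # off | l1
    angle_mode: str = "fixed"  # fixed | fitted
    fixed_angle_deg: float | None = 70.0

    def __post_init__(self) -> None:
        if self.regularization not in ("off", "l1"):
            raise ValueError("regularization must be 'off' or 'l1'")
        if self.angle_mode not in ("fixed", "fitted"):
            raise ValueError("angle_mode must be 'fixed' or 'fitted'")
        if self.angle_mode == "fixed" and self.fixed_angle_deg is None:
            raise ValueError("fixed angle_mode requires fixed_angle_deg")

    def fiber(self) -> FiberOrientation:
        if self.angle_mode == "fixed":
            return FiberOrientation(self.fixed_angle_deg, "fixed")
        init = self.fixed_angle_deg if self.fixed_angle_deg is not None else 70.0
        return FiberOrientation(init, "fitted")


@dataclass
class TermPrevalence:
    """Counts of runs in which each term was active, over a sweep grid."""

    counts: np.ndarray  # (16,)
    n_runs: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.index for t in TERM_TABLE],
                "label": [t.label for t in TERM_TABLE],
                "count": self.counts.astype(int),
                "fraction": self.counts / max(self.n_runs, 1),
            }
        )


@dataclass
class SweepResult:
    """Grid of fits keyed by (sample_id, angle) plus aggregates."""

    fits: dict
    failures: dict
    prevalence: TermPrevalence
    mean_r2: pd.DataFrame  # rows: sample_id, cols: angle
    scheduled_runs: int


@dataclass
class CrossSampleResult:
    cohort_fit: FitResult
    universal_terms: tuple
    per_sample_fits: list


@dataclass
class ModelComparison:
    r2_reduced: pd.DataFrame
    r2_hgo: pd.DataFrame

    @property
    def difference(self) -> pd.DataFrame:
        return self.r2_reduced - self.r2_hgo


def _mean_r2(fit: FitResult) -> float:
    """Cell statistic: R^2 averaged over direction x ratio blocks."""
    vals = [
        v for k, v in fit.r2.items()
        if v is not None and len(k) >= 2 and k[-1] in RATIOS
    ]
    return float(np.mean(vals)) if vals else float("nan")


def discover_sample(
    sample: BiaxialSample,
    regime: DiscoveryRegime,
    opt_cfg: OptimizerConfig | None = None,
    alpha_reg: float | None = None,
    two_fiber_families: bool = True,
) -> FitResult:
    """Full-network model discovery for a single sample under one regime."""
    if alpha_reg is None:
        alpha_reg = SAMPLE_ALPHA_REG if regime.regularization == "l1" else 0.0
    loss_cfg = LossConfig(mode="sample", alpha_reg=alpha_reg)
    return train(
        ModelSpec.full(), sample, loss_cfg, opt_cfg, regime.fiber(),
        two_fiber_families,
    )


def cross_sample_discovery(
    cohort,
    regularization: str = "l1",
    fixed_angle_deg: float = 70.0,
    opt_cfg: OptimizerConfig | None = None,
    alpha_reg: float | None = None,
    refit_per_sample: bool = True,
    two_fiber_families: bool = True,
) -> CrossSampleResult:
    """One weight set for all samples, then per-sample refits on the
    universal active-term set."""
    cohort = list(cohort)
    if len(cohort) < 1:
        raise ValueError("cohort must contain at least one sample")
    if alpha_reg is None:
        alpha_reg = CROSS_SAMPLE_ALPHA_REG if regularization == "l1" else 0.0
    loss_cfg = LossConfig(mode="cross_sample", alpha_reg=alpha_reg)
    fiber = FiberOrientation(fixed_angle_deg, "fixed")
    fit = train(ModelSpec.full(), cohort, loss_cfg, opt_cfg, fiber, two_fiber_families)
    universal = fit.active_terms

    per_sample = []
    if refit_per_sample and universal:
        frozen = ModelSpec.from_indices(universal, "custom")
        for s in cohort:
            per_sample.append(
                train(
                    frozen, s, LossConfig(mode="sample", alpha_reg=0.0),
                    opt_cfg, fiber, two_fiber_families,
                )
            )
    return CrossSampleResult(
        cohort_fit=fit, universal_terms=universal, per_sample_fits=per_sample
    )


def fixed_angle_sweep(
    cohort,
    angle_grid=None,
    regularization: str = "off",
    opt_cfg: OptimizerConfig | None = None,
    alpha_reg: float | None = None,
    two_fiber_families: bool = True,
    cache_dir: str | Path | None = None,
) -> SweepResult:
    """One full-network fit per (sample, fixed angle); aggregates prevalence."""
    cohort = list(cohort)
    angle_grid = list(ANGLE_GRID_DEG if angle_grid is None else angle_grid)
    if not angle_grid:
        raise ValueError("angle grid must be non-empty")
    if alpha_reg is None:
        alpha_reg = SAMPLE_ALPHA_REG if regularization == "l1" else 0.0
    loss_cfg = LossConfig(mode="sample", alpha_reg=alpha_reg)
    opt_cfg = opt_cfg or OptimizerConfig()

    fits: dict = {}
    failures: dict = {}
    counts = np.zeros(N_TERMS)
    r2_grid = pd.DataFrame(
        index=[s.sample_id for s in cohort], columns=angle_grid, dtype=float
    )
    for s in cohort:
        for angle in angle_grid:
            key = (s.sample_id, angle)
            try:
                fit = _cached_fit(
                    ModelSpec.full(), s, loss_cfg, opt_cfg,
                    FiberOrientation(angle, "fixed"), two_fiber_families, cache_dir,
                )
            except Exception as exc:  # failed cells recorded, not fatal
                failures[key] = repr(exc)
                continue
            fits[key] = fit
            for t in fit.active_terms:
                counts[t - 1] += 1
            r2_grid.loc[s.sample_id, angle] = _mean_r2(fit)

    scheduled = len(cohort) * len(angle_grid)
    return SweepResult(
        fits=fits, failures=failures,
        prevalence=TermPrevalence(counts=counts, n_runs=scheduled),
        mean_r2=r2_grid, scheduled_runs=scheduled,
    )


def compare_reduced_vs_hgo(
    cohort,
    angle_grid=None,
    opt_cfg: OptimizerConfig | None = None,
    two_fiber_families: bool = True,
    cache_dir: str | Path | None = None,
) -> ModelComparison:
    """Per-cell mean R^2 of the reduced and HGO variants over the angle grid."""
    cohort = list(cohort)
    angle_grid = list(ANGLE_GRID_DEG if angle_grid is None else angle_grid)
    if not angle_grid:
        raise ValueError("angle grid must be non-empty")
    opt_cfg = opt_cfg or OptimizerConfig()
    loss_cfg = LossConfig(mode="sample", alpha_reg=0.0)

    grids = {}
    for name, spec in (("reduced", ModelSpec.reduced()), ("hgo", ModelSpec.hgo())):
        grid = pd.DataFrame(
            index=[s.sample_id for s in cohort], columns=angle_grid, dtype=float
        )
        for s in cohort:
            for angle in angle_grid:
                fit = _cached_fit(
                    spec, s, loss_cfg, opt_cfg,
                    FiberOrientation(angle, "fixed"), two_fiber_families, cache_dir,
                )
                grid.loc[s.sample_id, angle] = _mean_r2(fit)
        grids[name] = grid
    return ModelComparison(r2_reduced=grids["reduced"], r2_hgo=grids["hgo"])


# ---------------------------------------------------------------------------
# content-hash fit cache (resumable sweeps)
# ---------------------------------------------------------------------------

def _cache_key(spec, sample, loss_cfg, opt_cfg, fiber, two_fib) -> str:
    payload = {
        "mask": list(spec.active_mask),
        "sample": {
            r: [b.lambda_ax.tolist(), b.lambda_cir.tolist(),
                b.P_ax.tolist(), b.P_cir.tolist()]
            for r, b in sorted(sample.curves.items())
        },
        "loss": [loss_cfg.mode, loss_cfg.alpha_reg],
        "opt": [opt_cfg.epochs, opt_cfg.batch_size, opt_cfg.patience,
                opt_cfg.learning_rate, opt_cfg.seed, opt_cfg.min_delta,
                opt_cfg.exp_clamp, list(opt_cfg.angle_grid)],
        "fiber": [fiber.alpha_deg, fiber.mode],
        "two_fib": two_fib,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _cached_fit(spec, sample, loss_cfg, opt_cfg, fiber, two_fib, cache_dir):
    if cache_dir is None:
        return train(spec, sample, loss_cfg, opt_cfg, fiber, two_fib)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{_cache_key(spec, sample, loss_cfg, opt_cfg, fiber, two_fib)}.json"
    if path.exists():
        return _fit_from_json(json.loads(path.read_text()), spec, loss_cfg)
    fit = train(spec, sample, loss_cfg, opt_cfg, fiber, two_fib)
    path.write_text(json.dumps(_fit_to_json(fit)))
    return fit


def _fit_to_json(fit: FitResult) -> dict:
    return {
        "w_star": fit.weights.w_star.tolist(),
        "w": fit.weights.w.tolist(),
        "alpha_deg": fit.weights.fiber.alpha_deg,
        "fiber_mode": fit.weights.fiber.mode,
        "final_loss": fit.final_loss,
        "r2": [[list(k), v] for k, v in fit.r2.items()],
        "active_terms": list(fit.active_terms),
        "n_epochs": fit.n_epochs,
        "fitted_alpha_deg": fit.fitted_alpha_deg,
    }


def _fit_from_json(payload: dict, spec: ModelSpec, loss_cfg: LossConfig) -> FitResult:
    weights = TermWeights(
        payload["w_star"], payload["w"],
        FiberOrientation(payload["alpha_deg"], payload["fiber_mode"]),
    )
    return FitResult(
        weights=weights, spec=spec, final_loss=payload["final_loss"],
        loss_trace=np.asarray([]),
        r2={tuple(k): v for k, v in payload["r2"]},
        active_terms=tuple(payload["active_terms"]),
        n_epochs=payload["n_epochs"],
        fitted_alpha_deg=payload["fitted_alpha_deg"],
        loss_config=loss_cfg,
    )
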