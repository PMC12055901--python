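"""Weighted least-squares training of the strain-energy network with Adam.

The loss is the mean squared normalized stress residual over all loading
points of a sample, plus an optional L1 penalty on all 32 weights:

    L = (1/n) sum_i || (P(F_i, w) - P_hat_i) / P_max(block_i) ||^2
        + alpha_reg * sum_t (|w*_t| + |w_t|)

where the normalizer is the maximum observed engineering stress of the
point's (ratio, direction) block — and additionally per sample in
cross-sample mode, where the per-sample means are summed over samples.  The
residual norm is the plain Euclidean norm of the two-direction stress vector.

Because the biaxial stresses are closed-form linear combinations of per-term
stress factors, the loss gradient w.r.t. every weight is analytic; only the
fitted fiber angle (a single scalar that enters through cos^2/sin^2 and the
anisotropic invariants) is differentiated by central differences.  Adam with
projection (clipping at zero after each update) enforces the non-negativity
constraint and keeps exact zeros reachable, which is what makes the L1
penalty an effective feature selector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinematics import FiberOrientation, normalize_angle_deg, stress_coefficients
from .model import (
    ModelSpec,
    N_TERMS,
    TermWeights,
    _TERM_EXP,
    _TERM_INV,
    shifted_invariants,
    term_stress_factor_weight_grads,
    term_stress_factors,
)
from .synthetic import RATIOS, BiaxialSample

__all__ = [
    "LossConfig",
    "OptimizerConfig",
    "TrainingData",
    "FitResult",
    "normalizers",
    "loss",
    "train",
    "r_squared",
    "fit_r2_table",
    "active_terms",
    "ANGLE_GRID_DEG",
]

ANGLE_GRID_DEG = (0.0, 10.0, 20.0, 30.0, 40.0, 45.0, 50.0, 60.0, 70.0, 80.0, 90.0)

DIRECTIONS = ("ax", "circ")


@dataclass(frozen=True)
class LossConfig:
    """Loss mode and L1 strength (0.01 sample-mode, 0.001 cross-sample)."""

    mode: str = "sample"  # sample | cross_sample
    alpha_reg: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("sample", "cross_sample"):
            raise ValueError(f"unknown loss mode {self.mode!r}")
        if self.alpha_reg < 0:
            raise ValueError("alpha_reg must be non-negative")


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam protocol: epochs, mini-batch size, patience, init, seed.

    The reference protocol is 8000 epochs at batch size 32 with early stopping
    after 2000 epochs without improvement; identity-term weights start from
    the magnitude of a Glorot-normal draw and exponential-term weights from
    U[0.0001, 0.1].  ``angle_grid`` seeds the multi-start used for fitted
    fiber angles.
    """

    epochs: int = 8000
    batch_size: int = 32
    patience: int = 2000
    learning_rate: float = 0.001
    seed: int = 0
    min_delta: float = 1e-8
    exp_clamp: float = 50.0
    angle_grid: tuple = ANGLE_GRID_DEG
    lr_decay: float = 1.0  # cosine-anneal the rate to lr * lr_decay by the last epoch
    # Adam's per-coordinate normalization moves the angle by ~lr radians per
    # step regardless of its gradient scale; a scale < 1 lets the angle evolve
    # quasi-statically against the conditionally converging weights.
    angle_lr_scale: float = 0.1
    # Fitted-angle runs hold the angle at its multi-start value for this
    # fraction of the epochs so the weights first reach their conditional
    # optimum; releasing the angle afterwards turns each start into a local
    # refinement around its grid angle instead of a race between coordinates.
    angle_warmup_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingData:
    """Flattened loading points with per-point normalizers and loss weights."""

    lam_ax: np.ndarray  # (n,)
    lam_cir: np.ndarray  # (n,)
    p_obs: np.ndarray  # (n, 2) observed (P_ax, P_cir), kPa
    norm: np.ndarray  # (n, 2) block max-stress normalizers, kPa
    point_weight: np.ndarray  # (n,) 1/n_points of the point's sample
    sample_ids: np.ndarray  # (n,) object
    ratios: np.ndarray  # (n,) object
    sample_max: np.ndarray  # (n,) sample-wide max observed stress, kPa
    n_samples: int = 1

    @property
    def n_points(self) -> int:
        return len(self.lam_ax)


def normalizers(data, mode: str = "sample") -> dict:
    """Max engineering stress per (ratio, direction) block.

    Sample mode expects a single sample and keys blocks as
    ``(ratio, direction)``; cross-sample mode expects a cohort and keys them
    as ``(sample_id, ratio, direction)``.  An all-zero block has no scale to
    normalize by and raises.
    """
    samples = [data] if isinstance(data, BiaxialSample) else list(data)
    if mode == "sample" and len(samples) != 1:
        raise ValueError("sample mode expects exactly one sample")
    table: dict = {}
    for s in samples:
        for ratio, b in s.curves.items():
            for direction, arr in (("ax", b.P_ax), ("circ", b.P_cir)):
                m = float(np.max(np.abs(arr)))
                if m <= 0.0:
                    raise ValueError(
                        f"all-zero stress block ({s.sample_id}, {ratio}, {direction})"
                    )
                key = (ratio, direction) if mode == "sample" else (s.sample_id, ratio, direction)
                table[key] = m
    return table


def build_training_data(data, mode: str = "sample") -> TrainingData:
    """Flatten a sample or cohort into point arrays for the optimizer."""
    samples = [data] if isinstance(data, BiaxialSample) else list(data)
    if mode == "sample" and len(samples) != 1:
        raise ValueError("sample mode expects exactly one sample")
    norm_table = normalizers(samples[0] if mode == "sample" else samples, mode)

    lam1, lam2, pobs, norm, pw, sids, rats, smax = [], [], [], [], [], [], [], []
    for s in samples:
        n_s = s.n_points
        s_max = s.max_stress()
        for ratio, b in s.curves.items():
            key_ax = (ratio, "ax") if mode == "sample" else (s.sample_id, ratio, "ax")
            key_ci = (ratio, "circ") if mode == "sample" else (s.sample_id, ratio, "circ")
            for i in range(b.n_points):
                lam1.append(b.lambda_ax[i])
                lam2.append(b.lambda_cir[i])
                pobs.append((b.P_ax[i], b.P_cir[i]))
                norm.append((norm_table[key_ax], norm_table[key_ci]))
                pw.append(1.0 / n_s)
                sids.append(s.sample_id)
                rats.append(ratio)
                smax.append(s_max)
    return TrainingData(
        lam_ax=np.asarray(lam1), lam_cir=np.asarray(lam2),
        p_obs=np.asarray(pobs), norm=np.asarray(norm),
        point_weight=np.asarray(pw),
        sample_ids=np.asarray(sids, dtype=object),
        ratios=np.asarray(rats, dtype=object),
        sample_max=np.asarray(smax),
        n_samples=len(samples),
    )


# ---------------------------------------------------------------------------
# loss and gradients
# ---------------------------------------------------------------------------

def _forward(td: TrainingData, w_star, w, mask_arr, alpha_rad, two_fib, exp_clamp):
    """Predicted stresses plus the intermediates needed for the gradient."""
    x4 = shifted_invariants(td.lam_ax, td.lam_cir, alpha_rad)  # (n, 4)
    coeff = stress_coefficients(td.lam_ax, td.lam_cir, alpha_rad, two_fib)  # (n, 2, 4)
    coeff_t = coeff[..., _TERM_INV]  # (n, 2, 16)
    d = term_stress_factors(x4, w_star, w, mask_arr, exp_clamp)  # (n, 16)
    p = np.einsum("ndt,nt->nd", coeff_t, d)
    return p, x4, coeff_t


def _data_loss(td: TrainingData, p_pred: np.ndarray) -> float:
    r = (p_pred - td.p_obs) / td.norm
    return float(np.sum(td.point_weight * np.sum(r * r, axis=1)))


def loss(
    weights: TermWeights,
    data,
    config: LossConfig,
    spec: ModelSpec | None = None,
    two_fiber_families: bool = True,
    exp_clamp: float | None = None,
) -> float:
    """Full-data loss for a sample (mode 'sample') or cohort ('cross_sample')."""
    td = data if isinstance(data, TrainingData) else build_training_data(data, config.mode)
    mask_arr = spec.mask_array() if spec is not None else None
    with np.errstate(over="ignore", invalid="ignore"):
        p, _, _ = _forward(
            td, weights.w_star, weights.w, mask_arr,
            weights.fiber.alpha_rad, two_fiber_families, exp_clamp,
        )
        value = _data_loss(td, p)
    l1 = np.sum(np.abs(weights.w_star) + np.abs(weights.w))
    return value + config.alpha_reg * float(l1)


def _loss_and_grads(td, w_star, w, mask_arr, alpha_rad, two_fib, cfg, scale, exp_clamp,
                    fitted_angle):
    """Batch loss gradient w.r.t. (w*, w) analytically and alpha by FD."""
    p, x4, coeff_t = _forward(td, w_star, w, mask_arr, alpha_rad, two_fib, exp_clamp)
    r = (p - td.p_obs) / td.norm  # (n, 2)
    # d(data loss)/d(stress factor of term t) summed over directions
    dl_dd = np.einsum("nd,ndt->nt", 2.0 * td.point_weight[:, None] * r / td.norm, coeff_t)
    g_ws, g_w = term_stress_factor_weight_grads(x4, w_star, w, mask_arr, exp_clamp)
    grad_ws = scale * np.sum(dl_dd * g_ws, axis=0)
    grad_w = scale * np.sum(dl_dd * g_w, axis=0)
    if cfg.alpha_reg > 0 and mask_arr is not None:
        grad_ws = grad_ws + cfg.alpha_reg * mask_arr
        grad_w = grad_w + cfg.alpha_reg * mask_arr
    elif cfg.alpha_reg > 0:
        grad_ws = grad_ws + cfg.alpha_reg
        grad_w = grad_w + cfg.alpha_reg

    grad_alpha = 0.0
    if fitted_angle:
        h = 1e-4
        for sgn in (+1.0, -1.0):
            ph, _, _ = _forward(td, w_star, w, mask_arr, alpha_rad + sgn * h, two_fib, exp_clamp)
            grad_alpha += sgn * _data_loss(td, ph)
        grad_alpha = scale * grad_alpha / (2.0 * h)
    batch_loss = scale * _data_loss(td, p)
    return batch_loss, grad_ws, grad_w, grad_alpha


def _batch_view(td: TrainingData, idx: np.ndarray) -> TrainingData:
    return TrainingData(
        lam_ax=td.lam_ax[idx], lam_cir=td.lam_cir[idx],
        p_obs=td.p_obs[idx], norm=td.norm[idx],
        point_weight=td.point_weight[idx],
        sample_ids=td.sample_ids[idx], ratios=td.ratios[idx],
        sample_max=td.sample_max[idx], n_samples=td.n_samples,
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

# Exact zero in BOTH weights of a term is a spurious stationary point of the
# bilinear (w*, w) parameterization: the term's gradient vanishes and it can
# never revive.  A tiny floor on the inner weight removes that trap; sparsity
# still emerges through exact zeros of the outer weight, which alone switch a
# term off.
W_STAR_FLOOR = 1e-8


def initialize_weights(spec: ModelSpec, rng: np.random.Generator):
    """Glorot normal for identity terms, U[0.0001, 0.1] for exp terms.

    Glorot draws are signed; the non-negativity constraint clips them at zero
    immediately, so roughly half the identity weights start from zero (kept
    revivable by the inner-weight floor).
    """
    glorot_std = math.sqrt(2.0 / (N_TERMS + 1))  # 16-term layer into one energy output
    w_star = np.where(
        _TERM_EXP,
        rng.uniform(1e-4, 0.1, N_TERMS),
        np.maximum(rng.normal(0.0, glorot_std, N_TERMS), W_STAR_FLOOR),
    )
    w = np.where(
        _TERM_EXP,
        rng.uniform(1e-4, 0.1, N_TERMS),
        np.maximum(rng.normal(0.0, glorot_std, N_TERMS), 0.0),
    )
    m = spec.mask_array()
    return w_star * m, w * m


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Trained weights plus diagnostics of one fit."""

    weights: TermWeights
    spec: ModelSpec
    final_loss: float
    loss_trace: np.ndarray
    r2: dict
    active_terms: tuple
    n_epochs: int
    fitted_alpha_deg: float | None = None
    multi_start: list = field(default_factory=list)
    loss_config: LossConfig | None = None


def _train_single(
    spec, td, loss_cfg, opt_cfg, alpha0_deg, fitted_angle, two_fib, rng
):
    """One Adam run from one angle start; returns (loss, weights, trace, epochs)."""
    w_star, w = initialize_weights(spec, rng)
    mask_arr = spec.mask_array()
    alpha = math.radians(alpha0_deg)
    lr, b1, b2, eps = opt_cfg.learning_rate, 0.9, 0.999, 1e-8
    n_param = 2 * N_TERMS + (1 if fitted_angle else 0)
    m = np.zeros(n_param)
    v = np.zeros(n_param)
    step = 0

    n = td.n_points
    best_loss = np.inf
    best = (w_star.copy(), w.copy(), alpha)
    since_improve = 0
    trace = []
    bad_epochs = 0
    epochs_run = 0
    warmup_epochs = (
        int(opt_cfg.angle_warmup_frac * opt_cfg.epochs) if fitted_angle else 0
    )

    with np.errstate(over="ignore", invalid="ignore"):
        for epoch in range(opt_cfg.epochs):
            angle_active = fitted_angle and epoch >= warmup_epochs
            if fitted_angle and epoch == warmup_epochs:
                # angle released: restart the early-stopping bookkeeping so a
                # converged warm-up cannot stop the run before the polish
                best_loss = np.inf
                since_improve = 0
            if opt_cfg.lr_decay < 1.0:
                frac = epoch / max(opt_cfg.epochs - 1, 1)
                lo = opt_cfg.learning_rate * opt_cfg.lr_decay
                lr = lo + 0.5 * (opt_cfg.learning_rate - lo) * (1 + math.cos(math.pi * frac))
            order = rng.permutation(n)
            for start in range(0, n, opt_cfg.batch_size):
                idx = order[start:start + opt_cfg.batch_size]
                batch = _batch_view(td, idx)
                scale = n / len(idx)  # unbiased estimate of the full-data loss
                _, g_ws, g_w, g_a = _loss_and_grads(
                    batch, w_star, w, mask_arr, alpha, two_fib, loss_cfg,
                    scale, opt_cfg.exp_clamp, angle_active,
                )
                g = np.concatenate([g_ws, g_w, [g_a]] if fitted_angle else [g_ws, g_w])
                if not np.all(np.isfinite(g)):
                    continue  # reject the step, keep parameters
                step += 1
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                mh = m / (1 - b1**step)
                vh = v / (1 - b2**step)
                delta = lr * mh / (np.sqrt(vh) + eps)
                w_star = np.maximum(w_star - delta[:N_TERMS], W_STAR_FLOOR) * mask_arr
                w = np.maximum(w - delta[N_TERMS:2 * N_TERMS], 0.0) * mask_arr
                if angle_active:
                    alpha -= opt_cfg.angle_lr_scale * delta[-1]

            p, _, _ = _forward(td, w_star, w, mask_arr, alpha, two_fib, opt_cfg.exp_clamp)
            full = _data_loss(td, p) + loss_cfg.alpha_reg * float(np.sum(w_star + w))
            trace.append(full)
            epochs_run = epoch + 1
            if not np.isfinite(full):
                bad_epochs += 1
                if bad_epochs >= 10:
                    raise RuntimeError(
                        f"training diverged: non-finite loss for {bad_epochs} "
                        f"consecutive epochs (epoch {epoch + 1})"
                    )
            else:
                bad_epochs = 0
                if full < best_loss - opt_cfg.min_delta:
                    best_loss = full
                    best = (w_star.copy(), w.copy(), alpha)
                    since_improve = 0
                else:
                    since_improve += 1
            if since_improve >= opt_cfg.patience:
                break

    w_star, w, alpha = best
    return best_loss, w_star, w, alpha, np.asarray(trace), epochs_run


def train(
    spec: ModelSpec,
    data,
    loss_cfg: LossConfig | None = None,
    opt_cfg: OptimizerConfig | None = None,
    fiber: FiberOrientation | None = None,
    two_fiber_families: bool = True,
) -> FitResult:
    """Fit the (masked) network to a sample or cohort.

    ``fiber.mode == 'fitted'`` makes the angle trainable; the run is then
    multi-started from every angle in ``opt_cfg.angle_grid`` and the start
    with the lowest final loss wins (ties: lower L1 norm, then lower start
    index).  Fixed mode trains once at ``fiber.alpha_deg``.  Deterministic
    given ``opt_cfg.seed``.
    """
    loss_cfg = loss_cfg or LossConfig()
    opt_cfg = opt_cfg or OptimizerConfig()
    fiber = fiber or FiberOrientation(70.0, "fixed")
    td = data if isinstance(data, TrainingData) else build_training_data(data, loss_cfg.mode)
    if td.n_points == 0:
        raise ValueError("training data is empty")
    fitted = fiber.mode == "fitted"
    starts = list(opt_cfg.angle_grid) if fitted else [fiber.alpha_deg]

    outcomes = []
    for k, alpha0 in enumerate(starts):
        rng = np.random.default_rng([opt_cfg.seed, k])
        outcomes.append(
            _train_single(spec, td, loss_cfg, opt_cfg, alpha0, fitted,
                          two_fiber_families, rng)
        )
    ranked = sorted(
        range(len(outcomes)),
        key=lambda k: (outcomes[k][0], float(np.sum(outcomes[k][1] + outcomes[k][2])), k),
    )
    best_k = ranked[0]
    best_loss, w_star, w, alpha, trace, epochs_run = outcomes[best_k]

    alpha_deg = normalize_angle_deg(math.degrees(alpha))
    weights = TermWeights(w_star, w, FiberOrientation(alpha_deg, fiber.mode))
    samples = _as_samples(data, td)
    r2 = fit_r2_table(weights, samples, spec, two_fiber_families)
    act = active_terms(weights, td, spec, two_fiber_families)
    return FitResult(
        weights=weights, spec=spec, final_loss=float(best_loss),
        loss_trace=trace, r2=r2, active_terms=act, n_epochs=epochs_run,
        fitted_alpha_deg=alpha_deg if fitted else None,
        multi_start=[
            (starts[k], float(outcomes[k][0]),
             normalize_angle_deg(math.degrees(outcomes[k][3])))
            for k in range(len(starts))
        ],
        loss_config=loss_cfg,
    )


def _as_samples(data, td: TrainingData):
    if isinstance(data, BiaxialSample):
        return [data]
    if isinstance(data, TrainingData):
        return None
    return list(data)


# ---------------------------------------------------------------------------
# goodness of fit and active terms
# ---------------------------------------------------------------------------

def r_squared(predictions, observations, groups=None) -> dict:
    """Coefficient of determination per group (1 - SS_res / SS_tot).

    ``groups`` is an array of hashable labels; ``None`` pools everything
    under the key 'all'.  Groups with fewer than 2 points or zero variance
    have no defined R^2 and are reported as ``None``.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observations, dtype=float).ravel()
    if groups is None:
        groups = np.array(["all"] * len(obs), dtype=object)
    groups = np.asarray(groups, dtype=object).ravel()
    out = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        sel = groups == g
        o, p = obs[sel], pred[sel]
        ss_tot = float(np.sum((o - o.mean()) ** 2))
        if len(o) < 2 or ss_tot == 0.0:
            out[g] = None
            continue
        ss_res = float(np.sum((o - p) ** 2))
        out[g] = 1.0 - ss_res / ss_tot
    return out


def fit_r2_table(
    weights: TermWeights, samples, spec: ModelSpec | None = None,
    two_fiber_families: bool = True,
) -> dict:
    """R^2 keyed by (direction, ratio), plus pooled (direction, 'all').

    For cohorts the table is additionally keyed (sample_id, direction, ratio).
    Returns an empty dict when the original sample structure is unavailable.
    """
    if samples is None:
        return {}
    table: dict = {}
    pooled: dict = {d: ([], []) for d in DIRECTIONS}
    per_sample = len(samples) > 1
    for s in samples:
        for ratio, b in s.curves.items():
            p_ax, p_cir = predict_stress_block(b, weights, spec, two_fiber_families)
            for direction, pred, obs in (("ax", p_ax, b.P_ax), ("circ", p_cir, b.P_cir)):
                r2 = r_squared(pred, obs)["all"]
                key = ((s.sample_id, direction, ratio) if per_sample
                       else (direction, ratio))
                table[key] = r2
                pooled[direction][0].append(pred)
                pooled[direction][1].append(obs)
    for direction, (preds, obss) in pooled.items():
        table[(direction, "all")] = r_squared(
            np.concatenate(preds), np.concatenate(obss)
        )["all"]
    return table


def predict_stress_block(block, weights, spec=None, two_fiber_families=True):
    from .model import predict_stress

    return predict_stress(
        block.lambda_ax, block.lambda_cir, weights, spec, two_fiber_families,
        warn_reference_stress=False,
    )


def active_terms(
    weights: TermWeights,
    data,
    spec: ModelSpec | None = None,
    two_fiber_families: bool = True,
    threshold: float = 1e-3,
) -> tuple:
    """Indices (1-based) of terms whose peak stress contribution matters.

    A term is active when its largest absolute contribution to either stress
    direction, over all training points, exceeds ``threshold`` times the
    sample's maximum observed stress (per sample in cohorts).
    """
    from .model import term_stress_contributions

    td = data if isinstance(data, TrainingData) else build_training_data(
        data, "sample" if isinstance(data, BiaxialSample) else "cross_sample"
    )
    contrib = term_stress_contributions(
        td.lam_ax, td.lam_cir, weights, spec, two_fiber_families
    )  # (n, 2, 16)
    rel = np.abs(contrib) / td.sample_max[:, None, None]
    peak = rel.max(axis=(0, 1))
    return tuple(int(i + 1) for i in np.nonzero(peak > threshold)[0])
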