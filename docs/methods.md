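# Methods

## Scope

`biaxcann` implements sparse, invariant-based discovery of hyperelastic
constitutive models for arterial tissue from planar-biaxial stress–stretch
data: a 16-term strain-energy network whose trained weights are interpretable
material parameters, fitted with Adam under non-negativity and optional L1
(lasso) regularization, together with a synthetic-cohort generator that
emulates an ovine main-pulmonary-artery biaxial protocol so that every stage
is testable without external data.

## Kinematics and stress

The tissue patch is treated as incompressible and shear-free, so the
deformation gradient is `F = diag{λ_ax, λ_cir, (λ_ax λ_cir)^-1}`.  One
in-plane collagen fiber direction at angle α from the axial axis
(`n0 = [cos α, sin α, 0]`) defines, next to the isotropic invariants I1 and
I2, the anisotropic invariants

    I4 = λ_ax² cos²α + λ_cir² sin²α,
    I5 = λ_ax⁴ cos²α + λ_cir⁴ sin²α.

The engineering (first Piola–Kirchhoff) stress is the F-derivative of the
strain energy, with the incompressibility pressure eliminated analytically
through the plane-stress condition P33 = 0.  On the incompressible biaxial
manifold this collapses to

    P_ax  = ∂ψ̂/∂λ_ax,   P_cir = ∂ψ̂/∂λ_cir,

where ψ̂(λ_ax, λ_cir) is the energy with the thickness stretch eliminated;
the implementation evaluates the four energy derivatives ∂ψ/∂I and combines
them with the closed-form total stretch-derivatives of the invariants.  Two
collagen fiber families placed symmetrically about the circumferential axis
with identical properties are modelled by doubling the I4/I5 stress
contributions (`two_fiber_families`, on by default; off is used by the
finite-difference and HGO-equivalence tests, which compare against
single-family closed forms).

Numerical note: I4 and I5 are evaluated in the anchored form
`λ_cir² + cos²α (λ_ax² − λ_cir²)` so that the reference state yields exactly
1 in floating point (`cos²α + sin²α` alone rounds away from one for most
angles); the zero-energy and zero-stress reference identities then hold
exactly, not just to 1e-16.

## The energy network

Sixteen terms: for each shifted invariant x ∈ {I1−3, I2−3, I4−1, I5−1},
the four nodes x, exp(w* x)−1, x², exp(w* x²)−1, each scaled by an outer
weight w (kPa); inner weights w* are dimensionless.  All 32 weights are
constrained non-negative, which—together with the shifts—guarantees zero
energy in the reference state and monotone tensile response for the I1/I4/I5
terms.  For identity-activation terms only the product w*·w is identifiable
and reporting uses the product.  Linear I4/I5 terms predict nonzero stress at
the reference state (their energy derivative does not vanish and the
plane-stress pressure cannot compensate in-plane fiber terms); they are
permitted but flagged with a warning.

Two classical models are masks of the network:

* HGO: terms {1, 12}, with c1 = 2 w1* w1, k1 = 2 w12* w12, k2 = w12*.
  The inverse mapping pins the unidentifiable w1* to 1.
* Reduced two-term artery model ψ = a1(exp(a2[I1−3]) − 1) + b[I5−1]², terms
  {2, 15}, with a1 = w2, a2 = w2*, b = w15*·w15.  The zero-energy
  normalization requires the "−1" outside the exponential, and that is how
  term 2 is implemented.

"Active" terms for discovery reporting are those whose largest absolute
stress contribution over the training points exceeds 1e-3 of the sample's
maximum observed stress; this behavioral threshold is what makes sparsity
statements meaningful when weights are small but nonzero.

## Loss and training

The sample-mode loss is the mean over loading points of the squared
Euclidean norm of the two-direction stress residual, each direction
normalized by the maximum observed stress of the point's (ratio, direction)
block, plus `alpha_reg · Σ(|w*| + |w|)` (0.01 when L1 is on in sample mode).
Cross-sample mode sums per-sample means over samples, with normalizers per
(sample, ratio, direction) and `alpha_reg = 0.001`; this "one model for all
samples" objective is the feature-selection stage, after which per-sample
magnitudes are refitted on the frozen universal term set.

Training is mini-batch Adam (reference protocol: 8000 epochs, batch 32,
learning rate 0.001, early stopping after 2000 epochs without an improvement
larger than 1e-8; identity-term weights initialized Glorot-normal with
std = sqrt(2/17) from the 16→1 output-layer fan and clipped at zero,
exponential-term weights uniform on [0.0001, 0.1]).  Weight gradients are
analytic (the stresses are closed-form in the weights); the fitted fiber
angle, a single scalar, uses central differences.  Non-negativity is
enforced by projection after every step, keeping exact zeros reachable for
the lasso.  Exponential arguments are clamped at 50 during training only.

Three numerical safeguards beyond the plain protocol, all config-exposed:

* **Inner-weight floor (1e-8).**  Exact zero in *both* weights of a term is
  a spurious stationary point of the bilinear (w*, w) parameterization: the
  term's gradient vanishes and it can never revive.  Flooring the inner
  weight removes the trap; sparsity still arises through exact zeros of the
  outer weight, which alone switch a term off.
* **Cosine learning-rate decay (`lr_decay`).**  Adam's stationary
  oscillation amplitude scales with the rate; annealing it settles the final
  iterates.  Off by default.
* **Fitted-angle warm-up and step scale.**  Adam moves every coordinate by
  roughly the learning rate per step, so in radians the angle races ahead of
  the kPa-scale weights and drags the fit into self-consistent wrong basins.
  Fitted runs therefore hold the angle at its multi-start value for the
  first half of the epochs (the weights reach their conditional optimum),
  then release it with a 0.1 step scale so it evolves quasi-statically.
  With the multi-start over the 11-angle grid this turns each start into a
  local refinement around its grid angle; the best final loss wins, ties
  broken by smaller L1 norm, then lower start index.  Reported angles are
  reflected into [0°, 90°]; all multi-start outcomes are retained in the
  fit result because the fitted angle is only weakly identified (the
  conditional loss is nearly flat over ±10° unless the weights are fully
  converged).

Scaled-down runs in the test-suite and analysis scripts use learning rate
0.01 with cosine decay and 500–12000 epochs depending on the question: the
per-step Adam displacement is ≈ lr, so the product steps × lr must exceed
the ~10 kPa weight magnitudes, and a short run at 0.001 simply cannot reach
the optimum.  The analysis scripts state their protocol in their headers.

## Goodness of fit

R² = 1 − SS_res/SS_tot per (direction, ratio) block, plus pooled
per-direction values across the three ratios (both are reported because
pooled and per-ratio summaries differ in general).  Zero-variance or
single-point groups have no defined R² and are reported as missing.  Sweep
heat-map cells average R² over the 2 × 3 (direction × ratio) blocks.

## Synthetic cohorts

The generator emulates the structure of a displacement-driven biaxial
protocol on n = 8 samples (four animals × two locations):

* three actuator ratios 2:1, 1:1, 1:2 of axial:circumferential stretch, a
  maximum actuator stretch of 1.30 ("30% deformation to the actuators"),
  and 15 points per ratio;
* actuator-to-tissue gain `dic_slip = 1.7`: strain localizes in the imaged
  central region, so tissue stretches reach ≈1.5 at 30% actuator strain,
  matching the >50% tissue strains of such protocols;
* ground truth: the reduced two-term model at α = 70° with the cohort-level
  magnitudes a1 = 8.48 kPa, a2 = 0.424, b = 0.0249 kPa — the generator
  shares one truth across samples and jitters only per-sample magnitudes,
  so its defaults follow a combined (all-sample) fit rather than any single
  sample's;
* heterogeneity: lognormal jitter (σ = 0.2) on the outer weights of active
  terms only, keeping the term set shared across the cohort — exactly the
  regime cross-sample feature selection assumes;
* noise: multiplicative lognormal (σ = 0.03) on stresses, because stress
  magnitudes span ~5–35 kPa and additive noise would distort the toe
  region;
* preload: recorded curves begin at the actuator offset where the
  equibiaxial mean stress crosses 5 kPa (one shared 1:1 offset for all
  three ratios, per-sample because the jittered magnitudes shift the
  crossing).  Stretches remain in the material frame, so the generating
  parameters stay exactly recoverable; the alternative of re-zeroing the
  stretch origin at the preload point would re-parameterize the truth and
  make parameter-recovery contracts ill-posed.  The real protocol's
  correction is force-based (0.1 N); the synthetic analog uses the stress
  level directly since synthetic samples have no geometry.

What the generator does **not** emulate: preconditioning cycles, rake
mechanics and DIC image processing, shear, rupture, and—importantly—the
sub-preload toe region, which the preload correction consumes in the real
protocol too.  Consequences for interpretation: over the recorded stretch
window (λ ≈ 1.19–1.51) the exponential isotropic response is approximated to
~2% by a linear+quadratic polynomial mix, so L1 feature selection at
`alpha_reg = 0.001` genuinely prefers spending cheap polynomial weights over
the expensive exponential outer weight (the bilinear L1 cost of an identity
term is 2√product, while an exponential term must carry its full kPa
magnitude in one weight).  Discovery on these cohorts therefore recovers the
generating terms *plus* low-order isotropic companions, and passing tests
show correct mechanics of selection, not that two-term selection is the
unique optimum under all conditions.

## Problem sizes used by the test suite

Analytic identities and oracle comparisons run at full precision on ~10³
random states.  Statistical checks use the 8-sample default cohort with
scaled training budgets chosen for convergence (8000 epochs at lr 0.01 for
parameter recovery; 500–2500 epochs for selection, sweep and comparison
checks; sweeps over 2–3 samples and 3–11 angles).  Stochastic assertions fix
seeds and, where the claim is distributional, aggregate over three seeds.

## Known limitations

* The fitted fiber angle is only weakly identified by biaxial data of this
  kind; outside a circumferentially oriented truth (α ≥ ~55°) and without
  the warm-up multi-start, runs can settle several degrees away at
  essentially the same loss.  All multi-start outcomes are reported.
* (a1, a2) of the exponential term trade off along a near-degenerate valley;
  accurate separation needs well-converged fits (mini-batch noise helps
  escape the valley's plateaus, and full-batch training is measurably worse
  here).
* L1 selection results depend on the observable stretch window and the
  truth magnitudes (see above); the exact discovered set should be read
  together with the term-prevalence tables, not as a binary outcome.
* The dispersion-free two-family assumption and the absence of shear are
  modelling choices inherited from the protocol, not fitted properties.
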