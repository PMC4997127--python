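# Methods

## Model and estimation

### Penalized linear discriminant direction

For a two-class cohort with feature matrix **X** (n × p) and labels H/D,
Fisher's criterion maximizes v'S_B v subject to v'S_W v = 1. With two
classes S_B = d d' where d = m_H − m_D, so v'S_B v = (d·v)²; the package
exploits this rank-1 identity everywhere and never materializes a p × p
matrix (all costs are O(np) memory). The within-class scatter is replaced
by its diagonal S_W* = diag(s²), with s²_j the pooled within-class sum of
squares of feature j (no degrees-of-freedom normalization — the constraint
absorbs any global scale). The penalized problem is

    max_v (d·v)² − λ Σ_j s_j |v_j|   s.t.   Σ_j s_j² v_j² = 1,

with the penalty weighted by the per-feature scale s_j so that selection is
scale-equivariant.

The solver is minorization-maximization. At the current iterate v⁰ the
convex quadratic (d·v)² is bounded below by its tangent
2(d·v⁰)(d·v) − (d·v⁰)², and the tangent-plus-penalty problem over the
constraint ellipsoid has the closed-form solution
u_j = soft(b_j, λ s_j)/s_j² with b_j = 2 d_j (d·v⁰), renormalized to the
ellipsoid. This guarantees a monotone objective, which the tests assert at
every iteration.

Numerical choices:

- **Initialization**: the λ = 0 closed form v_j ∝ d_j/s_j² — deterministic
  and a fixed point of the iteration when λ = 0.
- **Convergence**: relative objective change < 1e−6, cap 1000 iterations;
  hitting the cap sets `converged=False` without raising so λ-grid sweeps
  complete. Collapse to the zero vector (every coordinate thresholded) is a
  valid terminal state; at the experiment level a λ whose subset fits *all*
  collapse is flagged as outside the operating range.
- **Ties**: |b_j| = λ s_j exactly yields coefficient 0 (the closed-form
  maximizer at equality).
- **Sign**: the direction is fixed by d·v ≥ 0 so that weight maps are
  comparable across subsamples and folds.
- **Constant features** (s²_j = 0) are dropped before fitting with a logged
  warning and re-inserted as zeros; `unpenalized_direction` refuses them
  outright since v_j ∝ d_j/s_j² is undefined.
- A subtlety the tests encode: the equality constraint means the
  on-ellipsoid maximum of the objective can be negative while the collapse
  value v = 0 (objective 0) lies off the ellipsoid. Solver correctness is
  therefore checked against a brute-force grid *on the ellipsoid* whenever
  the returned direction is nonzero.

### Stability selection

pLDA alone at one λ is sample-sensitive, so the selected set is defined via
resampling: K stratified subsamples (default K = 100; without replacement,
⌊n_c/2⌋ subjects per class — half-sampling is the convention of the
stability-selection literature, and the fraction is configurable), per
subsample an indicator of nonzero coefficients, and per feature the
selection probability P_j(λ) = mean indicator. The selected set is
{j : P_j ≥ threshold} with threshold 0.99, **inclusive** — so a feature
selected in exactly 99 of 100 subsamples passes. Each subsample receives a
pre-spawned child seed from the root seed (`numpy` `SeedSequence`), so
serial and parallel (joblib) execution agree bit for bit. A subsample whose
fit collapses to v = 0 contributes all-zero indicators; features constant
within one subsample get indicator 0 for that subsample only.

### Baseline reductions

- **t-test selection**: per-feature two-sided two-sample Student's t with
  pooled variance (df = n − 2; the equal-variance form is the classical
  "Student's" test), selecting raw p < threshold, or Benjamini–Hochberg
  adjusted p < threshold in FDR mode — BH being the standard neuroimaging
  FDR procedure. Features constant in both classes are never selected.
- **PCA**: train-mean centering, thin SVD, every component with a nonzero
  singular value (≤ n_train − 1); covariance (not correlation) PCA on
  unscaled features. Labels never enter.
- **none**: identity selection, the unreduced comparison arm.

### Classifiers

- **LDA** (as a classifier, distinct from the reduction): equal-prior
  Gaussian discriminant with pooled covariance. With p ≫ n the covariance
  is singular; it is pseudo-inverted in the ≤ (n−2)-dimensional span of the
  class-centered training rows, which reduces exactly to classical LDA at
  full rank (verified against scikit-learn) and is deterministic. The
  intercept places the boundary at the midpoint of the projected class
  means; a decision value of exactly 0 deterministically predicts H. A
  diagonal-covariance variant is available behind `covariance="diagonal"`
  for sensitivity analysis.
- **Linear SVM**: soft-margin hinge loss via libsvm, default C = 1.0 with
  no inner tuning; results depend on C and the default is documented
  rather than optimized.

### Cross-validation designs and inference

`loocv_c` fits the reduction once on all n subjects, then leave-one-out
cross-validates only the classifier: supervised reducers thereby see every
test subject's label — the design whose optimism the package demonstrates.
`loocv_rc` refits the reduction (including all K stability subsamples) on
the n − 1 training subjects of every fold. Both record per-fold selected
sets, a per-feature selection-count map, and — for pLDA — the mean of
nonzero discriminant coefficients over all subsamples and folds.

A fold whose selected set is empty falls back, with a prominent log
message, to the features attaining the maximum selection probability
(pLDA) or the minimum p-value (t-test); aborting an n-fold run for one
degenerate fold would be worse, and an `empty_action="error"` mode exists
for callers who disagree. Note the fallback is itself supervised, so it
correctly *preserves* the leakage being measured in design c.

Metrics are accuracy, sensitivity and specificity in percent from the
confusion counts with class D positive; zero-denominator metrics are NaN
and flagged, never silently 0. McNemar's test uses the exact binomial form
up to 25 discordant pairs and the continuity-corrected χ² above
(statsmodels implementation; both validated against closed forms). The
test against chance is a one-sided exact binomial on #correct vs 0.5,
one-sided because the claim of interest is directional (better than
chance).

## Synthetic cohorts

The generator emulates the statistical structure of smoothed morphometry
maps, not their physics. Per subject: white Gaussian noise on the bounding
grid, multiplied by a per-voxel scale field noise_sd · LogNormal(0, h)
drawn once per cohort (h = `variance_heterogeneity`, default 0.3, giving
mild spatial variance heterogeneity), Gaussian-smoothed with
σ = FWHM/2.3548 (default FWHM 2 voxels, emulating 8-mm smoothing at a
4-mm desk-scale voxel size), plus a constant baseline and — for class D —
the planted effect field. Effects are spherical clusters added *after*
smoothing, so the expected group difference at a support voxel equals its
planted Δ exactly (asserted to 3·SE in tests). Features are the in-mask
voxels, linearized row-major over (x, y, z) after masking — any fixed
bijection would do; the conventional one is documented and stable.

Default scales, chosen once for testability (no quantitative noise or
effect sizes exist for real cohorts of this kind at desk scale):

| parameter | default | role |
|---|---|---|
| grid / mask | 24³, ellipsoid (4272 voxels) | desk-scale "brain" |
| n per class | 20 + 20 | small-cohort regime |
| noise_sd | 1.0 | white-noise scale before smoothing |
| smoothing FWHM | 2 voxels | spatial correlation of real maps |
| variance_heterogeneity | 0.3 | log-normal spread of voxel scales |
| strong-signal Δ | 5 × noise_sd, 81-voxel cluster | unambiguous support |
| bias-demo geometry | 20×10×10 box, p = 2000 | null experiments |

What the generator does **not** model: registration error, segmentation
artifacts, bias fields, anatomically shaped effect regions, long-range
anatomical covariance, site/scanner effects. Passing tests therefore show
that the *pipeline logic* is correct (selection recovers planted signal,
nested CV is unbiased, non-nested CV is optimistic); they do not certify
accuracy levels on real MRI data, where the paper-scale p ≈ 7.5×10⁵–1.9×10⁶
matrices are supported by the O(np) implementation but not exercised by the
test suite.

## Operating-range penalty for the null demonstration

The bias demonstration needs a λ at which subset fits are sparse but do not
all collapse. Following the standard practice of choosing the grid from the
feature-count profile, λ = 0.8 (`DEMO_LAM`) was fixed from a sweep on the
null fixture (λ_max ≈ 1.0 there; subset fits retain ~hundreds of the 2000
features at 0.8, collapse near 2). On null data the 0.99 threshold then
selects essentially nothing and the max-P fallback engages — which is the
realistic behavior of the procedure on signal-free data and leaks labels
exactly as the design-c critique predicts.

## Problem sizes

The shipped experiments run on one CPU in minutes: the null-bias experiment
uses 10 cohorts of n = 40, p = 2000 with K = 100 subsamples per stability
fit; the strong-signal fixture is p = 4272 with K = 50. Real-data scale is
a matter of memory and patience, not code paths.

## Known limitations

- Two classes only; the multi-class extension of penalized discriminant
  analysis is out of scope.
- The stability-selection error-control bound (expected false positives)
  is not implemented; selection is by probability threshold alone.
- MM convergence is to a stationary point; for the rank-1 two-class
  objective the brute-force checks show it attains the on-ellipsoid
  optimum on small instances, but no global-optimality proof is claimed
  for general instances.
- SVM determinism relies on libsvm's deterministic solver for fixed input;
  exotic degenerate inputs may be solver-version sensitive.
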