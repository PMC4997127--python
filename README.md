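# pldacv

Sparse penalized linear discriminant analysis with stability selection, and
an honest-versus-leaky comparison of leave-one-out cross-validation designs,
for two-class masked brain-volume cohorts.

## The problem

Structural-MRI group studies (e.g., patients with first-episode
schizophrenia vs. healthy controls) produce, per subject, a masked 3-D
scalar volume — smoothed gray-matter density from voxel-based morphometry,
or log-Jacobian local-deformation maps from deformation-based morphometry.
Flattening the in-mask voxels gives an *n × p* feature matrix **X** with
*n* in the tens and *p* in the hundreds of thousands, so the data must be
reduced before a classifier can be trained. How the reduction interacts
with cross-validation decides whether the reported accuracy means anything:
a *supervised* reduction (it looks at the diagnosis labels) fit on **all**
subjects before leave-one-out cross-validation leaks every test subject's
label into feature selection and inflates the estimate; refitting the
reduction inside every fold does not. This package implements the full
pipeline and, because clinical MRI cohorts are rarely shareable, ships a
synthetic cohort generator with known ground truth so the bias is
reproducible at desk scale.

## The method

**Penalized LDA.** For classes *H* and *D* with mean vectors
m_H, m_D, let d = m_H − m_D and let S_W\* = diag(s₁², …, s_p²) be the
diagonal of the pooled within-class scatter. The sparse discriminant
direction solves

    max_v  (dᵀv)² − λ Σⱼ sⱼ|vⱼ|   subject to   Σⱼ sⱼ²vⱼ² = 1.

At λ = 0 the closed-form solution vⱼ ∝ dⱼ/sⱼ² uses every feature; as λ
grows, coefficients are soft-thresholded to zero; beyond a data-dependent
λ_max the direction collapses entirely. The problem is solved by
minorization-maximization (MM): each iteration replaces (dᵀv)² with its
tangent minorant and maximizes in closed form, so the objective never
decreases.

**Stability selection.** pLDA is refit on K stratified half-subsamples;
feature *j*'s selection probability is P_j(λ) = (1/K) Σ_k c_j^(k)(λ), the
fraction of subsamples in which its coefficient was nonzero. Features with
P_j ≥ 0.99 form the selected set.

**Baselines and classifiers.** Voxel-wise two-sample Student's t-tests
(raw thresholds or Benjamini–Hochberg FDR), PCA with all ≤ n−1 nonzero
components, or no reduction; then equal-prior LDA (pseudo-inverse pooled
covariance, so p ≫ n is handled) or a linear soft-margin SVM.

**Two CV designs.** `loocv_c` fits the reduction once on all *n* subjects
and cross-validates only the classifier; `loocv_rc` nests the entire
reduction (including the K-subsample resampling) inside each of the *n*
folds. Accuracy, sensitivity and specificity come from the confusion
counts; runs are compared with McNemar's paired test and against chance
with a one-sided exact binomial test.

## Worked example

Stability selection on the built-in strong-signal cohort (24³ grid,
ellipsoidal mask with 4272 in-mask voxels, one planted 81-voxel cluster at
5× the noise sd), `python examples/03_stability_selection.py`:

```
K = 50 subsamples at lam = 30
selected (P >= 0.99): 81 features
planted support recovered: 81/81
false selections: 0 (0.00% of background voxels)
mean P on background voxels: 0.019
mean MM iterations per subsample: 2.0
```

Every planted voxel is selected in at least 99% of subsamples; smooth
background noise never is. The cross-validation bias demonstration,
`python examples/04_cv_bias_demo.py`, runs both CV designs on cohorts with
**no** class signal (true accuracy 50%):

```
mean LOOCV accuracy (%) on null cohorts, p=2000, n=20+20:

design           c    rc  bias
reduction
none          55.0  55.0   0.0
pca           55.0  55.0   0.0
plda          83.3  58.3  25.0
ttest_p<0.01  85.0  56.7  28.3
```

The supervised reducers report 83–85% "accuracy" on pure noise when the
reduction sits outside the CV loop (design c) — a 25–28 point optimistic
bias — while the nested design (rc) and the label-free reducers stay at
chance. The other examples show the cohort generator
(`01_synthetic_cohort.py`), the λ sparsity path (`02_plda_path.py`), and a
full reduction × classifier × design experiment grid with McNemar
comparisons (`05_full_experiment.py`).

## Layout

- `src/pldacv/synthetic.py` — geometry, masks, cohort generator, ground truth
- `src/pldacv/plda.py` — class statistics, penalized objective, MM solver
- `src/pldacv/stability.py` — subsample resampling, selection probabilities
- `src/pldacv/reduction.py` — t-test / FDR selection, PCA, identity
- `src/pldacv/classify.py` — equal-prior LDA (pseudo-inverse), linear SVM
- `src/pldacv/cv.py` — both LOOCV designs, metrics, McNemar, binomial test
- `src/pldacv/experiment.py` — experiment grids, summaries, bias demo
- `src/pldacv/io.py` — NIfTI volumes/masks/maps, labels CSV, spec configs
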