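"""Baseline data reductions: mass-univariate t-test selection and PCA.

These are the comparison reductions against which the penalized-discriminant
selection is judged: per-voxel two-sample Student's t-tests thresholded at a
raw (or Benjamini-Hochberg-adjusted) p-value, unsupervised principal-component
extraction keeping every component with a nonzero eigenvalue (at most
n_train - 1), and the identity "no reduction".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import LabeledFeatureMatrix


@dataclass
class PCATransform:
    """Train-mean centering plus orthonormal component loadings."""

    mean: np.ndarray        # length-p train mean
    components: np.ndarray  # r x p, rows orthonormal
    singular_values: np.ndarray

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return (X - self.mean) @ self.components.T


@dataclass
class ReductionResult:
    """Outcome of one reduction: a selected index set or a linear transform."""

    method: str  # {"plda", "ttest", "pca", "none"}
    selected: np.ndarray | None = None
    transform: PCATransform | None = None
    params: dict = field(default_factory=dict)
    per_fold: bool = False

    def __post_init__(self) -> None:
        if (self.selected is None) == (self.transform is None):
            raise ValueError("exactly one of selected/transform must be set")

    @property
    def n_features_out(self) -> int:
        if self.selected is not None:
            return int(self.selected.size)
        return int(self.transform.components.shape[0])


def ttest_pvalues(data: LabeledFeatureMatrix) -> np.ndarray:
    """Two-sided two-sample Student's t p-value per feature (pooled variance,
    df = n - 2); NaN for features constant in both classes."""
    if data.n_H < 2 or data.n_D < 2:
        raise ValueError("each class needs >= 2 members for a t-test")
    res = sps.ttest_ind(data.X[data.mask_H], data.X[data.mask_D],
                        axis=0, equal_var=True)
    return np.asarray(res.pvalue)


def ttest_select(data: LabeledFeatureMatrix, p_threshold: float = 0.01,
                 correction: str = "none") -> ReductionResult:
    """Select features with two-sample t-test p below the threshold.

    ``correction="fdr"`` applies Benjamini-Hochberg and compares the adjusted
    p-values against the same threshold.  Features constant in both classes
    are never selected.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    if correction not in ("none", "fdr"):
        raise ValueError(f"unknown correction {correction!r}")
    pvals = ttest_pvalues(data)
    testable = ~np.isnan(pvals)
    if correction == "fdr":
        adj = np.full_like(pvals, np.nan)
        if testable.any():
            adj[testable] = multipletests(pvals[testable],
                                          method="fdr_bh")[1]
        crit = adj
    else:
        crit = pvals
    selected = np.flatnonzero(testable & (crit < p_threshold))
    return ReductionResult(method="ttest", selected=selected,
                           params={"p_threshold": p_threshold,
                                   "correction": correction})


def pca_extract(train: LabeledFeatureMatrix | np.ndarray,
                test_rows: np.ndarray | None = None
                ) -> tuple[ReductionResult, np.ndarray, np.ndarray | None]:
    """Principal components of the training rows (labels unused).

    Centers on the train mean and keeps every right singular direction with
    a nonzero singular value — at most n_train - 1 components.  Returns the
    reduction, the train scores, and the test scores (None if no test rows).
    """
    X = train.X if isinstance(train, LabeledFeatureMatrix) else np.asarray(train)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA extraction needs at least 3 training rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(Xc.shape) * np.finfo(np.float64).eps
    r = int((s > tol).sum())
    if r < 1:
        raise ValueError("training rows are all identical; PCA rank is 0")
    transform = PCATransform(mean=mean, components=Vt[:r],
                             singular_values=s[:r])
    result = ReductionResult(method="pca", transform=transform,
                             params={"n_components": r})
    train_scores = Xc @ Vt[:r].T
    test_scores = transform.project(test_rows) if test_rows is not None else None
    return result, train_scores, test_scores


def no_reduction(data: LabeledFeatureMatrix) -> ReductionResult:
    """Identity reduction: all p features selected."""
    return ReductionResult(method="none", selected=np.arange(data.p))
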