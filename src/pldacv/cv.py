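"""Leave-one-out cross-validation in two designs, metrics and paired tests.

The package distinguishes two LOOCV designs that differ in *where* the data
reduction sits relative to the cross-validation loop:

* ``loocv_c`` — reduction is fit once on **all** n subjects, then only the
  classifier is cross-validated.  A supervised reducer (t-test, penalized
  discriminant) thereby sees the labels of every later test subject; this is
  the design under critique, and on data with no class signal it produces
  optimistically biased accuracy estimates.
* ``loocv_rc`` — reduction (including the stability resampling) is refit on
  the n-1 training subjects of every fold; the held-out subject's features
  enter only at prediction time.  This nested design is unbiased.

Per-run outputs include the confusion counts, per-fold selected-feature
sets, a per-feature selection-count map (how many folds selected each
voxel), and — for the penalized discriminant — the mean of the nonzero
discriminant coefficients over all subsamples and folds (a discriminative
weight map).

Accuracy, sensitivity and specificity are computed from the confusion counts
with class D as positive; paired runs are compared with McNemar's test on
the discordant subjects, and a one-sided exact binomial test compares a
single run against chance (0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .classify import predict, train_classifier
from .data import LABEL_D, LABEL_H, LabeledFeatureMatrix
from .reduction import (ReductionResult, no_reduction, pca_extract,
                        ttest_pvalues, ttest_select)
from .stability import SelectionProfile, run_stability, select_features

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReducerSpec:
    """Configuration of one data reduction.

    method: "plda" (stability-selected penalized discriminant), "ttest",
    "pca", or "none".  ``empty_action`` governs a fold whose selected set is
    empty: "fallback" selects the features attaining the maximum selection
    probability (or minimum t-test p-value) and logs prominently; "error"
    aborts.
    """

    method: str
    lam: float | None = None
    K: int = 100
    subsample_fraction: float = 0.5
    threshold: float = 0.99
    p_threshold: float = 0.01
    correction: str = "none"
    empty_action: str = "fallback"

    def __post_init__(self) -> None:
        if self.method not in ("plda", "ttest", "pca", "none"):
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.method == "plda" and (self.lam is None or self.lam < 0):
            raise ValueError("plda reduction requires lam >= 0")
        if self.empty_action not in ("fallback", "error"):
            raise ValueError(f"unknown empty_action {self.empty_action!r}")

    @property
    def supervised(self) -> bool:
        """True when the reduction uses the class labels."""
        return self.method in ("plda", "ttest")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "lda"  # {"lda", "linsvm"}
    C: float = 1.0
    covariance: str = "pooled"


@dataclass
class FoldRecord:
    test_subject: int
    true_label: str
    predicted_label: str
    n_selected: int
    reduction_refit: bool
    mm_iter_mean: float = math.nan


@dataclass
class CVRunResult:
    """Everything one LOOCV run produced."""

    design: str  # {"c", "rc"}
    folds: list[FoldRecord]
    tp: int
    tn: int
    fp: int
    fn: int
    n_features_per_fold: np.ndarray
    selection_counts: np.ndarray | None  # per-feature count of selecting folds
    weight_sum: np.ndarray | None = None
    weight_count: np.ndarray | None = None
    subject_ids: list[str] = field(default_factory=list)
    true_labels: np.ndarray | None = None
    predictions: np.ndarray | None = None
    reduction_converged: bool = True

    @property
    def n(self) -> int:
        return len(self.folds)

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    @property
    def mean_weight_map(self) -> np.ndarray | None:
        """Average of nonzero discriminant coefficients over all subsamples
        and folds in which each feature was active (NaN where never)."""
        if self.weight_sum is None:
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.weight_count > 0,
                            self.weight_sum / self.weight_count, np.nan)


@dataclass
class PerformanceReport:
    """Accuracy / sensitivity / specificity in percent.

    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
    sensitivity = 100 * TP / (TP + FN)   (patients correctly detected)
    specificity = 100 * TN / (TN + FP)   (controls correctly rejected)

    A metric with a zero denominator is NaN and listed in ``undefined``.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: list[str] = field(default_factory=list)


@dataclass
class McNemarResult:
    statistic: float
    pvalue: float
    only_a_correct: int
    only_b_correct: int
    method: str  # {"exact", "chi2_corrected"}


class _FittedReducer:
    """A reduction fit on one training set, applicable to any row batch."""

    def __init__(self, result: ReductionResult,
                 profile: SelectionProfile | None = None,
                 mm_iter_mean: float = math.nan):
        self.result = result
        self.profile = profile
        self.mm_iter_mean = mm_iter_mean

    @property
    def converged(self) -> bool:
        """False when the penalized discriminant failed to yield a usable
        direction: some subset fit hit the iteration cap, or every subset
        collapsed to the zero vector (lam beyond the operating range).
        True for reductions without an iterative solver."""
        if self.profile is None or self.profile.per_subset_converged is None:
            return True
        if self.profile.n_collapsed == self.profile.K:
            return False
        return bool(self.profile.per_subset_converged.all())

    @property
    def n_selected(self) -> int:
        return self.result.n_features_out

    @property
    def selected(self) -> np.ndarray | None:
        return self.result.selected

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.result.selected is not None:
            return X[:, self.result.selected]
        return self.result.transform.project(X)


def fit_reducer(spec: ReducerSpec, train: LabeledFeatureMatrix,
                seed: int | np.random.SeedSequence | None = None) -> _FittedReducer:
    """Fit the configured reduction on a training cohort."""
    if spec.method == "none":
        return _FittedReducer(no_reduction(train))

    if spec.method == "pca":
        result, _, _ = pca_extract(train)
        return _FittedReducer(result)

    if spec.method == "ttest":
        result = ttest_select(train, spec.p_threshold, spec.correction)
        if result.selected.size == 0:
            if spec.empty_action == "error":
                raise RuntimeError(
                    f"t-test at p<{spec.p_threshold} selected no features")
            pvals = ttest_pvalues(train)
            best = np.nanmin(pvals)
            fallback = np.flatnonzero(pvals == best)
            logger.warning(
                "t-test selected no features at p<%g; falling back to the "
                "%d feature(s) with minimum p=%g", spec.p_threshold,
                fallback.size, best)
            result = ReductionResult(method="ttest", selected=fallback,
                                     params={**result.params,
                                             "fallback": "min_p"})
        return _FittedReducer(result)

    # spec.method == "plda"
    profile = run_stability(train, lam=spec.lam, K=spec.K,
                            subsample_fraction=spec.subsample_fraction,
                            seed=seed, keep_indicators=False)
    selected = select_features(profile, spec.threshold)
    params = {"lam": spec.lam, "K": spec.K, "threshold": spec.threshold}
    if selected.size == 0:
        if spec.empty_action == "error":
            raise RuntimeError(
                f"no feature reached selection probability {spec.threshold} "
                f"at lam={spec.lam}")
        pmax = profile.P.max()
        selected = np.flatnonzero(profile.P == pmax)
        logger.warning(
            "no feature reached P>=%g at lam=%g; falling back to the %d "
            "feature(s) attaining max P=%g", spec.threshold, spec.lam,
            selected.size, pmax)
        params["fallback"] = "max_P"
    result = ReductionResult(method="plda", selected=selected, params=params)
    return _FittedReducer(result, profile=profile,
                          mm_iter_mean=float(profile.per_subset_iters.mean()))


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _confusion(true_labels: np.ndarray, predictions: np.ndarray):
    tp = int(((true_labels == LABEL_D) & (predictions == LABEL_D)).sum())
    tn = int(((true_labels == LABEL_H) & (predictions == LABEL_H)).sum())
    fp = int(((true_labels == LABEL_H) & (predictions == LABEL_D)).sum())
    fn = int(((true_labels == LABEL_D) & (predictions == LABEL_H)).sum())
    return tp, tn, fp, fn


def _accumulate_weights(run_sums, fitted: _FittedReducer):
    weight_sum, weight_count = run_sums
    if fitted.profile is not None:
        weight_sum += fitted.profile.weight_sum
        weight_count += fitted.profile.weight_count
    return weight_sum, weight_count


def loocv_c(data: LabeledFeatureMatrix, reducer: ReducerSpec,
            classifier: ClassifierSpec = ClassifierSpec(),
            seed: int | np.random.SeedSequence | None = None) -> CVRunResult:
    """LOOCV applied to classification only (reduction fit on all data).

    Supervised reducers here see every subject's label, including each later
    test subject's — the non-nested design whose optimism this package
    demonstrates.  The reduced representation is fixed; each fold retrains
    only the classifier on the other n-1 subjects.
    """
    root = _as_seedseq(seed)
    fitted = fit_reducer(reducer, data, seed=root.spawn(1)[0])
    reduced = fitted.transform(data.X)

    predictions = np.empty(data.n, dtype=object)
    folds = []
    for i in range(data.n):
        train_rows = np.delete(np.arange(data.n), i)
        model = train_classifier(classifier.kind, reduced[train_rows],
                                 data.labels[train_rows], C=classifier.C,
                                 covariance=classifier.covariance)
        predictions[i] = predict(model, reduced[i])[0]
        folds.append(FoldRecord(test_subject=i, true_label=data.labels[i],
                                predicted_label=predictions[i],
                                n_selected=fitted.n_selected,
                                reduction_refit=False,
                                mm_iter_mean=fitted.mm_iter_mean))
    predictions = predictions.astype(str)
    tp, tn, fp, fn = _confusion(data.labels, predictions)

    if fitted.selected is not None:
        counts = np.zeros(data.p, dtype=np.int64)
        counts[fitted.selected] = data.n  # same set in every fold
    else:
        counts = None
    weight_sum = weight_count = None
    if fitted.profile is not None:
        weight_sum = fitted.profile.weight_sum.copy()
        weight_count = fitted.profile.weight_count.copy()

    return CVRunResult(design="c", folds=folds, tp=tp, tn=tn, fp=fp, fn=fn,
                       n_features_per_fold=np.full(data.n, fitted.n_selected),
                       selection_counts=counts, weight_sum=weight_sum,
                       weight_count=weight_count,
                       subject_ids=list(data.subject_ids),
                       true_labels=data.labels.copy(),
                       predictions=predictions,
                       reduction_converged=fitted.converged)


def loocv_rc(data: LabeledFeatureMatrix, reducer: ReducerSpec,
             classifier: ClassifierSpec = ClassifierSpec(),
             seed: int | np.random.SeedSequence | None = None) -> CVRunResult:
    """Nested LOOCV: reduction and classification both inside the loop.

    In each fold the reduction — including the K-subsample stability
    resampling — is refit on the n-1 training subjects only; the held-out
    subject is reduced with that fold's selection/transform and classified.
    """
    root = _as_seedseq(seed)
    fold_seeds = root.spawn(data.n)

    predictions = np.empty(data.n, dtype=object)
    folds = []
    n_feat = np.empty(data.n, dtype=np.int64)
    counts = np.zeros(data.p, dtype=np.int64)
    have_counts = False
    weight_sum = np.zeros(data.p)
    weight_count = np.zeros(data.p, dtype=np.int64)
    have_weights = False
    all_converged = True

    for i in range(data.n):
        train_rows = np.delete(np.arange(data.n), i)
        train = data.subset_subjects(train_rows)
        fitted = fit_reducer(reducer, train, seed=fold_seeds[i])
        all_converged = all_converged and fitted.converged
        Xtr = fitted.transform(train.X)
        xte = fitted.transform(data.X[i])
        model = train_classifier(classifier.kind, Xtr, train.labels,
                                 C=classifier.C,
                                 covariance=classifier.covariance)
        predictions[i] = predict(model, xte)[0]
        n_feat[i] = fitted.n_selected
        if fitted.selected is not None:
            counts[fitted.selected] += 1
            have_counts = True
        if fitted.profile is not None:
            weight_sum += fitted.profile.weight_sum
            weight_count += fitted.profile.weight_count
            have_weights = True
        folds.append(FoldRecord(test_subject=i, true_label=data.labels[i],
                                predicted_label=predictions[i],
                                n_selected=int(n_feat[i]),
                                reduction_refit=True,
                                mm_iter_mean=fitted.mm_iter_mean))
    predictions = predictions.astype(str)
    tp, tn, fp, fn = _confusion(data.labels, predictions)

    return CVRunResult(design="rc", folds=folds, tp=tp, tn=tn, fp=fp, fn=fn,
                       n_features_per_fold=n_feat,
                       selection_counts=counts if have_counts else None,
                       weight_sum=weight_sum if have_weights else None,
                       weight_count=weight_count if have_weights else None,
                       subject_ids=list(data.subject_ids),
                       true_labels=data.labels.copy(),
                       predictions=predictions,
                       reduction_converged=all_converged)


def compute_metrics(run: CVRunResult) -> PerformanceReport:
    """Accuracy, sensitivity and specificity (percent) from the confusion
    counts; a zero-denominator metric is NaN and flagged, never silently 0."""
    tp, tn, fp, fn = run.tp, run.tn, run.fp, run.fn
    n = tp + tn + fp + fn
    if n != run.n:
        raise ValueError("confusion counts inconsistent with fold records")
    undefined = []
    accuracy = 100.0 * (tp + tn) / n
    if tp + fn == 0:
        sensitivity = math.nan
        undefined.append("sensitivity")
    else:
        sensitivity = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        specificity = math.nan
        undefined.append("specificity")
    else:
        specificity = 100.0 * tn / (tn + fp)
    return PerformanceReport(accuracy=accuracy, sensitivity=sensitivity,
                             specificity=specificity, undefined=undefined)


def mcnemar_compare(run_a: CVRunResult, run_b: CVRunResult,
                    exact_max_discordant: int = 25) -> McNemarResult:
    """McNemar's paired test on per-subject correctness of two runs.

    Uses the exact binomial form when the discordant count is at most
    ``exact_max_discordant``, else the continuity-corrected chi-square.
    Both runs must cover the same subjects in the same order.
    """
    if run_a.subject_ids != run_b.subject_ids or \
            not np.array_equal(run_a.true_labels, run_b.true_labels):
        raise ValueError("runs must cover identical subjects in identical order")
    correct_a = run_a.predictions == run_a.true_labels
    correct_b = run_b.predictions == run_b.true_labels
    b = int((correct_a & ~correct_b).sum())   # a right, b wrong
    c = int((~correct_a & correct_b).sum())   # b right, a wrong
    table = np.array([[int((correct_a & correct_b).sum()), b],
                      [c, int((~correct_a & ~correct_b).sum())]])
    exact = (b + c) <= exact_max_discordant
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return McNemarResult(statistic=float(res.statistic),
                         pvalue=min(float(res.pvalue), 1.0),
                         only_a_correct=b, only_b_correct=c,
                         method="exact" if exact else "chi2_corrected")


def binomial_vs_chance(run: CVRunResult) -> float:
    """One-sided exact binomial p-value for #correct against chance (0.5)."""
    return float(sps.binomtest(run.n_correct, run.n, 0.5,
                               alternative="greater").pvalue)
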