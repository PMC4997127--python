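"""Stability selection: selection probabilities from repeated subsampling.

A single lasso-type fit at one lam is sample-sensitive; stability selection
instead fits the penalized discriminant on K random stratified subsamples of
the cohort and records, per feature j, the indicator c_j^(k) that its
coefficient was nonzero in subsample k.  The selection probability

    P_j(lam) = (1/K) * sum_k c_j^(k)(lam)

is thresholded (default 0.99, inclusive) to form the final feature set.
Subsamples are half-samples per class, drawn without replacement, each with
a pre-drawn child seed so serial and parallel execution agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .data import LabeledFeatureMatrix
from .plda import DirectionVector, plda_fit

logger = logging.getLogger(__name__)


@dataclass
class SelectionProfile:
    """Per-feature selection probabilities P_j(lam) from K subsamples."""

    P: np.ndarray
    K: int
    lam: float
    subsample_scheme: dict = field(default_factory=dict)
    indicator_matrix: np.ndarray | None = None  # K x p, optional to retain
    per_subset_iters: np.ndarray | None = None
    per_subset_converged: np.ndarray | None = None
    n_collapsed: int = 0  # subsets whose fit collapsed to the zero vector
    weight_sum: np.ndarray | None = None   # per-feature sum of nonzero coefs
    weight_count: np.ndarray | None = None  # per-feature count of nonzero coefs

    @property
    def mean_nonzero_weight(self) -> np.ndarray:
        """Average of nonzero coefficients over subsamples (NaN if never
        selected)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.weight_count > 0,
                            self.weight_sum / self.weight_count, np.nan)


def _stratified_subsample(data: LabeledFeatureMatrix, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    idx = []
    for mask in (data.mask_H, data.mask_D):
        members = np.flatnonzero(mask)
        k = int(np.floor(fraction * members.size))
        if k < 2:
            raise ValueError(
                f"subsample would retain {k} subjects of a class; need >= 2 "
                f"(fraction={fraction})")
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def _fit_one_subset(data: LabeledFeatureMatrix, lam: float, fraction: float,
                    seed: np.random.SeedSequence,
                    tol: float, max_iter: int) -> DirectionVector:
    rng = np.random.default_rng(seed)
    rows = _stratified_subsample(data, fraction, rng)
    return plda_fit(data.subset_subjects(rows), lam, tol=tol, max_iter=max_iter)


def run_stability(data: LabeledFeatureMatrix, lam: float, K: int = 100,
                  subsample_fraction: float = 0.5,
                  seed: int | np.random.SeedSequence | None = None,
                  keep_indicators: bool = True, n_jobs: int = 1,
                  tol: float = 1e-6, max_iter: int = 1000) -> SelectionProfile:
    """Selection probabilities from K stratified half-subsample pLDA fits.

    Each subsample draws floor(fraction * n_c) subjects per class without
    replacement.  A subsample where pLDA collapses to the zero vector
    contributes all-zero indicators (logged); features constant within a
    subsample get indicator 0 for that subsample only.  Fixed ``seed`` gives
    an identical profile regardless of ``n_jobs``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    child_seeds = root.spawn(K)

    if n_jobs == 1:
        fits = [_fit_one_subset(data, lam, subsample_fraction, s, tol, max_iter)
                for s in child_seeds]
    else:
        fits = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one_subset)(data, lam, subsample_fraction, s, tol,
                                     max_iter)
            for s in child_seeds)

    indicators = np.stack([f.v != 0.0 for f in fits]).astype(np.uint8)
    n_collapsed = int((~indicators.any(axis=1)).sum())
    if n_collapsed:
        logger.info("run_stability: %d/%d subsamples collapsed to v = 0 "
                    "(lam=%g)", n_collapsed, K, lam)
    weight_sum = np.zeros(data.p)
    for f in fits:
        weight_sum += f.v  # zeros contribute nothing
    weight_count = indicators.sum(axis=0).astype(np.int64)

    return SelectionProfile(
        P=indicators.mean(axis=0),
        K=K,
        lam=float(lam),
        subsample_scheme={"fraction": subsample_fraction, "seed": seed,
                          "stratified": True, "replacement": False},
        indicator_matrix=indicators if keep_indicators else None,
        per_subset_iters=np.array([f.n_iter for f in fits]),
        per_subset_converged=np.array([f.converged for f in fits]),
        n_collapsed=n_collapsed,
        weight_sum=weight_sum,
        weight_count=weight_count,
    )


def select_features(profile: SelectionProfile, threshold: float = 0.99) -> np.ndarray:
    """Features with P_j >= threshold (inclusive), in feature order.

    May be empty; callers decide how to handle an empty set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    # P_j is a multiple of 1/K; guard the inclusive boundary against rounding
    return np.flatnonzero(profile.P >= threshold - 1e-12)
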