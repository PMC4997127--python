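"""Two-class penalized linear discriminant analysis (pLDA).

Fisher's two-class discriminant seeks the direction v maximizing the
between-class over within-class variance,

    max_v  v' S_B v   subject to  v' S_W v = 1,

with S_B the between-class and S_W the within-class scatter matrix.  For two
classes S_B is the rank-1 outer product d d' of the class-mean difference
d = m_H - m_D, so v' S_B v = (d.v)^2 and neither scatter matrix is ever
materialized — every operation here is O(n p) memory.

The penalized variant imposes a lasso penalty weighted by the per-feature
within-class scale s_j, and replaces S_W by its diagonal estimate
S_W* = diag(s_1^2, ..., s_p^2) to avoid singularity at p >> n:

    max_v  (d.v)^2 - lam * sum_j s_j |v_j|   subject to  sum_j s_j^2 v_j^2 = 1.

At lam = 0 every feature contributes and the maximizer has the closed form
v_j proportional to d_j / s_j^2; as lam grows, coefficients are driven to
zero by soft-thresholding until, beyond a data-dependent lam_max, v collapses
to the zero vector.  The problem is solved by minorization-maximization (MM):
the quadratic (d.v)^2 is minorized by its tangent at the current iterate,
and the resulting linear-plus-lasso problem over the ellipsoid has a
closed-form soft-threshold solution, so the objective never decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledFeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClassStats:
    """Per-feature class means and diagonal within-class scatter.

    ``s2`` is the per-feature pooled within-class *sum of squares* (no
    degrees-of-freedom normalization), the diagonal of S_W.
    """

    m_H: np.ndarray
    m_D: np.ndarray
    n_H: int
    n_D: int
    s2: np.ndarray

    @property
    def d(self) -> np.ndarray:
        """Class-mean difference m_H - m_D."""
        return self.m_H - self.m_D

    @property
    def s(self) -> np.ndarray:
        """Per-feature within-class scale sqrt(s2)."""
        return np.sqrt(self.s2)

    @property
    def p(self) -> int:
        return self.m_H.shape[0]

    @property
    def constant_features(self) -> np.ndarray:
        """Indices of features constant within both classes (s2 == 0)."""
        return np.flatnonzero(self.s2 == 0.0)


@dataclass
class DirectionVector:
    """A sparse discriminant direction for one value of lam.

    Any nonzero ``v`` satisfies the ellipsoid constraint
    sum_j s2_j v_j^2 = 1 (to 1e-8) with sign fixed so d.v >= 0.
    """

    v: np.ndarray
    lam: float
    n_iter: int
    converged: bool
    objective: float = field(default=np.nan)

    @property
    def active_set(self) -> np.ndarray:
        """Indices of features with nonzero coefficients."""
        return np.flatnonzero(self.v != 0.0)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.v))


def compute_class_stats(data: LabeledFeatureMatrix) -> ClassStats:
    """Class means, mean difference, and diagonal within-class scatter.

    Raises if either class has fewer than 2 members.  Constant features
    (s2 == 0) are permitted here and flagged via
    :attr:`ClassStats.constant_features`.
    """
    if data.n_H < 2 or data.n_D < 2:
        raise ValueError(
            f"each class needs >= 2 members (got n_H={data.n_H}, n_D={data.n_D})")
    X_H = data.X[data.mask_H]
    X_D = data.X[data.mask_D]
    m_H = X_H.mean(axis=0)
    m_D = X_D.mean(axis=0)
    s2 = ((X_H - m_H) ** 2).sum(axis=0) + ((X_D - m_D) ** 2).sum(axis=0)
    # rounding can leave tiny negatives on constant features
    np.maximum(s2, 0.0, out=s2)
    return ClassStats(m_H=m_H, m_D=m_D, n_H=data.n_H, n_D=data.n_D, s2=s2)


def penalized_objective(v: np.ndarray, stats: ClassStats, lam: float) -> float:
    """(d.v)^2 - lam * sum_j s_j |v_j|  (the quantity MM maximizes)."""
    v = np.asarray(v, dtype=np.float64)
    return float(np.dot(stats.d, v) ** 2 - lam * np.sum(stats.s * np.abs(v)))


def _normalize(u: np.ndarray, stats: ClassStats) -> np.ndarray:
    """Scale to the constraint ellipsoid and fix sign so d.u >= 0."""
    norm = np.sqrt(np.sum(stats.s2 * u ** 2))
    if norm == 0.0:
        return np.zeros_like(u)
    u = u / norm
    if np.dot(stats.d, u) < 0:
        u = -u
    return u


def unpenalized_direction(stats: ClassStats) -> DirectionVector:
    """Closed-form maximizer at lam = 0: v_j proportional to d_j / s2_j.

    Requires all s2_j > 0; drop constant features first.  A zero mean
    difference (identical class means) yields the zero vector.
    """
    if (stats.s2 == 0.0).any():
        k = stats.constant_features
        raise ValueError(
            f"{k.size} features are constant within both classes (e.g. index "
            f"{k[0]}); drop constant features before fitting")
    with np.errstate(invalid="ignore"):
        u = stats.d / stats.s2
    v = _normalize(u, stats)
    return DirectionVector(v=v, lam=0.0, n_iter=0, converged=True,
                           objective=penalized_objective(v, stats, 0.0))


def mm_step(v_old: np.ndarray, stats: ClassStats, lam: float) -> np.ndarray:
    """One minorization-maximization update.

    Minorize (d.v)^2 at v_old by its tangent 2(d.v_old)(d.v) - (d.v_old)^2;
    the maximizer of the minorant minus the lasso penalty over the constraint
    ellipsoid is, coordinate-wise with b_j = 2 d_j (d.v_old),

        u_j = soft(b_j, lam * s_j) / s2_j,

    renormalized to the ellipsoid (zero vector if every coordinate is
    thresholded away).  soft(z, g) = sign(z) * max(|z| - g, 0); equality
    |b_j| = lam*s_j yields exactly 0.
    """
    b = 2.0 * stats.d * np.dot(stats.d, v_old)
    u = np.sign(b) * np.maximum(np.abs(b) - lam * stats.s, 0.0)
    if not u.any():
        return np.zeros_like(u)
    u = u / stats.s2
    return _normalize(u, stats)


def lambda_max(stats: ClassStats) -> float:
    """Smallest lam at which the first MM step from the lam=0 solution
    thresholds every coefficient to zero: max_j |2 d_j (d.v0)| / s_j."""
    v0 = unpenalized_direction(stats).v
    b = 2.0 * stats.d * np.dot(stats.d, v0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(b) / stats.s
    return float(np.max(ratio[np.isfinite(ratio)], initial=0.0))


def plda_fit(data: LabeledFeatureMatrix | ClassStats, lam: float,
             tol: float = 1e-6, max_iter: int = 1000) -> DirectionVector:
    """Fit the penalized discriminant direction for one lam.

    Iterates :func:`mm_step` from the lam=0 closed form until the relative
    change of the penalized objective drops below ``tol``, the iterate
    collapses to zero, or ``max_iter`` is reached (then ``converged=False``;
    no exception, so lam-grid sweeps complete).  Features constant within
    both classes are dropped before fitting (coefficient 0, logged).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    stats = data if isinstance(data, ClassStats) else compute_class_stats(data)

    keep = stats.s2 > 0.0
    p_full = stats.p
    dropped = int(p_full - keep.sum())
    if dropped:
        logger.warning("plda_fit: dropping %d constant feature(s)", dropped)
        stats = ClassStats(m_H=stats.m_H[keep], m_D=stats.m_D[keep],
                           n_H=stats.n_H, n_D=stats.n_D, s2=stats.s2[keep])
    if stats.p == 0:
        raise ValueError("no non-constant features to fit")

    if not stats.d.any():
        # identical class means: objective is maximized at 0 for any lam > 0
        result_v = np.zeros(p_full)
        return DirectionVector(v=result_v, lam=lam, n_iter=0, converged=True,
                               objective=0.0)

    v = unpenalized_direction(stats).v
    obj = penalized_objective(v, stats, lam)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        v_new = mm_step(v, stats, lam)
        obj_new = penalized_objective(v_new, stats, lam)
        if not v_new.any():
            v, obj = v_new, obj_new
            converged = True
            break
        if abs(obj_new - obj) <= tol * max(abs(obj), 1e-12):
            v, obj = v_new, obj_new
            converged = True
            break
        v, obj = v_new, obj_new

    if dropped:
        full = np.zeros(p_full)
        full[keep] = v
        v = full
    return DirectionVector(v=v, lam=float(lam), n_iter=n_iter,
                           converged=converged, objective=obj)
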