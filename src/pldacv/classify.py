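"""Linear classifiers on reduced features: LDA and linear soft-margin SVM.

Both produce a weight vector w and intercept b; a subject with feature row x
is predicted class D (patient) when w.x + b > 0 and class H otherwise — a
score exactly on the boundary deterministically breaks to H.

LDA is the Gaussian equal-covariance discriminant with equal priors.  With
p >> n the pooled covariance is singular; it is (pseudo-)inverted in the
subspace spanned by the class-centered training rows (dimension <= n - 2),
which reduces to classical LDA when the pooled covariance has full rank and
never materializes a p x p matrix.  A diagonal-covariance variant is
available for sensitivity analysis.

The SVM delegates to libsvm (scikit-learn's SVC with a linear kernel), hinge
loss, penalty C, no inner tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .data import LABEL_D, LABEL_H


@dataclass
class TrainedClassifier:
    """Linear decision rule: predict D iff w.x + b > 0."""

    kind: str  # {"lda", "linsvm"}
    w: np.ndarray
    b: float
    meta: dict = field(default_factory=dict)


def _split_classes(X: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels).astype(str)
    H = np.asarray(X, dtype=np.float64)[labels == LABEL_H]
    D = np.asarray(X, dtype=np.float64)[labels == LABEL_D]
    return H, D


def lda_train(X: np.ndarray, labels: np.ndarray,
              covariance: str = "pooled") -> TrainedClassifier:
    """Train the equal-prior Gaussian discriminant.

    ``covariance="pooled"`` uses the pooled within-class covariance,
    pseudo-inverted in the span of the centered training rows;
    ``covariance="diagonal"`` uses only its diagonal (features with zero
    within-class variance get weight 0).
    """
    X_H, X_D = _split_classes(X, labels)
    if len(X_H) < 2 or len(X_D) < 2:
        raise ValueError("LDA needs >= 2 training subjects per class")
    n = len(X_H) + len(X_D)
    m_H = X_H.mean(axis=0)
    m_D = X_D.mean(axis=0)
    delta = m_D - m_H
    Xc = np.vstack([X_H - m_H, X_D - m_D])  # class-centered rows

    if covariance == "pooled":
        # pooled cov = Xc' Xc / (n - 2); pseudo-invert via thin SVD of Xc
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s.max(initial=0.0) * max(Xc.shape) * np.finfo(np.float64).eps
        keep = s > tol
        inv_eig = (n - 2) / s[keep] ** 2  # 1 / eigenvalues of pooled cov
        w = Vt[keep].T @ (inv_eig * (Vt[keep] @ delta))
    elif covariance == "diagonal":
        var = (Xc ** 2).sum(axis=0) / (n - 2)
        w = np.where(var > 0, delta / np.where(var > 0, var, 1.0), 0.0)
    else:
        raise ValueError(f"unknown covariance {covariance!r}")

    b = -float(w @ (m_H + m_D) / 2.0)  # midpoint of projected class means
    return TrainedClassifier(kind="lda", w=w, b=b,
                             meta={"n_features": X.shape[1],
                                   "n_H": len(X_H), "n_D": len(X_D),
                                   "covariance": covariance,
                                   "priors": "equal"})


def svm_train(X: np.ndarray, labels: np.ndarray, C: float = 1.0) -> TrainedClassifier:
    """Train a soft-margin linear SVM (libsvm), penalty C, no tuning."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels).astype(str)
    if not (labels == LABEL_H).any() or not (labels == LABEL_D).any():
        raise ValueError("SVM needs both classes in the training set")
    y = np.where(labels == LABEL_D, 1, -1)
    try:
        svc = SVC(kernel="linear", C=C)
        svc.fit(X, y)
    except Exception as exc:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"linear SVM solver failed: {exc}") from exc
    # classes_ = [-1, 1]; positive decision value => class 1 = D
    return TrainedClassifier(kind="linsvm", w=svc.coef_.ravel().copy(),
                             b=float(svc.intercept_[0]),
                             meta={"n_features": X.shape[1], "C": C,
                                   "n_support": svc.n_support_.tolist()})


def decision_values(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training "
            f"({model.w.shape[0]})")
    return X @ model.w + model.b


def predict(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Predict one label per row; ties on the boundary go to H."""
    scores = decision_values(model, X)
    return np.where(scores > 0, LABEL_D, LABEL_H)


def train_classifier(kind: str, X: np.ndarray, labels: np.ndarray,
                     C: float = 1.0, covariance: str = "pooled") -> TrainedClassifier:
    """Dispatch on ``kind`` in {"lda", "linsvm"}."""
    if kind == "lda":
        return lda_train(X, labels, covariance=covariance)
    if kind == "linsvm":
        return svm_train(X, labels, C=C)
    raise ValueError(f"unknown classifier kind {kind!r}")
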