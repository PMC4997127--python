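"""Core data container: a masked-voxel feature matrix with binary class labels.

Subjects are rows, in-mask voxels (features) are columns.  The two classes
are coded ``"H"`` (healthy controls) and ``"D"`` (diseased / patients); class
``D`` is the positive class throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_H = "H"
LABEL_D = "D"


@dataclass
class LabeledFeatureMatrix:
    """n-subjects x p-features matrix with binary labels.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Feature matrix (arbitrary intensity units), no missing values.
    labels : ndarray of str, shape (n,)
        Class label per subject, each ``"H"`` or ``"D"``.
    feature_ids : ndarray of int, shape (p,), optional
        Identifiers tying columns to voxel positions (defaults to 0..p-1).
    subject_ids : sequence of str, optional
        Subject identifiers (defaults to ``s000, s001, ...``).
    """

    X: np.ndarray
    labels: np.ndarray
    feature_ids: np.ndarray | None = None
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object).astype(str)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D (n x p) array")
        n, p = self.X.shape
        if self.labels.shape != (n,):
            raise ValueError(f"labels has shape {self.labels.shape}, expected ({n},)")
        bad = set(np.unique(self.labels)) - {LABEL_H, LABEL_D}
        if bad:
            raise ValueError(f"labels must be 'H' or 'D'; got {sorted(bad)}")
        if n < 4:
            raise ValueError(f"need at least 4 subjects, got {n}")
        if self.n_H == 0 or self.n_D == 0:
            raise ValueError("both classes must be non-empty")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        if self.feature_ids is None:
            self.feature_ids = np.arange(p)
        else:
            self.feature_ids = np.asarray(self.feature_ids)
            if self.feature_ids.shape != (p,):
                raise ValueError("feature_ids length must equal number of features")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(n)]
        elif len(self.subject_ids) != n:
            raise ValueError("subject_ids length must equal number of subjects")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def mask_H(self) -> np.ndarray:
        return self.labels == LABEL_H

    @property
    def mask_D(self) -> np.ndarray:
        return self.labels == LABEL_D

    @property
    def n_H(self) -> int:
        return int((self.labels == LABEL_H).sum())

    @property
    def n_D(self) -> int:
        return int((self.labels == LABEL_D).sum())

    def subset_subjects(self, indices: np.ndarray) -> "LabeledFeatureMatrix":
        """Return a new matrix restricted to the given subject rows."""
        indices = np.asarray(indices, dtype=int)
        return LabeledFeatureMatrix(
            X=self.X[indices],
            labels=self.labels[indices],
            feature_ids=self.feature_ids,
            subject_ids=[self.subject_ids[i] for i in indices],
        )

    def subset_features(self, columns: np.ndarray) -> "LabeledFeatureMatrix":
        """Return a new matrix restricted to the given feature columns."""
        columns = np.asarray(columns, dtype=int)
        return LabeledFeatureMatrix(
            X=self.X[:, columns],
            labels=self.labels,
            feature_ids=self.feature_ids[columns],
            subject_ids=list(self.subject_ids),
        )
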