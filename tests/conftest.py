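import numpy as np
import pytest

import pldacv as p


@pytest.fixture
def toy_data():
    """Hand-checkable 4-subject, 2-feature cohort:
    H rows (0,0),(2,0); D rows (4,1),(6,3)."""
    return p.LabeledFeatureMatrix(
        X=np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 1.0], [6.0, 3.0]]),
        labels=np.array(["H", "H", "D", "D"]))


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signal fixture: planted cluster at 5x the noise sd."""
    data, truth = p.generate_cohort(p.strong_signal_spec(seed=3))
    return data, truth


@pytest.fixture(scope="session")
def null_cohort_2000():
    """Signal-free cohort on the flat 2000-feature demo geometry."""
    return p.generate_null_cohort(p.bias_demo_geometry(), seed=11)


@pytest.fixture(scope="session")
def tiny_geometry():
    """2x2x2 grid with a 3-voxel mask at known coordinates."""
    mask = np.zeros((2, 2, 2), dtype=bool)
    mask[0, 0, 0] = mask[0, 1, 1] = mask[1, 0, 1] = True
    return p.VolumeGeometry(dims=(2, 2, 2), mask=mask)


def make_run(correct, design="c"):
    """CVRunResult with the given per-subject correctness (all subjects D)."""
    correct = np.asarray(correct, dtype=bool)
    n = correct.size
    true_labels = np.array(["D"] * n)
    predictions = np.where(correct, "D", "H")
    tp = int(correct.sum())
    folds = [p.FoldRecord(test_subject=i, true_label="D",
                          predicted_label=predictions[i], n_selected=1,
                          reduction_refit=False) for i in range(n)]
    return p.CVRunResult(design=design, folds=folds, tp=tp, tn=0, fp=0,
                         fn=n - tp, n_features_per_fold=np.ones(n, dtype=int),
                         selection_counts=None,
                         subject_ids=[f"s{i:03d}" for i in range(n)],
                         true_labels=true_labels, predictions=predictions)
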