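import math

import numpy as np
import pytest
from scipy import stats as sps

import pldacv as p
from conftest import make_run


class TestLoocvBasics:
    def test_rc_folds_partition_subjects(self, null_cohort_2000):
        run = p.loocv_rc(null_cohort_2000,
                         p.ReducerSpec("ttest", p_threshold=0.01),
                         p.ClassifierSpec("lda"), seed=0)
        assert sorted(f.test_subject for f in run.folds) == \
            list(range(null_cohort_2000.n))
        assert run.tp + run.tn + run.fp + run.fn == run.n
        assert run.tp + run.fn == null_cohort_2000.n_D
        assert run.tn + run.fp == null_cohort_2000.n_H

    def test_design_c_fixes_selected_set_across_folds(self, null_cohort_2000):
        run = p.loocv_c(null_cohort_2000,
                        p.ReducerSpec("ttest", p_threshold=0.01),
                        p.ClassifierSpec("lda"), seed=0)
        assert np.unique(run.n_features_per_fold).size == 1
        counts = run.selection_counts
        assert set(np.unique(counts)) <= {0, run.n}

    def test_selection_count_map_bounds(self, null_cohort_2000):
        run = p.loocv_rc(null_cohort_2000,
                         p.ReducerSpec("ttest", p_threshold=0.01),
                         p.ClassifierSpec("lda"), seed=0)
        assert run.selection_counts.min() >= 0
        assert run.selection_counts.max() <= run.n

    def test_identity_reduction_makes_designs_coincide(self, null_cohort_2000):
        a = p.loocv_c(null_cohort_2000, p.ReducerSpec("none"),
                      p.ClassifierSpec("lda"), seed=1)
        b = p.loocv_rc(null_cohort_2000, p.ReducerSpec("none"),
                       p.ClassifierSpec("lda"), seed=2)
        assert np.array_equal(a.predictions, b.predictions)
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)

    def test_separable_cohort_classified_perfectly(self, strong_cohort):
        data, _ = strong_cohort
        for design in (p.loocv_c, p.loocv_rc):
            run = design(data, p.ReducerSpec("ttest", p_threshold=0.001),
                         p.ClassifierSpec("lda"), seed=3)
            assert run.n_correct == run.n

    def test_plda_reduction_recovers_signal_nested(self, strong_cohort):
        """Nested CV with stability-selected pLDA on the strong-signal
        cohort classifies essentially perfectly."""
        data, _ = strong_cohort
        run = p.loocv_rc(data, p.ReducerSpec("plda", lam=30.0, K=20),
                         p.ClassifierSpec("lda"), seed=4)
        assert p.compute_metrics(run).accuracy >= 90.0
        assert run.weight_sum is not None
        assert run.mean_weight_map is not None

    def test_fixed_seed_reproduces_run(self, null_cohort_2000):
        spec = p.ReducerSpec("plda", lam=p.DEMO_LAM, K=10)
        a = p.loocv_rc(null_cohort_2000, spec, p.ClassifierSpec("lda"), seed=9)
        b = p.loocv_rc(null_cohort_2000, spec, p.ClassifierSpec("lda"), seed=9)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.array_equal(a.selection_counts, b.selection_counts)
        assert np.array_equal(a.weight_sum, b.weight_sum)

    def test_empty_selection_error_mode(self, null_cohort_2000):
        spec = p.ReducerSpec("ttest", p_threshold=1e-12,
                             empty_action="error")
        with pytest.raises(RuntimeError, match="no features"):
            p.loocv_c(null_cohort_2000, spec, p.ClassifierSpec("lda"), seed=0)


class TestMetrics:
    def test_perfect_run(self):
        run = p.CVRunResult(design="c", folds=[], tp=52, tn=52, fp=0, fn=0,
                            n_features_per_fold=np.ones(104),
                            selection_counts=None)
        run.folds = [None] * 104  # only the count matters for n
        rep = p.compute_metrics(run)
        assert (rep.accuracy, rep.sensitivity, rep.specificity) == \
            (100.0, 100.0, 100.0)

    def test_hand_arithmetic_example(self):
        run = p.CVRunResult(design="c", folds=[None] * 104, tp=46, tn=44,
                            fp=8, fn=6, n_features_per_fold=np.ones(104),
                            selection_counts=None)
        rep = p.compute_metrics(run)
        assert rep.accuracy == pytest.approx(86.54, abs=0.005)
        assert rep.sensitivity == pytest.approx(88.46, abs=0.005)
        assert rep.specificity == pytest.approx(84.62, abs=0.005)

    def test_all_predicted_H(self):
        run = p.CVRunResult(design="c", folds=[None] * 104, tp=0, tn=52,
                            fp=0, fn=52, n_features_per_fold=np.ones(104),
                            selection_counts=None)
        rep = p.compute_metrics(run)
        assert rep.accuracy == 50.0
        assert rep.sensitivity == 0.0
        assert rep.specificity == 100.0

    def test_zero_denominator_flagged_not_zeroed(self):
        run = p.CVRunResult(design="c", folds=[None] * 4, tp=0, tn=2,
                            fp=2, fn=0, n_features_per_fold=np.ones(4),
                            selection_counts=None)
        rep = p.compute_metrics(run)
        assert math.isnan(rep.sensitivity)
        assert rep.undefined == ["sensitivity"]


class TestMcNemar:
    def test_identical_predictions_give_p_one(self):
        a = make_run([True] * 6 + [False] * 2)
        b = make_run([True] * 6 + [False] * 2)
        res = p.mcnemar_compare(a, b)
        assert res.pvalue == 1.0

    def test_chi2_branch_closed_form(self):
        # 10 discordant one way, 2 the other; continuity-corrected chi2
        a = make_run([True] * 18 + [False] * 2)
        b = make_run([True] * 8 + [False] * 10 + [True] * 2)
        res = p.mcnemar_compare(a, b, exact_max_discordant=5)
        assert res.method == "chi2_corrected"
        assert res.statistic == pytest.approx((abs(10 - 2) - 1) ** 2 / 12,
                                              abs=1e-6)
        assert res.pvalue == pytest.approx(sps.chi2.sf(49 / 12, 1), abs=1e-6)
        assert res.pvalue == pytest.approx(0.0433, abs=5e-4)

    def test_exact_branch_binomial(self):
        # 5 discordant pairs, all favoring run a: p = 2 * (1/2)^5
        a = make_run([True] * 10)
        b = make_run([True] * 5 + [False] * 5)
        res = p.mcnemar_compare(a, b)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.0625, abs=1e-12)

    def test_subject_mismatch_rejected(self):
        a = make_run([True] * 6)
        b = make_run([True] * 8)
        with pytest.raises(ValueError):
            p.mcnemar_compare(a, b)


class TestBinomialVsChance:
    def test_all_correct_closed_form(self):
        assert p.binomial_vs_chance(make_run([True] * 40)) == \
            pytest.approx(0.5 ** 40, rel=1e-9)

    def test_half_correct_matches_binomial_tail(self):
        run = make_run([True] * 20 + [False] * 20)
        expected = sps.binom.sf(19, 40, 0.5)
        assert p.binomial_vs_chance(run) == pytest.approx(expected, rel=1e-12)
        assert p.binomial_vs_chance(run) == pytest.approx(0.563, abs=1e-3)

    def test_none_correct_is_near_one(self):
        assert p.binomial_vs_chance(make_run([False] * 40)) > 0.999999
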