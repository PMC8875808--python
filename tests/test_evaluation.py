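"""Evaluation metrics: cross-validated curves, occurrence matrices,
ordinal confusion/MSE, weighted P/R/F1, threshold adjustment, ICC(3,1)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ebbs.battery import RiskCategory
from ebbs.evaluation import (
    adjust_thresholds,
    confusion_and_mse,
    crossval_curve,
    icc_3_1,
    occurrence_matrix,
    rater_table,
    subset_cv_predictions,
    weighted_prf,
)
from ebbs.selectors import SelectorConfig
from ebbs.session import SessionStep, SessionTrace

from conftest import TOY_TASK_IDS, make_separable_cohort, make_toy_battery


def make_trace(seq, preds=None):
    """Build a synthetic trace administering ``seq`` in order."""
    steps = []
    css = frozenset()
    for j, t in enumerate(seq):
        css = css | {t}
        steps.append(
            SessionStep(None if j == 0 else t, css, RiskCategory.LOW, 0.5 + 0.1 * j)
        )
    return SessionTrace("s", frozenset({seq[0]}), steps, "tasks_exhausted")


class TestConfusionAndMse:
    def test_perfect_predictions(self):
        cm, mse = confusion_and_mse([0, 1, 2], [0, 1, 2])
        assert np.array_equal(cm, np.eye(3, dtype=int))
        assert mse == 0.0

    def test_single_adjacent_error(self):
        _, mse = confusion_and_mse([0, 1, 2, 2], [0, 1, 2, 1])
        assert mse == 0.25

    def test_two_band_error(self):
        _, mse = confusion_and_mse([0, 2], [0, 0])  # one high<->low miss
        assert mse == 2.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_and_mse([0, 1], [0])


class TestWeightedPrf:
    def test_perfect(self):
        assert weighted_prf([0, 1, 2], [0, 1, 2]) == (1.0, 1.0, 1.0)

    def test_degenerate_single_class_predictions(self):
        _, rec, _ = weighted_prf([0, 1, 2, 0, 1, 2], [0, 0, 0, 0, 0, 0])
        assert rec == pytest.approx(1 / 3)

    def test_hand_computed_nine_subject_example(self):
        truth = [0, 0, 1, 1, 1, 2, 2, 2, 2]
        pred = [0, 1, 1, 1, 2, 2, 2, 2, 2]
        # per-class contingency arithmetic done by hand:
        #   P = (2*1 + 3*(2/3) + 4*(4/5)) / 9 = 7.2/9
        #   R = (2*(1/2) + 3*(2/3) + 4*1) / 9 = 7/9
        #   F1 = (2*(2/3) + 3*(2/3) + 4*(8/9)) / 9 = 62/81
        p, r, f = weighted_prf(truth, pred)
        assert p == pytest.approx(7.2 / 9)
        assert r == pytest.approx(7 / 9)
        assert f == pytest.approx(62 / 81)


class TestAdjustThresholds:
    def test_tau_zero_everything_high_risk(self):
        rng = np.random.default_rng(0)
        S = rng.random((20, 3))
        assert (adjust_thresholds(S, 0.0) == 0).all()

    def test_tau_one_without_unanimity_keeps_modal(self):
        S = np.array([[0.5, 0.3, 0.2], [0.1, 0.2, 0.7]])
        assert np.array_equal(adjust_thresholds(S, 1.0), [0, 2])

    def test_unanimous_row_still_reassigned_at_tau_one(self):
        S = np.array([[0.0, 0.0, 1.0]])
        assert adjust_thresholds(S, 1.0)[0] == 2

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_false_negatives_monotone_under_tau_sweep(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.dirichlet(np.ones(3), size=50)
        truth = rng.integers(0, 3, size=50)
        fns = []
        high_calls = []
        for tau in np.linspace(1.0, 0.0, 11):
            pred = adjust_thresholds(S, tau)
            fns.append(int(np.sum((truth == 0) & (pred != 0))))
            high_calls.append(int(np.sum(pred == 0)))
        assert fns == sorted(fns, reverse=True)  # non-increasing as tau falls
        assert high_calls == sorted(high_calls)

    def test_malformed_scores_rejected(self):
        with pytest.raises(ValueError):
            adjust_thresholds(np.array([[0.1, 0.2]]), 0.5)
        with pytest.raises(ValueError):
            adjust_thresholds(np.array([[-0.1, 0.5, 0.6]]), 0.5)


class TestIcc:
    def test_duplicated_rater_is_one(self):
        col = np.array([10.0, 25, 40, 55, 30, 18])
        assert icc_3_1(np.c_[col, col]) == pytest.approx(1.0)

    def test_matches_independent_two_way_anova(self):
        # 6-subject toy table checked against a reference implementation
        pg = pytest.importorskip("pingouin")
        A = [42.0, 18, 30, 51, 25, 47]
        D = [40.0, 20, 33, 50, 22, 45]
        ours = icc_3_1(np.c_[A, D])
        long = pd.DataFrame(
            {
                "subject": list(range(6)) * 2,
                "rater": ["A"] * 6 + ["D"] * 6,
                "score": A + D,
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        # consistency, single measure: labeled ICC3 or ICC(C,1) by version
        icc3 = float(ref.loc[ref["Type"].isin(["ICC3", "ICC(C,1)"]), "ICC"].iloc[0])
        assert ours == pytest.approx(icc3, abs=1e-10)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 50, size=10).astype(float)
        d = a + rng.normal(0, 2, size=10)
        base = icc_3_1(np.c_[a, d])
        shifted = icc_3_1(np.c_[a, d + 5.0])
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_undefined_without_subject_variance(self):
        with pytest.raises(ValueError):
            icc_3_1(np.array([[3.0, 3.0], [3.0, 3.0]]))

    def test_rater_table_min_column(self):
        t = rater_table([10, 40], [12, 35], ml=[11, 38])
        assert list(t["MIN(A,D)"]) == [10, 35]
        assert list(t.columns) == ["A", "D", "MIN(A,D)", "ML"]
        v = icc_3_1(t, ("A", "ML"))
        assert -1.0 <= v <= 1.0


class TestOccurrenceMatrix:
    def test_constant_complete_order_is_permutation_matrix(self, toy_battery):
        order = [3, 1, 4, 2]
        traces = [make_trace(order) for _ in range(5)]
        M = occurrence_matrix(traces, toy_battery)
        P = np.zeros((4, 4))
        for j, t in enumerate(order):
            P[t - 1, j] = 1.0
        assert np.array_equal(M, P)

    def test_single_partial_trace_on_standard_battery(self):
        from ebbs.battery import standard_battery

        M = occurrence_matrix([make_trace([9, 11, 8])], standard_battery())
        assert M[8, 0] == M[10, 1] == M[7, 2] == 1.0
        assert M.sum() == 3.0

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_invariants_on_random_traces(self, toy_battery, seed):
        rng = np.random.default_rng(seed)
        traces = []
        for _ in range(50):
            length = int(rng.integers(1, 5))
            seq = rng.permutation(list(TOY_TASK_IDS))[:length].tolist()
            traces.append(make_trace(seq))
        M = occurrence_matrix(traces, toy_battery)
        assert ((0 <= M) & (M <= 1)).all()
        reach = [np.mean([len(t.task_sequence) > j for t in traces]) for j in range(4)]
        assert np.allclose(M.sum(axis=0), reach)
        sums = M.sum(axis=0)
        assert all(a >= b - 1e-12 for a, b in zip(sums, sums[1:]))
        assert M.sum(axis=0)[0] == 1.0  # all sessions have a first task
        # brute-force position tally oracle
        for j in range(4):
            for t in TOY_TASK_IDS:
                n = sum(
                    1
                    for tr in traces
                    if len(tr.task_sequence) > j and tr.task_sequence[j] == t
                )
                assert M[t - 1, j] == pytest.approx(n / len(traces))

    def test_foreign_tasks_rejected(self, toy_battery):
        with pytest.raises(ValueError):
            occurrence_matrix([make_trace([9, 11])], toy_battery)

    def test_empty_trace_set_rejected(self, toy_battery):
        with pytest.raises(ValueError):
            occurrence_matrix([], toy_battery)


class TestCrossval:
    def test_separable_cohort_perfect_at_ct_one(self):
        cohort = make_separable_cohort(n_per_class=10)
        res = crossval_curve(
            cohort,
            SelectorConfig(method=1, confidence_threshold=1.0),
            thresholds=[1.0],
            n_folds=3,
            seed=0,
            initial_subset_size=1,
        )
        assert res.points[0].accuracy == 1.0
        # pooled accuracy equals the confusion-matrix trace fraction
        cm, _ = confusion_and_mse(res.truth[1.0], res.predicted[1.0])
        assert np.trace(cm) / cm.sum() == res.points[0].accuracy

    def test_mean_tasks_monotone_in_threshold(self):
        cohort = make_separable_cohort(n_per_class=12, seed=8)
        res = crossval_curve(
            cohort,
            SelectorConfig(method=1),
            thresholds=[0.5, 0.8, 0.95, 1.0],
            n_folds=3,
            seed=1,
        )
        means = [p.mean_tasks for p in res.points]
        assert means == sorted(means)

    def test_fold_hygiene_fingerprints(self):
        cohort = make_separable_cohort(n_per_class=8, seed=2)
        res = crossval_curve(
            cohort, SelectorConfig(method=1), thresholds=[0.9], n_folds=2, seed=3
        )
        for train_fp, full_fp in res.fold_fingerprints:
            assert train_fp != full_fp

    def test_stratification_error_when_class_too_small(self):
        cohort = make_separable_cohort(n_per_class=3)
        with pytest.raises(ValueError):
            crossval_curve(cohort, SelectorConfig(method=1), [0.9], n_folds=4)

    def test_subset_cv_predictions_shapes(self):
        cohort = make_separable_cohort(n_per_class=10, seed=4)
        truth, pred = subset_cv_predictions(cohort, frozenset({1, 2}), n_folds=3, seed=0)
        assert len(truth) == len(pred) == len(cohort)
        assert np.mean(truth == pred) == 1.0  # separable: subset suffices
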