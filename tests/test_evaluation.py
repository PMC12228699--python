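"""Metric definitions against independent counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemtaste.evaluation import (
    binary_reduction,
    confusion_matrix,
    evaluate,
    macro_average,
    multilabel_eval,
    ovr_auroc,
    per_class_metrics,
    weighted_average,
)
from chemtaste.labels import ABSTAIN, LABEL_ORDER, TasteLabel

S, B, SO, U, UN = LABEL_ORDER


def _counting_oracle(y_true, y_pred):
    """Independent per-sample counting of precision/recall/F1/accuracy."""
    n = len(y_true)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
    per_class = {}
    for c in range(5):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = (prec, rec, f1)
    return acc, per_class


class TestConfusionMatrix:
    def test_perfect_is_diagonal(self):
        y = [S, B, SO, U, UN] * 3
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([3, 3, 3, 3, 3]))

    def test_single_off_diagonal(self):
        cm = confusion_matrix([S], [B])
        expected = np.zeros((5, 5), dtype=int)
        expected[0, 1] = 1
        assert np.array_equal(cm, expected)

    def test_row_sums_are_class_counts(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 5, 200)
        p = rng.integers(0, 5, 200)
        cm = confusion_matrix(t, p)
        assert np.array_equal(cm.sum(axis=1), np.bincount(t, minlength=5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([S], [S, B])


class TestPerClassMetrics:
    def test_perfect_diagonal_all_ones(self):
        pc = per_class_metrics(np.diag([10] * 5))
        assert np.allclose(pc.precision, 1.0)
        assert np.allclose(pc.recall, 1.0)
        assert np.allclose(pc.f1, 1.0)

    def test_absent_class_zero_and_flagged(self):
        cm = np.diag([10, 10, 10, 10, 0])
        pc = per_class_metrics(cm)
        assert pc.precision[4] == pc.recall[4] == 0.0
        assert pc.undefined_flags[4]

    def test_embedded_two_class_hand_count(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0], cm[0, 1] = 8, 2
        cm[1, 0], cm[1, 1] = 3, 7
        pc = per_class_metrics(cm)
        assert pc.precision[1] == pytest.approx(7 / 9)
        assert pc.recall[1] == pytest.approx(0.7)
        # spec'd variant: precision_1 with column sum 11 when cm[1,0]=... hand-count
        cm2 = np.zeros((5, 5), dtype=int)
        cm2[1, 1], cm2[0, 1], cm2[1, 0] = 8, 3, 2
        pc2 = per_class_metrics(cm2)
        assert pc2.precision[1] == pytest.approx(8 / 11)
        assert pc2.recall[1] == pytest.approx(0.8)


class TestAverages:
    def test_macro_example(self):
        assert macro_average([1.0, 0.5, 0.0, 0.5, 1.0]) == pytest.approx(0.6)

    def test_weighted_example(self):
        assert weighted_average([0.9, 0.5, 0, 0, 0], [80, 20, 0, 0, 0]) == pytest.approx(0.82)

    def test_uniform_counts_weighted_equals_macro(self):
        vals = [0.3, 0.9, 0.1, 0.6, 0.5]
        assert weighted_average(vals, [7] * 5) == pytest.approx(macro_average(vals))

    def test_single_nonzero_class(self):
        assert weighted_average([0.1, 0.9, 0.2, 0.3, 0.4], [0, 5, 0, 0, 0]) == pytest.approx(0.9)

    def test_oracle_equivalence_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            vals = rng.random(5)
            counts = rng.integers(0, 50, 5)
            if counts.sum() == 0:
                counts[0] = 1
            brute_macro = sum(vals) / 5
            brute_weighted = sum(v * c for v, c in zip(vals, counts)) / counts.sum()
            assert abs(macro_average(vals) - brute_macro) <= 1e-12
            assert abs(weighted_average(vals, counts) - brute_weighted) <= 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(0, 1), min_size=5, max_size=5),
        counts=st.lists(st.integers(0, 1000), min_size=5, max_size=5).filter(
            lambda c: sum(c) > 0
        ),
    )
    def test_weighted_between_min_and_max_and_macro_ordering(self, vals, counts):
        """The weighted average lies in [min, max] of the per-class values,
        and uniform counts make it coincide with the macro average."""
        w = weighted_average(vals, counts)
        assert min(vals) - 1e-12 <= w <= max(vals) + 1e-12
        assert weighted_average(vals, [3] * 5) == pytest.approx(macro_average(vals))

    def test_empty_and_zero_errors(self):
        with pytest.raises(ValueError):
            macro_average([])
        with pytest.raises(ValueError):
            weighted_average([1, 1, 1, 1, 1], [0, 0, 0, 0, 0])


class TestOvrAuroc:
    def test_perfect_separation(self):
        y = [0] * 10 + [1] * 10
        P = np.zeros((20, 5))
        P[:10, 0], P[10:, 1] = 1.0, 1.0
        per_class, macro = ovr_auroc(y, P)
        assert per_class[0] == 1.0 and per_class[1] == 1.0
        assert macro == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        n = 2000
        y = rng.integers(0, 2, n)
        P = rng.random((n, 5))
        per_class, _ = ovr_auroc(y, P)
        assert per_class[0] == pytest.approx(0.5, abs=0.03)
        assert per_class[1] == pytest.approx(0.5, abs=0.03)

    def test_reversed_scores_complement(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 100)
        P = rng.random((100, 5))
        fwd, _ = ovr_auroc(y, P)
        rev, _ = ovr_auroc(y, 1 - P)
        assert rev[0] == pytest.approx(1 - fwd[0], abs=1e-12)

    def test_degenerate_class_skipped(self):
        y = [0] * 10  # only one class present
        P = np.random.default_rng(0).random((10, 5))
        per_class, macro = ovr_auroc(y, P)
        assert np.all(np.isnan(per_class))
        assert np.isnan(macro)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        y = rng.integers(0, 5, 300)
        P = rng.random((300, 5))
        per_class, _ = ovr_auroc(y, P)
        for c in range(5):
            ref = roc_auc_score((y == c).astype(int), P[:, c])
            assert per_class[c] == pytest.approx(ref, abs=1e-12)


class TestBinaryReduction:
    def test_all_positive_perfect(self):
        y = [S] * 10
        out = binary_reduction(y, y, S)
        assert out["accuracy"] == 1.0 and out["f1"] == 1.0

    def test_hand_count(self):
        y_true = [S, S, B, SO, U, UN, S, B]
        y_pred = [S, B, B, S, U, UN, S, S]
        out = binary_reduction(y_true, y_pred, S)
        # positives: true {0,1,6}; predicted {0,3,6,7}; tp=2 fp=2 fn=1
        assert out["precision"] == pytest.approx(2 / 4)
        assert out["recall"] == pytest.approx(2 / 3)
        assert out["f1"] == pytest.approx(2 * 0.5 * (2 / 3) / (0.5 + 2 / 3))
        assert out["accuracy"] == pytest.approx(5 / 8)

    def test_dominates_multiclass_accuracy_fuzz(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = rng.integers(5, 60)
            t = rng.integers(0, 5, n)
            p = rng.integers(0, 5, n)
            multi_acc = (t == p).mean()
            for c in range(5):
                out = binary_reduction(
                    [LABEL_ORDER[i] for i in t], [LABEL_ORDER[i] for i in p], LABEL_ORDER[c]
                )
                assert out["accuracy"] >= multi_acc

    def test_abstentions_excluded_with_support(self):
        y_true = [S, S, B, B]
        y_pred = [S, ABSTAIN, B, ABSTAIN]
        out = binary_reduction(y_true, y_pred, S)
        assert out["support"] == 0.5
        assert out["accuracy"] == 1.0


class TestMultilabelEval:
    def test_exact(self):
        out = multilabel_eval([[0.5, 0.3, 0.1, 0.05, 0.05]], [{S, B}])
        assert out.n_exact == 1

    def test_boundary_strictly_above(self):
        out = multilabel_eval([[0.2, 0.2, 0.2, 0.2, 0.2]], [{S, B}])
        assert out.n_exact == out.n_too_many == out.n_collapsed == 0
        assert out.n_other == 1  # empty predicted set

    def test_collapsed_correct(self):
        out = multilabel_eval([[0.9, 0.04, 0.02, 0.02, 0.02]], [{S, B}])
        assert out.n_collapsed == 1 and out.n_collapsed_correct == 1

    def test_collapsed_incorrect(self):
        out = multilabel_eval([[0.02, 0.04, 0.9, 0.02, 0.02]], [{S, B}])
        assert out.n_collapsed == 1 and out.n_collapsed_correct == 0

    def test_too_many(self):
        out = multilabel_eval([[0.3, 0.3, 0.25, 0.1, 0.05]], [{S, B}])
        assert out.n_too_many == 1


class TestEvaluate:
    def test_perfect_model_all_ones(self, clean_split, gbt_model):
        table = evaluate(gbt_model, clean_split.train[:100])
        assert table.accuracy == 1.0
        assert table.macro["f1"] == 1.0
        assert table.support_fraction == 1.0

    def test_table_matches_counting_oracle(self, clean_split, gbt_model):
        records = clean_split.test
        table = evaluate(gbt_model, records)
        y_true = [r.label.index for r in records]
        y_pred = [gbt_model.predict_label(r.canonical_smiles).index for r in records]
        acc, per_class = _counting_oracle(y_true, y_pred)
        assert table.accuracy == pytest.approx(acc, abs=1e-12)
        for c in range(5):
            assert table.precision[c] == pytest.approx(per_class[c][0], abs=1e-12)
            assert table.recall[c] == pytest.approx(per_class[c][1], abs=1e-12)
            assert table.f1[c] == pytest.approx(per_class[c][2], abs=1e-12)

    def test_confidence_on_form_invariant_model_identical(self, clean_split, gbt_model):
        records = clean_split.test[:40]
        plain = evaluate(gbt_model, records)
        conf = evaluate(gbt_model, records, confidence_k=5, seed=1)
        assert conf.support_fraction == 1.0
        assert conf.accuracy == pytest.approx(plain.accuracy)

    def test_empty_test_set(self, gbt_model):
        with pytest.raises(ValueError, match="empty"):
            evaluate(gbt_model, [])
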