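"""One-vs-rest metric suite against brute-force oracles and independent
library implementations (sklearn is the cross-check, never the path)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazecam.evaluation import (ConfusionMatrix, attention_alignment,
                                classification_report, cohens_kappa,
                                metrics_from_counts, multiclass_mcc,
                                one_vs_rest_counts, ovr_auc)


def random_cm(rng, k=3, max_count=30):
    counts = rng.integers(0, max_count, size=(k, k))
    if counts.sum() == 0:
        counts[0, 0] = 1
    return ConfusionMatrix(counts=counts)


def all_pairs_auc_oracle(scores, positive):
    """Count concordant pairs; ties count half."""
    pos = scores[positive]
    neg = scores[~positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestOneVsRestCounts:
    def test_diagonal_matrix_has_no_errors(self):
        cm = ConfusionMatrix(counts=np.diag([4, 7, 2]))
        for k in range(3):
            tp, fp, tn, fn = one_vs_rest_counts(cm, k)
            assert fp == 0 and fn == 0

    def test_hand_counted_two_class(self):
        cm = ConfusionMatrix(counts=np.array([[3, 1], [2, 4]]))
        assert one_vs_rest_counts(cm, 0) == (3, 1, 4, 2)
        assert one_vs_rest_counts(cm, 1) == (4, 2, 3, 1)

    def test_column_partition(self):
        rng = np.random.default_rng(0)
        cm = random_cm(rng, k=4)
        total = sum(one_vs_rest_counts(cm, k)[0] + one_vs_rest_counts(cm, k)[3]
                    for k in range(4))
        assert total == cm.total

    def test_index_error(self):
        with pytest.raises(IndexError):
            one_vs_rest_counts(ConfusionMatrix(counts=np.eye(3, dtype=int)), 3)


class TestMetricsFromCounts:
    def test_perfect(self):
        acc, pre, rec, f1, mcc = metrics_from_counts(50, 0, 50, 0)
        assert (acc, pre, rec, f1, mcc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_all_tp(self):
        with pytest.warns(UserWarning):
            acc, pre, rec, f1, mcc = metrics_from_counts(10, 0, 0, 0)
        assert acc == pre == rec == f1 == 1.0
        assert mcc == 0.0  # zero-denominator convention

    def test_formula_oracle(self):
        tp, fp, tn, fn = 3, 1, 4, 2
        acc, pre, rec, f1, mcc = metrics_from_counts(tp, fp, tn, fn)
        assert acc == pytest.approx((3 + 4) / 10)
        assert pre == pytest.approx(3 / 4)
        assert rec == pytest.approx(3 / 5)
        assert f1 == pytest.approx(2 * (3 / 4) * (3 / 5) / (3 / 4 + 3 / 5))
        assert mcc == pytest.approx((3 * 4 - 1 * 2)
                                    / np.sqrt(4 * 5 * 5 * 6), abs=1e-12)

    def test_mcc_matches_sklearn_binary(self):
        from sklearn.metrics import matthews_corrcoef
        rng = np.random.default_rng(1)
        for _ in range(20):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            tp = int(np.sum((y_pred == 1) & (y_true == 1)))
            fp = int(np.sum((y_pred == 1) & (y_true == 0)))
            tn = int(np.sum((y_pred == 0) & (y_true == 0)))
            fn = int(np.sum((y_pred == 0) & (y_true == 1)))
            *_, mcc = metrics_from_counts(tp, fp, tn, fn)
            assert mcc == pytest.approx(matthews_corrcoef(y_true, y_pred),
                                        abs=1e-10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(0, 0, 0, 0)


class TestCohensKappa:
    def test_perfect_diagonal(self):
        assert cohens_kappa(ConfusionMatrix(counts=np.diag([5, 5, 5]))) == 1.0

    def test_independent_predictions_zero(self):
        # all predictions class 0 on a balanced set: p0 = pe
        cm = ConfusionMatrix(counts=np.array([[10, 10], [0, 0]]))
        assert cohens_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_two_line_oracle_and_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(2)
        for _ in range(20):
            y_true = rng.integers(0, 3, 40)
            y_pred = rng.integers(0, 3, 40)
            cm = ConfusionMatrix.from_predictions(y_true, y_pred, 3)
            total = cm.total
            p0 = np.trace(cm.counts) / total
            pe = np.sum(cm.counts.sum(1) * cm.counts.sum(0)) / total ** 2
            assert cohens_kappa(cm) == pytest.approx((p0 - pe) / (1 - pe),
                                                     abs=1e-12)
            assert cohens_kappa(cm) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-10)

    def test_single_class_degenerate(self):
        cm = ConfusionMatrix(counts=np.array([[7, 0], [0, 0]]))
        with pytest.raises(ValueError):
            cohens_kappa(cm)


class TestOvrAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.05, 0.05, 0.9]])
        labels = np.array([0, 1, 2])
        assert ovr_auc(scores, labels) == 1.0

    def test_identical_scores_give_half(self):
        scores = np.full((9, 3), 1 / 3)
        labels = np.array([0, 1, 2] * 3)
        assert ovr_auc(scores, labels) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_all_pairs_oracle_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        labels = rng.integers(0, 3, n)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, n)
        raw = rng.random((n, 3))
        scores = raw / raw.sum(1, keepdims=True)
        expected = np.mean([all_pairs_auc_oracle(scores[:, k], labels == k)
                            for k in range(3)])
        assert ovr_auc(scores, labels) == expected  # exact

    def test_matches_sklearn_macro_ovr(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(6)
        labels = np.array([0, 1, 2] * 10)
        raw = rng.random((30, 3))
        scores = raw / raw.sum(1, keepdims=True)
        assert ovr_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores, multi_class="ovr", average="macro"),
            abs=1e-10)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            ovr_auc(np.ones((4, 3)), np.array([0, 1, 2, 0]))

    def test_absent_class_skipped(self):
        scores = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2],
                           [0.3, 0.3, 0.4], [0.5, 0.3, 0.2]])
        labels = np.array([0, 1, 0, 1])  # class 2 never appears
        val = ovr_auc(scores, labels)
        expected = np.mean([all_pairs_auc_oracle(scores[:, k], labels == k)
                            for k in (0, 1)])
        assert val == expected


class TestAttentionAlignment:
    def test_exact_match_is_one(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:10, 5:11] = True
        att = np.where(mask, 0.9, 0.1)
        assert attention_alignment(att, mask) == 1.0

    def test_disjoint_support_is_zero(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[:4, :4] = True
        att = np.full((16, 16), 0.1)
        att[10:, 10:] = 0.9
        assert attention_alignment(att, mask) == 0.0

    def test_gaussian_on_block_matches_pixel_count_oracle(self):
        from skimage.filters import threshold_otsu
        mask = np.zeros((64, 64), dtype=bool)
        mask[27:37, 27:37] = True
        yy, xx = np.mgrid[0:64, 0:64]
        att = np.exp(-((xx - 32.0) ** 2 + (yy - 32.0) ** 2) / (2 * 5.0 ** 2))
        level = threshold_otsu(att)
        binary = att > level
        oracle = np.sum(binary & mask) / np.sum(binary | mask)
        assert attention_alignment(att, mask) == pytest.approx(oracle)

    def test_fixed_threshold_strategy(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        att = np.linspace(0, 1, 64).reshape(8, 8)
        iou = attention_alignment(att, mask, threshold=0.5)
        binary = att > 0.5
        assert iou == np.sum(binary & mask) / np.sum(binary | mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            attention_alignment(np.random.default_rng(0).random((8, 8)),
                                np.zeros((8, 8), dtype=bool))


class TestClassificationReport:
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_macro_f1_is_mean_of_per_class_f1(self, seed):
        rng = np.random.default_rng(seed)
        cm = random_cm(rng, k=3)
        try:
            report = classification_report(cm)
        except ValueError:
            return  # degenerate single-class matrix
        per_f1 = [v["f1"] for v in report.per_class.values()]
        assert report.f1 == pytest.approx(np.mean(per_f1), abs=1e-12)
        per_pre = [v["precision"] for v in report.per_class.values()]
        assert report.precision == pytest.approx(np.mean(per_pre), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        raw = rng.random((60, 3))
        scores = raw / raw.sum(1, keepdims=True)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, 3)
        r1 = classification_report(cm, scores=scores, labels=y_true)
        perm = np.array([2, 0, 1])
        cm2 = ConfusionMatrix.from_predictions(perm[y_true], perm[y_pred], 3)
        inv = np.argsort(perm)
        r2 = classification_report(cm2, scores=scores[:, inv], labels=perm[y_true])
        for attr in ("accuracy", "kappa", "precision", "recall", "f1", "auc"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr),
                                                      abs=1e-12)

    def test_weighted_average_option(self):
        cm = ConfusionMatrix(counts=np.array([[8, 2, 0], [1, 5, 1], [0, 1, 2]]))
        macro = classification_report(cm, average="macro")
        weighted = classification_report(cm, average="weighted")
        supports = np.array([v["support"] for v in macro.per_class.values()])
        per_pre = np.array([v["precision"] for v in macro.per_class.values()])
        assert weighted.precision == pytest.approx(
            np.dot(per_pre, supports / supports.sum()), abs=1e-12)
        assert macro.accuracy == weighted.accuracy

    def test_generalized_mcc_available(self):
        cm = ConfusionMatrix(counts=np.array([[8, 2, 0], [1, 5, 1], [0, 1, 2]]))
        val = multiclass_mcc(cm)
        assert -1.0 <= val <= 1.0
        assert multiclass_mcc(ConfusionMatrix(counts=np.diag([3, 3, 3]))) == \
            pytest.approx(1.0)
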