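"""Metrics, confusion matrices and embedding separation diagnostics."""

import numpy as np
import pytest

import tripletlstm as tl
from tripletlstm.evaluation import metrics_from_predictions


def textbook_metrics(y_true, y_pred, n):
    """Independent formula-level recomputation from the confusion table."""
    cm = np.zeros((n, n), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    total = cm.sum()
    oa = np.trace(cm) / total
    pe = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0))) / total**2
    kappa = (oa - pe) / (1 - pe) if pe != 1 else 0.0
    prec = np.zeros(n)
    rec = np.zeros(n)
    f1 = np.zeros(n)
    for k in range(n):
        tp = cm[k, k]
        col = cm[:, k].sum()
        row = cm[k, :].sum()
        prec[k] = tp / col if col else 0.0
        rec[k] = tp / row if row else 0.0
        f1[k] = 2 * prec[k] * rec[k] / (prec[k] + rec[k]) if prec[k] + rec[k] else 0.0
    return oa, kappa, prec, rec, f1, cm


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 2, 1, 0])
        report, pair = metrics_from_predictions(y, y, 3)
        assert report.overall_accuracy == 1.0
        assert report.kappa == 1.0
        assert report.mean_f1 == report.mean_precision == report.mean_recall == 1.0
        np.testing.assert_array_equal(np.diag(pair.raw), [2, 2, 2])

    def test_constant_predictor_on_balanced_binary(self):
        # OA = 0.5 and kappa = 0 from the 2x2 table by hand
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.zeros(20, dtype=int)
        report, _ = metrics_from_predictions(y_true, y_pred, 2)
        assert report.overall_accuracy == pytest.approx(0.5)
        assert report.kappa == pytest.approx(0.0, abs=1e-12)

    def test_against_textbook_formulas_random_tables(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 8))
            size = int(rng.integers(20, 120))
            y_true = rng.integers(0, n, size=size)
            y_pred = rng.integers(0, n, size=size)
            report, pair = metrics_from_predictions(y_true, y_pred, n)
            oa, kappa, prec, rec, f1, cm = textbook_metrics(y_true, y_pred, n)
            assert report.overall_accuracy == pytest.approx(oa, abs=1e-9)
            assert report.kappa == pytest.approx(kappa, abs=1e-9)
            np.testing.assert_allclose(report.per_class_precision, prec, atol=1e-9)
            np.testing.assert_allclose(report.per_class_recall, rec, atol=1e-9)
            np.testing.assert_allclose(report.per_class_f1, f1, atol=1e-9)
            assert report.mean_f1 == pytest.approx(f1.mean(), abs=1e-9)
            np.testing.assert_array_equal(pair.raw, cm)

    def test_kappa_identity_from_marginals(self, rng):
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        report, pair = metrics_from_predictions(y_true, y_pred, 4)
        cm = pair.raw.astype(float)
        pe = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1))) / cm.sum() ** 2
        oa = report.overall_accuracy
        assert report.kappa == pytest.approx((oa - pe) / (1 - pe), abs=1e-9)

    def test_normalizations(self, rng):
        y_true = rng.integers(0, 5, size=300)
        y_pred = rng.integers(0, 5, size=300)
        _, pair = metrics_from_predictions(y_true, y_pred, 5)
        assert pair.raw.sum() == 300
        col_sums = pair.precision_normalized.sum(axis=0)
        row_sums = pair.recall_normalized.sum(axis=1)
        occupied_cols = pair.raw.sum(axis=0) > 0
        occupied_rows = pair.raw.sum(axis=1) > 0
        np.testing.assert_allclose(col_sums[occupied_cols], 1.0, atol=1e-9)
        np.testing.assert_allclose(row_sums[occupied_rows], 1.0, atol=1e-9)

    def test_permutation_invariance(self, rng):
        y_true = rng.integers(0, 3, size=90)
        y_pred = rng.integers(0, 3, size=90)
        perm = rng.permutation(90)
        r1, p1 = metrics_from_predictions(y_true, y_pred, 3)
        r2, p2 = metrics_from_predictions(y_true[perm], y_pred[perm], 3)
        assert r1.to_dict() == r2.to_dict()
        np.testing.assert_array_equal(p1.raw, p2.raw)

    def test_empty_class_counts_as_zero(self):
        # class 2 never appears in truth or prediction
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 1, 1, 1])
        report, _ = metrics_from_predictions(y_true, y_pred, 3)
        assert report.per_class_precision[2] == 0.0
        assert report.per_class_recall[2] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics_from_predictions(np.array([]), np.array([]), 2)


class TestEmbeddingSeparation:
    def test_two_point_masses(self):
        emb = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        labels = np.array([0, 0, 1, 1])
        stats = tl.embedding_separation(emb, labels)
        assert stats["within_class_distance"] == 0.0
        assert stats["between_class_distance"] == pytest.approx(5.0)
        assert stats["ratio"] == float("inf")

    def test_identical_embeddings_flagged_infinite(self):
        emb = np.zeros((6, 3))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert tl.embedding_separation(emb, labels)["ratio"] == float("inf")

    def test_matches_brute_force(self, rng):
        emb = rng.normal(size=(200, 8))
        labels = rng.integers(0, 5, size=200)
        stats = tl.embedding_separation(emb, labels)

        within_all = []
        centroids = []
        for c in range(5):
            pts = emb[labels == c]
            centroids.append(pts.mean(axis=0))
            dists = [
                np.linalg.norm(pts[i] - pts[j])
                for i in range(len(pts))
                for j in range(i + 1, len(pts))
            ]
            if dists:
                within_all.append(np.mean(dists))
        between = [
            np.linalg.norm(centroids[i] - centroids[j])
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        assert stats["within_class_distance"] == pytest.approx(np.mean(within_all))
        assert stats["between_class_distance"] == pytest.approx(np.mean(between))
        assert stats["ratio"] == pytest.approx(np.mean(between) / np.mean(within_all))

    def test_singleton_class_excluded_from_within(self):
        emb = np.array([[0.0], [1.0], [2.0], [10.0]])
        labels = np.array([0, 0, 0, 1])  # class 1 has one member
        stats = tl.embedding_separation(emb, labels)
        assert stats["within_class_distance"] == pytest.approx((1 + 2 + 1) / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            tl.embedding_separation(np.zeros((4, 2)), np.zeros(4, dtype=int))
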