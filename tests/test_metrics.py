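"""Confusion-matrix metrics vs independent counting oracles."""

from fractions import Fraction

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, cohen_kappa_score

from paddyfuse.metrics import (
    ConfusionMatrix,
    build_confusion,
    improvement_range,
    kappa,
    mapping_accuracy,
    metric_report,
    overall_accuracy,
    user_accuracy,
)

CM2 = ConfusionMatrix(np.array([[40, 10], [5, 45]]), ("a", "b"))


def oracle_metrics(truth, pred, classes):
    """Brute-force pair counting and exact rational metric arithmetic."""
    counts = {(a, p): 0 for a in classes for p in classes}
    for a, p in zip(truth, pred):
        counts[(a, p)] += 1
    N = len(truth)
    m = {c: counts[(c, c)] for c in classes}
    G = {c: sum(counts[(c, p)] for p in classes) for c in classes}
    C = {c: sum(counts[(a, c)] for a in classes) for c in classes}
    oa = Fraction(100) * sum(m.values()) / N
    chance = sum(G[c] * C[c] for c in classes)
    kap = (None if N * N == chance
           else Fraction(N * sum(m.values()) - chance, N * N - chance))
    ma = {c: None if G[c] == 0 else Fraction(100 * m[c], G[c]) for c in classes}
    ua = {c: None if C[c] == 0 else Fraction(100 * m[c], C[c]) for c in classes}
    return oa, kap, ma, ua


class TestBuildConfusion:
    def test_perfect_prediction_is_diagonal(self):
        cm = build_confusion(["a", "b", "a"], ["a", "b", "a"], ("a", "b"))
        assert np.array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_confusion([], [], ("a", "b"))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_confusion(["a"], ["z"], ("a", "b"))

    def test_marginals_consistent(self, rng):
        labels = rng.choice(list("abc"), size=50)
        preds = rng.choice(list("abc"), size=50)
        cm = build_confusion(labels, preds, ("a", "b", "c"))
        assert cm.G.sum() == cm.C.sum() == cm.N == 50


class TestWorkedValues:
    def test_overall_accuracy(self):
        assert overall_accuracy(CM2) == pytest.approx(85.0)

    def test_kappa(self):
        # (10000*85/100... directly: (100*85 - 5000)/(10000 - 5000) = 0.70
        assert kappa(CM2) == pytest.approx(0.70)

    def test_mapping_accuracy(self):
        assert mapping_accuracy(CM2, "a") == pytest.approx(80.0)

    def test_user_accuracy(self):
        assert user_accuracy(CM2, "a") == pytest.approx(100 * 40 / 45)

    def test_diagonal_matrix_perfect_scores(self):
        cm = ConfusionMatrix(np.diag([50, 50]), ("a", "b"))
        assert overall_accuracy(cm) == 100.0
        assert kappa(cm) == pytest.approx(1.0)
        assert user_accuracy(cm, "a") == mapping_accuracy(cm, "a") == 100.0

    def test_chance_level_kappa_zero(self):
        cm = ConfusionMatrix(np.full((2, 2), 25), ("a", "b"))
        assert kappa(cm) == pytest.approx(0.0)

    def test_all_off_diagonal_zero_oa(self):
        cm = ConfusionMatrix(np.array([[0, 30], [20, 0]]), ("a", "b"))
        assert overall_accuracy(cm) == 0.0

    def test_single_cell_kappa_undefined(self):
        cm = ConfusionMatrix(np.array([[10, 0], [0, 0]]), ("a", "b"))
        assert np.isnan(kappa(cm))

    def test_empty_class_per_class_metrics_undefined(self):
        cm = ConfusionMatrix(np.array([[10, 0], [0, 0]]), ("a", "b"))
        assert np.isnan(mapping_accuracy(cm, "b"))
        assert np.isnan(user_accuracy(cm, "b"))


def test_metrics_agree_with_brute_force_oracle():
    """1000 random label vectors, up to 5 classes and 200 samples."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n_cls = int(rng.integers(2, 6))
        n = int(rng.integers(1, 201))
        classes = tuple("abcde"[:n_cls])
        truth = rng.choice(classes, size=n)
        pred = rng.choice(classes, size=n)
        cm = build_confusion(truth, pred, classes)
        oa, kap, ma, ua = oracle_metrics(truth, pred, classes)
        assert overall_accuracy(cm) == pytest.approx(float(oa), abs=1e-10)
        if kap is None:
            assert np.isnan(kappa(cm))
        else:
            assert kappa(cm) == pytest.approx(float(kap), abs=1e-10)
        for c in classes:
            for got, want in ((mapping_accuracy(cm, c), ma[c]),
                              (user_accuracy(cm, c), ua[c])):
                if want is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(float(want), abs=1e-10)


def test_cross_check_against_sklearn(rng):
    truth = rng.choice(list("abcd"), size=300)
    pred = rng.choice(list("abcd"), size=300)
    cm = build_confusion(truth, pred, ("a", "b", "c", "d"))
    assert overall_accuracy(cm) == pytest.approx(
        100 * accuracy_score(truth, pred))
    assert kappa(cm) == pytest.approx(cohen_kappa_score(truth, pred))


def test_class_permutation_consistency(rng):
    truth = rng.choice(list("abc"), size=120)
    pred = rng.choice(list("abc"), size=120)
    cm1 = build_confusion(truth, pred, ("a", "b", "c"))
    cm2 = build_confusion(truth, pred, ("c", "a", "b"))
    assert overall_accuracy(cm1) == pytest.approx(overall_accuracy(cm2))
    assert kappa(cm1) == pytest.approx(kappa(cm2))
    for c in "abc":
        assert user_accuracy(cm1, c) == pytest.approx(user_accuracy(cm2, c))
        assert mapping_accuracy(cm1, c) == pytest.approx(mapping_accuracy(cm2, c))


def test_kappa_one_iff_no_confusion(rng):
    # diagonal with >= 2 non-empty classes -> exactly 1; any off-diagonal -> < 1
    cm = ConfusionMatrix(np.diag([7, 3, 5]), ("a", "b", "c"))
    assert kappa(cm) == pytest.approx(1.0)
    cm2 = ConfusionMatrix(np.array([[7, 1, 0], [0, 3, 0], [0, 0, 5]]),
                          ("a", "b", "c"))
    assert kappa(cm2) < 1.0


class TestImprovementRange:
    OA_TABLE = {"knn": 85.29, "rf": 87.33, "svm": 89.16, "gbdt": 90.07}
    KAPPA_TABLE = {"knn": 0.786, "rf": 0.817, "svm": 0.843, "gbdt": 0.855}
    UA_TABLE = {
        "knn": {"single": 86.30, "double": 85.78, "regenerated": 80.51, "other": 85.10},
        "rf": {"single": 90.69, "double": 83.47, "regenerated": 83.04, "other": 86.88},
        "svm": {"single": 91.16, "double": 86.02, "regenerated": 85.22, "other": 89.54},
        "gbdt": {"single": 89.91, "double": 88.21, "regenerated": 83.48, "other": 93.02},
    }
    MA_TABLE = {
        "knn": {"single": 86.96, "double": 83.91, "regenerated": 82.61, "other": 84.72},
        "rf": {"single": 84.69, "double": 90.00, "regenerated": 80.87, "other": 90.79},
        "svm": {"single": 87.71, "double": 88.26, "regenerated": 85.22, "other": 92.36},
        "gbdt": {"single": 92.63, "double": 87.83, "regenerated": 83.48, "other": 89.89},
    }
    FUSED_UA = {"single": 94.12, "double": 92.03, "regenerated": 89.47, "other": 93.36}
    FUSED_MA = {"single": 93.76, "double": 90.43, "regenerated": 88.70, "other": 93.36}

    def test_overall_accuracy_range(self):
        assert improvement_range(93.10, self.OA_TABLE) == (3.36, 9.16)

    def test_kappa_range(self):
        assert improvement_range(0.899, self.KAPPA_TABLE) == (5.15, 14.38)

    def test_user_accuracy_range_pooled_across_classes(self):
        assert improvement_range(self.FUSED_UA, self.UA_TABLE,
                                 paired_by_class=True) == (0.37, 11.13)

    def test_mapping_accuracy_range_pooled_across_classes(self):
        assert improvement_range(self.FUSED_MA, self.MA_TABLE,
                                 paired_by_class=True) == (0.48, 10.71)

    def test_no_change_is_zero_range(self):
        assert improvement_range(80.0, [80.0, 80.0]) == (0.0, 0.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            improvement_range(90.0, [0.0])


def test_metric_report_bundles_all_four(rng):
    truth = rng.choice(list("ab"), size=60)
    pred = rng.choice(list("ab"), size=60)
    cm = build_confusion(truth, pred, ("a", "b"))
    rep = metric_report(cm)
    assert rep.oa == overall_accuracy(cm)
    assert set(rep.ua) == set(rep.ma) == {"a", "b"}
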