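"""Confusion-matrix accuracy metrics.

Conventions: rows are actual classes, columns are predicted classes. With
``m_i`` the diagonal counts, ``G_i`` the row sums (actual samples of class i),
``C_i`` the column sums (predicted samples of class i) and ``N`` the grand
total:

* Overall Accuracy  OA = 100 * sum(m_i) / N
* Kappa = (N * sum(m_i) - sum(G_i * C_i)) / (N^2 - sum(G_i * C_i))
* Mapping Accuracy (producer's) MA_i = 100 * m_i / G_i
* User Accuracy                 UA_i = 100 * m_i / C_i

`improvement_range` expresses how much a fused classifier improves on each
base classifier, as RELATIVE percent change 100 * (fused - base) / base,
returning the (min, max) over all comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass(frozen=True)
class ConfusionMatrix:
    """n x n contingency counts, rows = actual, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", arr)
        n = len(self.classes)
        if arr.shape != (n, n):
            raise ValueError("counts must be n x n for n classes")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def m(self) -> np.ndarray:
        """Correctly classified counts per class (diagonal)."""
        return np.diag(self.counts)

    @property
    def G(self) -> np.ndarray:
        """Actual samples per class (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def C(self) -> np.ndarray:
        """Predicted samples per class (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def build_confusion(truth, predicted, classes: tuple[str, ...]) -> ConfusionMatrix:
    """Count (actual, predicted) label pairs into a confusion matrix."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    if truth.size == 0:
        raise ValueError("empty label vectors (N = 0)")
    known = set(classes)
    bad = [l for l in set(truth) | set(predicted) if l not in known]
    if bad:
        raise ValueError(f"labels outside class set: {sorted(map(str, bad))}")
    counts = _sk_confusion(truth, predicted, labels=list(classes))
    return ConfusionMatrix(counts, tuple(classes))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of samples on the diagonal."""
    if cm.N < 1:
        raise ValueError("empty confusion matrix")
    return 100.0 * cm.m.sum() / cm.N


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement; NaN when expected agreement is 1."""
    if cm.N < 1:
        raise ValueError("empty confusion matrix")
    N = cm.N
    chance = float(np.dot(cm.G.astype(float), cm.C.astype(float)))
    denom = N * N - chance
    if denom == 0:  # a single populated cell: agreement expected by chance
        return float("nan")
    return (N * cm.m.sum() - chance) / denom


def mapping_accuracy(cm: ConfusionMatrix, class_id: str) -> float:
    """Producer's accuracy: percent of actual class-i samples predicted i."""
    i = cm.classes.index(class_id)
    G_i = cm.G[i]
    if G_i == 0:
        return float("nan")
    return 100.0 * cm.m[i] / G_i


def user_accuracy(cm: ConfusionMatrix, class_id: str) -> float:
    """Percent of samples predicted class i that are truly class i."""
    i = cm.classes.index(class_id)
    C_i = cm.C[i]
    if C_i == 0:
        return float("nan")
    return 100.0 * cm.m[i] / C_i


@dataclass(frozen=True)
class MetricReport:
    """Validation scorecard of one classifier."""

    oa: float
    kappa: float
    ua: dict[str, float]
    ma: dict[str, float]


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    return MetricReport(
        oa=overall_accuracy(cm),
        kappa=kappa(cm),
        ua={c: user_accuracy(cm, c) for c in cm.classes},
        ma={c: mapping_accuracy(cm, c) for c in cm.classes},
    )


def improvement_range(fused, individual, paired_by_class: bool = False):
    """(min, max) relative percent improvement of fused over base values.

    Unpaired mode (scalar metrics such as OA or Kappa): ``fused`` is one
    scalar, ``individual`` the per-model scalars. Paired mode (per-class
    metrics such as UA or MA): ``fused`` maps class -> value and
    ``individual`` maps model -> {class -> value}; improvements are computed
    per (model, class) and pooled. Results are rounded to 2 decimals.
    """
    if paired_by_class:
        pairs = [
            (fused[c], v)
            for per_class in (individual.values()
                              if isinstance(individual, dict) else individual)
            for c, v in per_class.items()
        ]
    else:
        fused = float(fused)
        pairs = [(fused, float(v)) for v in
                 (individual.values() if isinstance(individual, dict)
                  else individual)]
    if not pairs:
        raise ValueError("no individual values supplied")
    if any(base <= 0 for _, base in pairs):
        raise ValueError("individual metric values must be positive")
    rel = [100.0 * (f - base) / base for f, base in pairs]
    return round(min(rel), 2), round(max(rel), 2)
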