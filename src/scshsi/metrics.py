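"""Confusion matrix and agreement metrics for tissue classification.

Implements the evaluation suite used throughout: Cohen's kappa (chance-
corrected agreement between predicted and ground-truth maps), overall
accuracy (OA), average accuracy (AA, macro-averaged recall) and per-class /
macro / weighted F1. Per-class TP/FP/TN/FN tallies come from one-vs-rest
readings of the C x C confusion matrix (rows = truth, cols = prediction).

Kappa uses the standard marginal-product expected agreement

    A_o = trace / total,   A_e = sum_c row_c * col_c / total^2,
    kappa = (A_o - A_e) / (1 - A_e)

``kappa_binary_literal`` additionally exposes a printed two-class variant of
the expected-agreement formula (one marginal product plus a bare marginal)
that circulates in the applied literature; it is provided for inspection
only and does not reduce to Cohen's form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix", "MetricsReport", "confusion_matrix", "cohens_kappa",
    "kappa_binary_literal", "overall_accuracy", "average_accuracy",
    "average_accuracy_literal", "f1_scores", "compute_report",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; ``counts[i, j]`` = samples of true class i predicted j."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square; got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(len(self.counts))]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class ``c`` against all others."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn


def confusion_matrix(true_labels, pred_labels, n_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    """Tally a C x C confusion matrix from 0-based label sequences."""
    true_labels = np.asarray(true_labels, dtype=np.int64).ravel()
    pred_labels = np.asarray(pred_labels, dtype=np.int64).ravel()
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"label sequences differ in length: {len(true_labels)} vs {len(pred_labels)}"
        )
    if len(true_labels) == 0:
        raise ValueError("cannot build a confusion matrix from empty label sequences")
    for name, arr in (("true", true_labels), ("pred", pred_labels)):
        bad = (arr < 0) | (arr >= n_classes)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{name} label {arr[i]} at index {i} outside [0, {n_classes})"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (true_labels, pred_labels), 1)
    return ConfusionMatrix(counts=counts,
                           class_names=list(class_names) if class_names else [])


def cohens_kappa(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Cohen's kappa with its observed and expected agreement, ``(kappa, A_o, A_e)``.

    If all mass sits in a single row/column pair (A_e = 1), kappa is returned
    as 0 by convention with a warning: agreement is then indistinguishable
    from chance.
    """
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix is empty")
    a_o = float(np.trace(cm.counts)) / total
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    a_e = float(rows @ cols) / total ** 2
    if a_e >= 1.0 - 1e-15:
        warnings.warn("expected agreement is 1 (degenerate marginals); kappa := 0")
        return 0.0, a_o, a_e
    return (a_o - a_e) / (1.0 - a_e), a_o, a_e


def kappa_binary_literal(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Two-class kappa using the as-printed expected-agreement variant.

    A_e = (FN+TN)/total * (FP+TN)/total + (TP+FN)/total — kept verbatim for
    comparison with :func:`cohens_kappa`; only defined for 2 x 2 matrices.
    """
    if cm.n_classes != 2:
        raise ValueError("literal binary kappa requires a 2x2 confusion matrix")
    tp, fp, tn, fn = cm.one_vs_rest(0)
    total = cm.total
    a_o = (tp + tn) / total
    a_e = ((fn + tn) / total) * ((fp + tn) / total) + (tp + fn) / total
    if a_e >= 1.0:
        warnings.warn("literal expected agreement >= 1; kappa := 0")
        return 0.0, a_o, a_e
    return (a_o - a_e) / (1.0 - a_e), a_o, a_e


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples: trace / total."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm.counts)) / cm.total


def average_accuracy(cm: ConfusionMatrix) -> float:
    """Macro-averaged per-class recall; empty classes are excluded with a warning."""
    rows = cm.counts.sum(axis=1)
    present = rows > 0
    if not present.any():
        raise ValueError("no class has any true samples")
    if not present.all():
        warnings.warn(f"{int((~present).sum())} class(es) have no true samples; "
                      "excluded from AA")
    recalls = np.diag(cm.counts)[present] / rows[present]
    return float(recalls.mean())


def average_accuracy_literal(cm: ConfusionMatrix) -> float:
    """As-printed AA variant: mean over classes of (TP+TN)/(TP+TN+FN), one-vs-rest."""
    vals = []
    for c in range(cm.n_classes):
        tp, _, tn, fn = cm.one_vs_rest(c)
        if tp + tn + fn:
            vals.append((tp + tn) / (tp + tn + fn))
    if not vals:
        raise ValueError("confusion matrix is empty")
    return float(np.mean(vals))


def f1_scores(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class F1 (one-vs-rest) and their unweighted macro mean.

    F1 = 2PR/(P+R); a class with P + R = 0 (never predicted, no true
    positives) scores 0 by convention.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    f1 = np.zeros(cm.n_classes)
    for c in range(cm.n_classes):
        tp, fp, _, fn = cm.one_vs_rest(c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1[c] = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return f1, float(f1.mean())


@dataclass
class MetricsReport:
    """Full evaluation record; serializes to JSON and a per-image CSV row."""

    kappa: float
    overall_accuracy: float
    average_accuracy: float
    f1_per_class: list[float]
    f1_macro: float
    f1_weighted: float
    observed_agreement: float
    expected_agreement: float
    class_names: list[str] = field(default_factory=list)
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "overall_accuracy": self.overall_accuracy,
            "average_accuracy": self.average_accuracy,
            "f1_per_class": dict(zip(self.class_names, self.f1_per_class)),
            "f1_macro": self.f1_macro,
            "f1_weighted": self.f1_weighted,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "n_samples": self.n_samples,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def csv_row(self) -> dict:
        row = {"kappa": self.kappa, "overall_accuracy": self.overall_accuracy,
               "average_accuracy": self.average_accuracy, "f1_macro": self.f1_macro,
               "f1_weighted": self.f1_weighted}
        row.update({f"f1_{n}": v for n, v in zip(self.class_names, self.f1_per_class)})
        return row


def compute_report(true_labels, pred_labels, n_classes: int,
                   class_names: list[str] | None = None) -> MetricsReport:
    """One-call evaluation: confusion matrix + kappa, OA, AA and F1 variants."""
    cm = confusion_matrix(true_labels, pred_labels, n_classes, class_names)
    kappa, a_o, a_e = cohens_kappa(cm)
    f1, f1_macro = f1_scores(cm)
    support = cm.counts.sum(axis=1)
    f1_weighted = float((f1 * support).sum() / support.sum())
    return MetricsReport(
        kappa=kappa,
        overall_accuracy=overall_accuracy(cm),
        average_accuracy=average_accuracy(cm),
        f1_per_class=[float(v) for v in f1],
        f1_macro=f1_macro,
        f1_weighted=f1_weighted,
        observed_agreement=a_o,
        expected_agreement=a_e,
        class_names=list(cm.class_names),
        n_samples=cm.total,
    )
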