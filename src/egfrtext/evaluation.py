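"""Extraction-accuracy evaluation: sampling, confusion matrix, metrics.

The validation protocol for a rule-based extractor is a manual chart
review: draw a simple random sample of test results, have a reviewer
record the actual result, and cross-tabulate actual against predicted
classes.  Four classes are used — detected, not detected, inconclusive
(a result qualified by a non-definitive clinician comment) and not tested
(cancelled / insufficient material).

Correctness scoring follows the review convention: a detected sample is
correct when predicted detected (with the right location, when full
predictions are available), a not-detected sample when predicted not
detected, and an inconclusive sample when extracted as not detected —
the definitive part of its report text.  Accuracy is correct/total;
sensitivity and specificity are the detected→detected and
not-detected→not-detected rates among their actual classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .extraction import EGFRResult

__all__ = [
    "CLASSES",
    "ValidationLabel",
    "ConfusionMatrix",
    "MetricsReport",
    "draw_sample",
    "predicted_class",
    "build_confusion",
    "compute_metrics",
    "location_metrics",
]

#: Fixed class order for confusion-matrix rows (actual) and columns (predicted).
CLASSES = ("detected", "not_detected", "inconclusive", "not_tested")

_STATUS_TO_CLASS = {
    "identified": "detected",
    "not_detected": "not_detected",
    "insufficient_dna": "not_tested",
    "cancelled": "not_tested",
    "unparseable": "inconclusive",
}


@dataclass(frozen=True)
class ValidationLabel:
    """One manually reviewed sample: record id plus its actual class."""

    record_id: str
    actual: str

    def __post_init__(self) -> None:
        if self.actual not in CLASSES:
            raise ValueError(f"unknown actual class {self.actual!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """4×4 actual-by-predicted count table in the fixed class order."""

    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (len(CLASSES), len(CLASSES)):
            raise ValueError(f"confusion matrix must be {len(CLASSES)}x{len(CLASSES)}")
        if (arr < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @classmethod
    def from_counts(cls, cells: Mapping[tuple[str, str], int]) -> "ConfusionMatrix":
        """Build from a sparse {(actual, predicted): count} mapping."""
        arr = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
        for (actual, predicted), count in cells.items():
            arr[CLASSES.index(actual), CLASSES.index(predicted)] = count
        return cls(counts=tuple(tuple(int(x) for x in row) for row in arr))

    def cell(self, actual: str, predicted: str) -> int:
        return self.counts[CLASSES.index(actual)][CLASSES.index(predicted)]

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    def to_dict(self) -> dict:
        return {
            "classes": list(CLASSES),
            "counts": [list(row) for row in self.counts],
        }


@dataclass(frozen=True)
class MetricsReport:
    """Headline metrics; a metric with a zero denominator is None, not 0."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    n_correct: int
    n_total: int
    correctness_rule: str

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "correctness_rule": self.correctness_rule,
        }


def draw_sample(ids: Sequence[str], n: int, seed: int) -> list[str]:
    """Seeded simple random sample without replacement, in original order."""
    if n > len(ids):
        raise ValueError(f"sample size {n} exceeds population size {len(ids)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(chosen)]


def predicted_class(prediction: EGFRResult | str) -> str:
    """Map an extraction status to its validation class."""
    status = prediction.status if isinstance(prediction, EGFRResult) else prediction
    try:
        return _STATUS_TO_CLASS[status]
    except KeyError:
        raise ValueError(f"unknown extraction status {status!r}") from None


def build_confusion(
    labels: Sequence[ValidationLabel],
    predictions: Mapping[str, EGFRResult | str],
) -> ConfusionMatrix:
    """Tally actual-vs-predicted counts for the labeled sample."""
    unmatched = [lab.record_id for lab in labels if lab.record_id not in predictions]
    if unmatched:
        raise ValueError(f"no prediction for labeled id(s): {unmatched}")
    arr = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for lab in labels:
        pred = predicted_class(predictions[lab.record_id])
        arr[CLASSES.index(lab.actual), CLASSES.index(pred)] += 1
    return ConfusionMatrix(counts=tuple(tuple(int(x) for x in row) for row in arr))


def compute_metrics(
    cm: ConfusionMatrix,
    sample_correct: Sequence[bool] | None = None,
) -> MetricsReport:
    """Accuracy / sensitivity / specificity from a confusion matrix.

    By the matrix-cell rule, correct extractions are detected→detected,
    not_detected→not_detected, and inconclusive→not_detected (the
    definitive part of a commented report is its not-detected result).
    When per-sample correctness flags are available — they additionally
    encode location agreement for detected samples, which the matrix alone
    cannot express — they override the cell rule for accuracy.
    """
    n_total = cm.total
    if sample_correct is not None:
        if len(sample_correct) != n_total:
            raise ValueError("one correctness flag per labeled sample required")
        n_correct = int(sum(bool(flag) for flag in sample_correct))
        rule = "per-sample flags (location-aware)"
    else:
        n_correct = (
            cm.cell("detected", "detected")
            + cm.cell("not_detected", "not_detected")
            + cm.cell("inconclusive", "not_detected")
        )
        rule = "matrix cells: det->det + nd->nd + inconclusive->nd"

    accuracy = n_correct / n_total if n_total else None
    actual_det = sum(cm.counts[CLASSES.index("detected")])
    actual_nd = sum(cm.counts[CLASSES.index("not_detected")])
    sensitivity = cm.cell("detected", "detected") / actual_det if actual_det else None
    specificity = cm.cell("not_detected", "not_detected") / actual_nd if actual_nd else None
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        n_correct=n_correct,
        n_total=n_total,
        correctness_rule=rule,
    )


def location_metrics(
    truth: Mapping[str, frozenset[str]],
    predictions: Mapping[str, frozenset[str]],
) -> dict[str, dict[str, float | int | None]]:
    """Supplementary per-location precision/recall.

    ``truth`` and ``predictions`` map record id → set of location names
    called for that record (empty set for non-identified results).
    """
    locations = sorted(set().union(*truth.values(), *predictions.values()) if truth else set())
    table: dict[str, dict[str, float | int | None]] = {}
    for loc in locations:
        tp = sum(1 for rid in truth if loc in truth[rid] and loc in predictions.get(rid, frozenset()))
        fp = sum(1 for rid in predictions if loc in predictions[rid] and loc not in truth.get(rid, frozenset()))
        fn = sum(1 for rid in truth if loc in truth[rid] and loc not in predictions.get(rid, frozenset()))
        table[loc] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
        }
    return table
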