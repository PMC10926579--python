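"""Validation protocol: sampling, confusion matrix, accuracy metrics."""

import pytest

from egfrtext import (
    CLASSES,
    ConfusionMatrix,
    EGFRResult,
    ValidationLabel,
    build_confusion,
    compute_metrics,
    draw_sample,
    location_metrics,
    predicted_class,
)

# The published chart-review outcome: 362 reviewed samples, all 35 detected
# and 308 not-detected samples extracted correctly, 10 inconclusive samples
# extracted as not detected (scored correct), 9 cancelled tests extracted
# as not detected (scored incorrect).
REVIEW_MATRIX = ConfusionMatrix.from_counts(
    {
        ("detected", "detected"): 35,
        ("not_detected", "not_detected"): 308,
        ("inconclusive", "not_detected"): 10,
        ("not_tested", "not_detected"): 9,
    }
)


class TestDrawSample:
    def test_sample_fraction_matches_review_design(self):
        ids = [f"id{i}" for i in range(8900)]
        sample = draw_sample(ids, 362, seed=1)
        assert len(sample) == len(set(sample)) == 362
        assert round(362 / 8900 * 100, 1) == 4.1  # ~4% review fraction

    def test_exhaustive_sample_returns_all_ids(self):
        ids = ["a", "b", "c"]
        assert draw_sample(ids, 3, seed=0) == ids

    def test_same_seed_same_sample(self):
        ids = [str(i) for i in range(100)]
        assert draw_sample(ids, 10, seed=7) == draw_sample(ids, 10, seed=7)

    def test_preserves_original_order(self):
        ids = [str(i) for i in range(50)]
        sample = draw_sample(ids, 20, seed=3)
        assert sample == sorted(sample, key=ids.index)

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            draw_sample(["a"], 2, seed=0)


class TestBuildConfusion:
    def test_review_outcome_matrix(self):
        labels = (
            [ValidationLabel(f"d{i}", "detected") for i in range(35)]
            + [ValidationLabel(f"n{i}", "not_detected") for i in range(308)]
            + [ValidationLabel(f"i{i}", "inconclusive") for i in range(10)]
            + [ValidationLabel(f"t{i}", "not_tested") for i in range(9)]
        )
        predictions = {lab.record_id: "identified" if lab.actual == "detected" else "not_detected" for lab in labels}
        cm = build_confusion(labels, predictions)
        assert cm == REVIEW_MATRIX

    def test_perfect_predictions_are_diagonal(self):
        status_for = {
            "detected": "identified",
            "not_detected": "not_detected",
            "inconclusive": "unparseable",
            "not_tested": "cancelled",
        }
        labels = [ValidationLabel(f"x{i}{c}", c) for c in CLASSES for i in range(2)]
        predictions = {lab.record_id: status_for[lab.actual] for lab in labels}
        cm = build_confusion(labels, predictions)
        for actual in CLASSES:
            for predicted in CLASSES:
                assert cm.cell(actual, predicted) == (2 if actual == predicted else 0)

    def test_empty_label_set_all_zero(self):
        cm = build_confusion([], {})
        assert cm.total == 0

    def test_unmatched_id_is_an_error(self):
        with pytest.raises(ValueError, match="orphan"):
            build_confusion([ValidationLabel("orphan", "detected")], {})

    def test_status_class_mapping(self):
        assert predicted_class("identified") == "detected"
        assert predicted_class("insufficient_dna") == "not_tested"
        assert predicted_class("cancelled") == "not_tested"
        assert predicted_class(EGFRResult(status="unparseable")) == "inconclusive"


class TestComputeMetrics:
    def test_review_matrix_headline_metrics(self):
        metrics = compute_metrics(REVIEW_MATRIX)
        assert (metrics.n_correct, metrics.n_total) == (353, 362)
        assert metrics.accuracy == pytest.approx(353 / 362)
        assert round(metrics.accuracy * 100, 1) == 97.5
        assert metrics.sensitivity == 1.0
        assert metrics.specificity == 1.0

    def test_all_correct_two_samples(self):
        cm = ConfusionMatrix.from_counts({("detected", "detected"): 1, ("not_detected", "not_detected"): 1})
        assert compute_metrics(cm).accuracy == 1.0

    def test_all_detected_missed_gives_zero_sensitivity(self):
        cm = ConfusionMatrix.from_counts({("detected", "not_detected"): 5})
        metrics = compute_metrics(cm)
        assert metrics.sensitivity == 0.0
        assert metrics.specificity is None  # no actual not-detected samples

    def test_zero_denominators_are_undefined_not_zero(self):
        metrics = compute_metrics(ConfusionMatrix.from_counts({}))
        assert metrics.accuracy is None and metrics.sensitivity is None and metrics.specificity is None

    def test_per_sample_flags_override_cell_rule(self):
        # Location-aware review: one detected sample has the wrong location,
        # which the matrix cells cannot see.
        cm = ConfusionMatrix.from_counts({("detected", "detected"): 2})
        metrics = compute_metrics(cm, sample_correct=[True, False])
        assert metrics.n_correct == 1 and metrics.accuracy == 0.5

    def test_accuracy_invariant_under_label_order(self):
        labels = [
            ValidationLabel("a", "detected"),
            ValidationLabel("b", "not_detected"),
            ValidationLabel("c", "not_tested"),
        ]
        predictions = {"a": "identified", "b": "not_detected", "c": "not_detected"}
        fwd = compute_metrics(build_confusion(labels, predictions))
        rev = compute_metrics(build_confusion(list(reversed(labels)), predictions))
        assert fwd == rev


class TestLocationMetrics:
    def test_precision_recall_per_location(self):
        truth = {
            "r1": frozenset({"exon19"}),
            "r2": frozenset({"T790M", "L858R"}),
            "r3": frozenset(),
        }
        predictions = {
            "r1": frozenset({"exon19"}),
            "r2": frozenset({"T790M"}),
            "r3": frozenset({"L858R"}),
        }
        table = location_metrics(truth, predictions)
        assert table["exon19"]["precision"] == 1.0 and table["exon19"]["recall"] == 1.0
        assert table["T790M"]["recall"] == 1.0
        assert table["L858R"] == {"tp": 0, "fp": 1, "fn": 1, "precision": 0.0, "recall": 0.0}
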