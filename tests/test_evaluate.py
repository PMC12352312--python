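import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheetscribe.core import BoundingBox, FieldClass, FieldRecord, LabelClass, SpecimenRecord
from sheetscribe.evaluate import (
    GroundTruthRecord,
    average_precision,
    detection_f1,
    field_similarity,
    mean_average_precision,
    normalize_for_eval,
    summarize,
)


class TestNormalizeForEval:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Mélu-Tag!", "mlutag"),
            ("A.S.George", "asgeorge"),
            ("", ""),
            ("  Two   words ", "two words"),
            ("37°48'S", "3748s"),
        ],
    )
    def test_rules(self, text, expected):
        assert normalize_for_eval(text) == expected


class TestFieldSimilarity:
    def test_both_absent_excluded(self):
        assert field_similarity(None, None) is None
        assert field_similarity("", "  ") is None

    def test_one_side_present_scores_zero(self):
        assert field_similarity("Rubiaceae", None) == 0.0
        assert field_similarity(None, "Rubiaceae") == 0.0

    def test_case_insensitive_exact(self):
        assert field_similarity("rubiaceae", "Rubiaceae") == 1.0

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.one_of(st.none(), st.text(alphabet="abc ", max_size=8)),
        b=st.one_of(st.none(), st.text(alphabet="abc ", max_size=8)),
    )
    def test_presence_symmetric_and_bounded(self, a, b):
        # the underlying Ratcliff/Obershelp value is order-sensitive in
        # rare tie cases (as is difflib's), so exact value symmetry is not
        # asserted; presence/exclusion handling and bounds are symmetric
        va, vb = field_similarity(a, b), field_similarity(b, a)
        assert (va is None) == (vb is None)
        assert (va == 0.0) == (vb == 0.0) or (a and b)
        for v in (va, vb):
            assert v is None or 0.0 <= v <= 1.0


def _record(sheet_id, label_class, fields):
    rec = SpecimenRecord(sheet_id=sheet_id, label_class=label_class)
    for fc, text in fields.items():
        rec.fields[fc] = FieldRecord(chosen_text=text)
    return rec


class TestSummarize:
    def _truths(self):
        return [
            GroundTruthRecord(
                "s1",
                LabelClass.printed,
                {FieldClass.genus: "Acacia", FieldClass.species: "dealbata"},
            ),
            GroundTruthRecord(
                "s2", LabelClass.handwritten, {FieldClass.genus: "Banksia"}
            ),
        ]

    def test_identity_scores_100_everywhere(self):
        truths = self._truths()
        preds = [_record(t.sheet_id, t.label_class, t.fields) for t in truths]
        s = summarize(preds, truths)
        assert (
            s.label_classification_accuracy,
            s.field_present_accuracy,
            s.similarity_median,
            s.similarity_mean,
        ) == (100.0, 100.0, 100.0, 100.0)

    def test_all_empty_predictions_score_zero_mean(self):
        truths = self._truths()
        preds = [_record(t.sheet_id, t.label_class, {}) for t in truths]
        s = summarize(preds, truths)
        assert s.similarity_mean == 0.0
        assert s.field_present_accuracy == 0.0

    def test_one_wrong_label_class_of_two_gives_50(self):
        truths = self._truths()
        preds = [_record(t.sheet_id, t.label_class, t.fields) for t in truths]
        preds[1].label_class = LabelClass.printed
        assert summarize(preds, truths).label_classification_accuracy == 50.0

    def test_orphan_sheets_raise_listing_ids(self):
        truths = self._truths()
        preds = [_record("s1", LabelClass.printed, {})]
        with pytest.raises(ValueError, match="s2"):
            summarize(preds, truths)

    def test_spurious_predicted_field_counts_against_presence(self):
        truths = self._truths()
        preds = [_record(t.sheet_id, t.label_class, dict(t.fields)) for t in truths]
        preds[1].fields[FieldClass.locality] = FieldRecord(chosen_text="nowhere")
        s = summarize(preds, truths)
        # 3 agreeing pairs + 1 disagreeing = 75%
        assert s.field_present_accuracy == 75.0


class TestDetectionMetrics:
    def test_perfect_predictions_give_f1_one(self):
        truths = [
            ("a", BoundingBox(0, 0, 10, 10)),
            ("b", BoundingBox(20, 20, 30, 30)),
        ]
        preds = [(c, b, 0.9) for c, b in truths]
        assert all(v == (1.0, 1.0, 1.0) for v in detection_f1(preds, truths).values())

    def test_no_predictions_recall_and_f1_zero(self):
        truths = [("a", BoundingBox(0, 0, 10, 10))]
        assert detection_f1([], truths)["a"] == (0.0, 0.0, 0.0)

    def test_two_truths_one_matching_pred_f1_two_thirds(self):
        truths = [
            ("a", BoundingBox(0, 0, 10, 10)),
            ("a", BoundingBox(20, 20, 30, 30)),
        ]
        preds = [("a", BoundingBox(0, 0, 10, 10), 0.9)]
        p, r, f1 = detection_f1(preds, truths)["a"]
        assert (p, r) == (1.0, 0.5)
        assert f1 == pytest.approx(2 / 3)

    def test_iou_below_threshold_does_not_match(self):
        truths = [("a", BoundingBox(0, 0, 10, 10))]
        preds = [("a", BoundingBox(8, 8, 18, 18), 0.9)]  # IoU ~ 0.02
        assert detection_f1(preds, truths, 0.5)["a"] == (0.0, 0.0, 0.0)

    def test_greedy_matching_is_one_to_one(self):
        truths = [("a", BoundingBox(0, 0, 10, 10))]
        preds = [
            ("a", BoundingBox(0, 0, 10, 10), 0.9),
            ("a", BoundingBox(1, 1, 11, 11), 0.8),
        ]
        p, r, _ = detection_f1(preds, truths)["a"]
        assert (p, r) == (0.5, 1.0)

    def test_map_one_on_perfect_predictions(self):
        truths = [
            ("a", BoundingBox(0, 0, 10, 10)),
            ("b", BoundingBox(20, 20, 30, 30)),
        ]
        preds = [(c, b, 0.9) for c, b in truths]
        assert mean_average_precision(preds, truths) == 1.0
        assert average_precision(preds, truths) == {"a": 1.0, "b": 1.0}

    def test_invalid_iou_threshold_rejected(self):
        with pytest.raises(ValueError):
            detection_f1([], [], iou_threshold=0.0)
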