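"""The matching core: formatting, Gestalt similarity, reference
correction and engine arbitration."""

import difflib
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheetscribe.core import FieldClass, LabelClass, TextCandidate
from sheetscribe.taxonmatch import (
    MatchConfig,
    ReferenceLists,
    arbitrate,
    assign_scores,
    closest_match,
    engine_preference,
    gestalt_similarity,
    match_candidates,
    normalize_field,
)

from .oracles import brute_gestalt


class TestNormalizeField:
    @pytest.mark.parametrize(
        "text, field, expected",
        [
            ("RUBIACEAE,", FieldClass.family, "Rubiaceae"),
            (" torulosa.", FieldClass.species, "torulosa"),
            ("", FieldClass.genus, ""),
            ("ahnfeltia", FieldClass.genus, "Ahnfeltia"),
            ("..VAR. Minor ", FieldClass.infraspecific_taxon, "var. minor"),
            ("  A.S.George ", FieldClass.authority, "A.S.George"),
            (" 12 km N of Orbost ", FieldClass.locality, "12 km N of Orbost"),
        ],
    )
    def test_formatting_rules(self, text, field, expected):
        assert normalize_field(text, field) == expected


class TestGestaltSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("abc", "abc", 1.0),
            ("", "x", 0.0),
            ("", "", 1.0),
            ("serulata", "sertulata", 16 / 17),
            ("ahnfletia", "ahnfeltia", 16 / 18),
            ("odontitis", "odontites", 16 / 18),
            ("sisymbrifolium", "sisymbriifolium", 28 / 29),
        ],
    )
    def test_worked_values_frozen_from_oracle(self, a, b, expected):
        assert gestalt_similarity(a, b) == pytest.approx(expected)
        assert brute_gestalt(a, b) == pytest.approx(expected)

    def test_exhaustive_equivalence_tiny_alphabet(self):
        """Matches the brute-force oracle on every string pair of length
        <= 3 over {a, b, c} (the longer exhaustive sweep lives in the
        acceptance suite)."""
        strings = [""]
        for n in range(1, 4):
            strings += ["".join(p) for p in itertools.product("abc", repeat=n)]
        for a, b in itertools.product(strings, repeat=2):
            assert gestalt_similarity(a, b) == brute_gestalt(a, b), (a, b)

    @settings(max_examples=300, deadline=None)
    @given(
        a=st.text(alphabet="abcdef", max_size=12),
        b=st.text(alphabet="abcdef", max_size=12),
    )
    def test_oracle_and_difflib_agree_on_random_pairs(self, a, b):
        v = gestalt_similarity(a, b)
        assert 0.0 <= v <= 1.0
        assert v == brute_gestalt(a, b)
        # stdlib Ratcliff/Obershelp as an independent library cross-check
        assert v == pytest.approx(
            difflib.SequenceMatcher(None, a, b).ratio(), abs=1e-12
        )
        assert (v == 1.0) == (a == b)


class TestReferenceLists:
    def test_duplicates_dropped_order_preserved(self):
        refs = ReferenceLists({"genus": ["B", "A", "B", "C", "A"]})
        assert refs.get("genus") == ["B", "A", "C"]

    def test_unknown_list_name_raises(self):
        with pytest.raises(ValueError):
            ReferenceLists({"subgenus": ["X"]})
        with pytest.raises(ValueError):
            ReferenceLists({}).get("subgenus")

    def test_comment_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "genus.txt"
        p.write_text("# header\nAcacia\n\nBanksia\n", encoding="utf-8")
        refs = ReferenceLists.from_files({"genus": p})
        assert refs.get("genus") == ["Acacia", "Banksia"]

    def test_bundled_fixture_contains_worked_example_names(self, refs):
        assert "Ahnfeltia" in refs.get("genus")
        species = refs.get("species")
        # the tie between sertulata and serrulata resolves by list order
        assert species.index("sertulata") < species.index("serrulata")


class TestClosestMatch:
    @pytest.mark.parametrize(
        "query, list_name, expected_name, expected_score",
        [
            ("Ahnfletia", "genus", "Ahnfeltia", 16 / 18),
            ("Odontitis", "genus", "Odontites", 16 / 18),
            ("sisymbrifolium", "species", "sisymbriifolium", 28 / 29),
            ("serulata", "species", "sertulata", 16 / 17),
        ],
    )
    def test_misspelling_corrections(
        self, refs, query, list_name, expected_name, expected_score
    ):
        r = closest_match(query, list_name, refs)
        assert r.matched_name == expected_name
        assert r.changed
        assert r.score == pytest.approx(expected_score)
        assert r.score >= 0.8

    def test_exact_hit_scores_one_unchanged(self, refs):
        r = closest_match("Ahnfeltia", "genus", refs)
        assert (r.score, r.changed, r.matched_name) == (1.0, False, "Ahnfeltia")

    def test_exact_hit_is_case_insensitive(self, refs):
        r = closest_match("ahnfeltia", "genus", refs)
        assert r.score == 1.0 and not r.changed

    def test_nothing_close_scores_zero(self, refs):
        r = closest_match("Xyzabc", "genus", refs)
        assert (r.score, r.matched_name, r.changed) == (0.0, None, False)

    def test_empty_query_never_matches(self, refs):
        r = closest_match("", "genus", refs)
        assert r.score == 0.0 and r.matched_name is None

    def test_disabled_matching_passes_through(self, refs):
        r = closest_match("Ahnfletia", "genus", refs, MatchConfig(enabled=False))
        assert (r.query, r.matched_name, r.changed, r.score) == (
            "Ahnfletia",
            None,
            False,
            0.0,
        )

    def test_result_always_from_reference_list(self, refs):
        for q in ("Ahnfletia", "Banksiaa", "serulata", "zzz"):
            for ln in ("genus", "species"):
                r = closest_match(q, ln, refs)
                assert r.matched_name is None or r.matched_name in refs.get(ln)

    def test_raising_threshold_never_increases_changes(self, refs):
        queries = ["Ahnfletia", "Odontitis", "Banksi", "Eucalipt", "zzz", "Photinia"]
        changed_counts = []
        for thr in (0.6, 0.8, 0.9, 0.95, 1.0):
            cfg = MatchConfig(threshold=thr)
            changed_counts.append(
                sum(closest_match(q, "genus", refs, cfg).changed for q in queries)
            )
        assert changed_counts == sorted(changed_counts, reverse=True)


def _cand(fc, engine, raw):
    return TextCandidate(fc, engine, raw, normalize_field(raw, fc))


class TestArbitrate:
    def _matches(self, refs, cands, enabled=True):
        return match_candidates(cands, refs, MatchConfig(enabled=enabled))

    def test_strictly_better_engine_wins_printed_label(self, refs):
        cands = [
            _cand(FieldClass.genus, "tesseract", "Ahnfeltia"),
            _cand(FieldClass.genus, "trocr", "Xyzabc"),
            _cand(FieldClass.locality, "tesseract", "near Orbost"),
            _cand(FieldClass.locality, "trocr", "noar Orbsot"),
        ]
        winner, chosen, _ = arbitrate(
            cands,
            self._matches(refs, cands),
            LabelClass.printed,
            "tesseract",
            "trocr",
        )
        assert winner == "tesseract"
        assert chosen[FieldClass.locality] == "near Orbost"

    def test_better_htr_engine_wins_even_on_printed_label(self, refs):
        cands = [
            _cand(FieldClass.genus, "tesseract", "Xyzabc"),
            _cand(FieldClass.genus, "trocr", "Ahnfeltia"),
        ]
        winner, _, _ = arbitrate(
            cands, self._matches(refs, cands), LabelClass.printed, "tesseract", "trocr"
        )
        assert winner == "trocr"

    def test_equal_means_handwritten_takes_htr(self, refs):
        cands = [
            _cand(FieldClass.genus, "tesseract", "Ahnfeltia"),
            _cand(FieldClass.genus, "trocr", "Ahnfeltia"),
        ]
        winner, _, _ = arbitrate(
            cands,
            self._matches(refs, cands),
            LabelClass.handwritten,
            "tesseract",
            "trocr",
        )
        assert winner == "trocr"

    def test_both_below_threshold_printed_takes_ocr(self, refs):
        cands = [
            _cand(FieldClass.genus, "tesseract", "Qqq"),
            _cand(FieldClass.genus, "trocr", "Zzz"),
        ]
        winner, _, _ = arbitrate(
            cands, self._matches(refs, cands), LabelClass.printed, "tesseract", "trocr"
        )
        assert winner == "tesseract"

    def test_both_below_threshold_falls_back_despite_unequal_means(self, refs):
        # one engine scores higher but neither reaches the threshold: the
        # label class decides, not the means
        cands = [
            _cand(FieldClass.genus, "tesseract", "Ahnfeltia"),
            _cand(FieldClass.species, "tesseract", "zzz"),
            _cand(FieldClass.genus, "trocr", "Qqq"),
            _cand(FieldClass.species, "trocr", "qqq"),
        ]
        matches = self._matches(refs, cands)
        from sheetscribe.taxonmatch import arbitration_score

        means = {e: arbitration_score(m) for e, m in matches.items()}
        assert means["tesseract"] == 0.5 and means["trocr"] == 0.0
        winner, _, _ = arbitrate(
            cands, matches, LabelClass.combination, "tesseract", "trocr"
        )
        assert winner == "trocr"

    def test_no_cross_checked_fields_uses_label_class_rule(self, refs):
        cands = [
            _cand(FieldClass.locality, "tesseract", "somewhere"),
            _cand(FieldClass.locality, "trocr", "somewhere else"),
        ]
        for label_class, expected in [
            (LabelClass.handwritten, "trocr"),
            (LabelClass.combination, "trocr"),
            (LabelClass.typewritten, "tesseract"),
            (LabelClass.printed, "tesseract"),
            (LabelClass.empty, "tesseract"),
        ]:
            winner, _, _ = arbitrate(
                cands, {}, label_class, "tesseract", "trocr"
            )
            assert winner == expected

    def test_winner_carries_corrected_text_for_cross_checked_fields(self, refs):
        cands = [
            _cand(FieldClass.genus, "tesseract", "Ahnfletia"),
            _cand(FieldClass.genus, "trocr", "Xyzabc"),
        ]
        winner, chosen, notes = arbitrate(
            cands, self._matches(refs, cands), LabelClass.printed, "tesseract", "trocr"
        )
        assert winner == "tesseract"
        assert chosen[FieldClass.genus] == "Ahnfeltia"
        assert any("corrected genus" in n for n in notes)

    def test_arbitration_is_deterministic(self, refs):
        cands = [
            _cand(FieldClass.genus, "tesseract", "Ahnfletia"),
            _cand(FieldClass.genus, "trocr", "Ahnfeltia"),
            _cand(FieldClass.species, "tesseract", "torulosa"),
            _cand(FieldClass.species, "trocr", "torulosa"),
        ]
        results = {
            arbitrate(
                cands,
                self._matches(refs, cands),
                LabelClass.printed,
                "tesseract",
                "trocr",
            )[0]
            for _ in range(5)
        }
        assert len(results) == 1


def test_engine_preference_total_over_label_classes():
    mapping = {lc: engine_preference(lc) for lc in LabelClass}
    assert mapping[LabelClass.handwritten] == "htr"
    assert mapping[LabelClass.combination] == "htr"
    assert mapping[LabelClass.typewritten] == "ocr"
    assert mapping[LabelClass.printed] == "ocr"
    assert mapping[LabelClass.empty] == "ocr"


def test_assign_scores_only_on_cross_checked_fields(refs):
    from sheetscribe.core import FieldRecord, SpecimenRecord

    rec = SpecimenRecord(sheet_id="s")
    for fc in (FieldClass.genus, FieldClass.species, FieldClass.locality):
        rec.fields[fc] = FieldRecord(chosen_text="x")
    matches = {
        FieldClass.genus: closest_match("Ahnfeltia", "genus", refs),
        FieldClass.species: closest_match("serulata", "species", refs),
        FieldClass.locality: closest_match("ignored", "genus", refs),
    }
    assign_scores(rec, matches)
    assert rec.fields[FieldClass.genus].match_score == 1.0
    assert rec.fields[FieldClass.species].match_score == pytest.approx(16 / 17)
    assert rec.fields[FieldClass.locality].match_score is None
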