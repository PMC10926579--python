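"""Structured-result extraction from parsed sentences and sectioned reports."""

import itertools

import pytest

from egfrtext import (
    EGFRResult,
    MutationCall,
    enumerate_trees,
    extract_result,
    extract_sentence,
    interpret_tree,
    normalize,
    result_to_records,
    split_sections,
)

SAD_HEADERS = ["interpretation and comments:", "egfr mutation assay:", "note:", "comment:"]
SAD_PRIORITY = ["egfr mutation assay:", "interpretation and comments:"]


def _report(body: str, headers=SAD_HEADERS):
    return split_sections(normalize(body), headers)


class TestExtractSentence:
    def test_worked_example_deletion_exon19(self, lexicon, grammar):
        status, calls, _ = extract_sentence("the deletions in exon 19 was identified", lexicon, grammar)
        assert status == "identified"
        assert calls == (MutationCall(location="exon19", specific="deletion"),)

    def test_not_detected(self, lexicon, grammar):
        assert extract_sentence("not detected", lexicon, grammar)[0] == "not_detected"

    def test_cancelled_phrase(self, lexicon, grammar):
        assert extract_sentence("test cancelled due to insufficient dna", lexicon, grammar)[0] == "cancelled"

    def test_insufficient_dna(self, lexicon, grammar):
        assert extract_sentence("there was insufficient dna for the test", lexicon, grammar)[0] == "insufficient_dna"

    def test_multi_location_with_specific_pairing(self, lexicon, grammar):
        status, calls, _ = extract_sentence("deletion exon 19 and t790m identified", lexicon, grammar)
        assert status == "identified"
        assert set(calls) == {
            MutationCall(location="exon19", specific="deletion"),
            MutationCall(location="T790M", specific="none"),
        }

    def test_specific_never_crosses_a_conjunction(self, lexicon, grammar):
        """The deletion binds to exon 19, not to the T790M after the conjunction."""
        _, calls, _ = extract_sentence("exon 19 deletion and t790m identified", lexicon, grammar)
        by_loc = {c.location: c.specific for c in calls}
        assert by_loc == {"exon19": "deletion", "T790M": "none"}

    def test_tokenless_sentence_returns_none(self, lexicon, grammar):
        assert extract_sentence("the specimen was reviewed", lexicon, grammar) is None

    def test_unparseable_token_stream(self, lexicon, grammar):
        status, calls, reason = extract_sentence("exon 19 region evaluated", lexicon, grammar)
        assert status == "unparseable" and calls == () and reason

    def test_synonym_sentences_extract_identically(self, lexicon, grammar):
        plain = extract_sentence("l858r identified", lexicon, grammar)
        synonym = extract_sentence("l858r positive", lexicon, grammar)
        assert plain == synonym
        neg_a = extract_sentence("not detected", lexicon, grammar)
        neg_b = extract_sentence("negative", lexicon, grammar)
        assert neg_a == neg_b

    def test_repeated_location_collapses_keeping_specific(self, lexicon, grammar):
        status, calls, _ = extract_sentence("exon 19 and exon 19 deletion identified", lexicon, grammar)
        assert status == "identified"
        assert calls == (MutationCall(location="exon19", specific="deletion"),)


class TestDerivationInvariance:
    def test_all_short_ambiguous_strings_extract_identically(self, grammar):
        """Every derivation of an ambiguous token string yields one interpretation."""
        from egfrtext import recognize

        terminals = sorted(grammar.terminals)
        checked_ambiguous = 0
        for length in range(1, 5):
            for seq in itertools.product(terminals, repeat=length):
                if not recognize(seq, grammar):
                    continue
                trees = enumerate_trees(seq, grammar, limit=64)
                if len(trees) < 2:
                    continue
                checked_ambiguous += 1
                interpretations = {
                    (status, frozenset(calls))
                    for status, calls, _ in (interpret_tree(t) for t in trees)
                }
                assert len(interpretations) == 1, seq
        assert checked_ambiguous > 0

    def test_location_count_matches_location_tokens(self, grammar):
        terminals = sorted(grammar.terminals)
        for length in range(1, 4):
            for seq in itertools.product(terminals, repeat=length):
                trees = enumerate_trees(seq, grammar, limit=8)
                if not trees:
                    continue
                status, calls, _ = interpret_tree(trees[0])
                if status == "identified":
                    n_locations = len({s for s in seq if s.endswith("_location")})
                    assert len(calls) == n_locations


class TestExtractResult:
    def test_fig_sentence_in_sad_section(self, lexicon, grammar):
        report = _report(
            "Interpretation and Comments:\nEGFR assessed.\n"
            "EGFR Mutation Assay:\nThe deletions in Exon 19 was identified.\n"
            "Note:\nhotspots.\nComment:\nNone."
        )
        result = extract_result(report, lexicon, grammar, SAD_PRIORITY)
        assert result.status == "identified"
        assert result.mutations == (MutationCall(location="exon19", specific="deletion"),)
        assert result.source_section == "egfr mutation assay:"

    def test_fallback_to_interpretation_section(self, lexicon, grammar):
        report = _report("Interpretation and Comments:\nNot Detected.\nNote:\nx.")
        result = extract_result(report, lexicon, grammar, SAD_PRIORITY)
        assert result.status == "not_detected"
        assert result.source_section == "interpretation and comments:"

    def test_nad_result_section(self, lexicon, grammar):
        report = split_sections(normalize("Result: not detected"), ["result:"])
        result = extract_result(report, lexicon, grammar, ["result:"])
        assert result.status == "not_detected"

    def test_residual_fallback_when_no_headers(self, lexicon, grammar):
        report = _report("L858R identified.")
        assert extract_result(report, lexicon, grammar, SAD_PRIORITY).status == "identified"

    def test_no_section_no_residual(self, lexicon, grammar):
        report = _report("")
        result = extract_result(report, lexicon, grammar, SAD_PRIORITY)
        assert result.status == "unparseable" and result.reason == "no result section"

    def test_first_parseable_sentence_wins(self, lexicon, grammar):
        report = _report("EGFR Mutation Assay:\nNot detected. T790M identified.")
        assert extract_result(report, lexicon, grammar, SAD_PRIORITY).status == "not_detected"

    def test_unparseable_keeps_raw_sentence(self, lexicon, grammar):
        report = _report("EGFR Mutation Assay:\nexon 19 region was evaluated")
        result = extract_result(report, lexicon, grammar, SAD_PRIORITY)
        assert result.status == "unparseable"
        assert "exon 19" in result.raw_sentence


class TestResultInvariants:
    def test_identified_requires_mutations(self):
        with pytest.raises(ValueError):
            EGFRResult(status="identified", mutations=())

    def test_non_identified_forbids_mutations(self):
        with pytest.raises(ValueError):
            EGFRResult(status="not_detected", mutations=(MutationCall(location="T790M"),))

    def test_duplicate_locations_rejected(self):
        with pytest.raises(ValueError):
            EGFRResult(
                status="identified",
                mutations=(MutationCall(location="T790M"), MutationCall(location="T790M")),
            )

    def test_mixed_polarity_surfaces_as_unparseable(self, lexicon, grammar):
        outcome = extract_sentence("exon 19 not detected and t790m identified", lexicon, grammar)
        assert outcome[0] == "unparseable"


class TestResultToRecords:
    def test_one_record_per_mutation(self):
        result = EGFRResult(
            status="identified",
            mutations=(
                MutationCall(location="exon19", specific="deletion"),
                MutationCall(location="T790M"),
            ),
        )
        records = result_to_records(result, result_id="r1", patient_id="p1")
        assert len(records) == 2
        assert {r["location"] for r in records} == {"exon19", "T790M"}

    def test_not_detected_single_empty_record(self):
        records = result_to_records(EGFRResult(status="not_detected"), result_id="r2")
        assert records == [
            {
                "result_id": "r2",
                "patient_id": "",
                "status": "not_detected",
                "source_section": "",
                "location": "",
                "specific": "",
            }
        ]

    def test_four_locations_four_records(self):
        result = EGFRResult(
            status="identified",
            mutations=tuple(MutationCall(location=loc) for loc in ("exon19", "T790M", "L858R", "G719X")),
        )
        assert len(result_to_records(result)) == 4
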