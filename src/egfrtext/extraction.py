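"""Mapping parsed result sentences to structured EGFR records.

The payload of the whole framework: given a sectioned report, pick the
section that carries the assay result, tokenize and parse its sentences,
and read the structured result off the parse tree — the terminals on the
leaves ARE the test result.

A specific result (deletion/insertion) binds to the location it shares a
``Location`` subtree with, never to a location across a conjunction; this
pairing is invariant across all derivations of an ambiguous sentence, which
a property test enforces.  Sentences the grammar cannot account for are
never dropped: they come back with ``status="unparseable"`` and the raw
text retained for manual review.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .grammar import Grammar, ParseTree, Rejection, parse
from .lexer import Lexicon, SectionedReport, Token, tokenize

__all__ = [
    "MutationCall",
    "EGFRResult",
    "extract_result",
    "extract_sentence",
    "interpret_tree",
    "result_to_records",
    "STATUSES",
    "LOCATION_NAMES",
]

STATUSES = ("identified", "not_detected", "insufficient_dna", "cancelled", "unparseable")

#: Token symbol → canonical location name.
LOCATION_NAMES: Mapping[str, str] = {
    "exon_19_location": "exon19",
    "exon_20_location": "exon20",
    "t790m_location": "T790M",
    "l858r_location": "L858R",
    "l861q_location": "L861Q",
    "g719x_location": "G719X",
    "s768i_location": "S768I",
}

_SPECIFIC_NAMES: Mapping[str, str] = {
    "deletion_specific_result": "deletion",
    "insertion_specific_result": "insertion",
}


@dataclass(frozen=True)
class MutationCall:
    """One detected mutation: a location plus its specific result.

    ``specific`` is ``"deletion"``, ``"insertion"``, ``"none"`` (no modifier
    in the sentence), or ``"other:<surface>"`` when a wildcard grammar
    variant matched an arbitrary modifier token.
    """

    location: str
    specific: str = "none"

    def __post_init__(self) -> None:
        if self.location not in LOCATION_NAMES.values():
            raise ValueError(f"unknown location {self.location!r}")


@dataclass(frozen=True)
class EGFRResult:
    """The structured outcome of one laboratory report.

    Invariants: ``identified`` results carry at least one mutation call with
    no duplicate locations; every other status carries none.
    """

    status: str
    mutations: tuple[MutationCall, ...] = ()
    source_section: str = ""
    raw_sentence: str = ""
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "identified" and not self.mutations:
            raise ValueError("identified result must carry at least one mutation")
        if self.status != "identified" and self.mutations:
            raise ValueError(f"status {self.status!r} must not carry mutations")
        locs = [m.location for m in self.mutations]
        if len(locs) != len(set(locs)):
            raise ValueError("duplicate mutation locations")


def interpret_tree(tree: ParseTree) -> tuple[str, tuple[MutationCall, ...], str]:
    """Read (status, mutations, reason) off a parse tree.

    Walks the tree once: each maximal ``Location`` subtree yields one
    mutation call pairing its single location terminal with any specific
    result terminals inside the same subtree; result/status terminals
    anywhere in the tree decide the overall status.
    """
    results: list[str] = []
    statuses: list[str] = []
    mutations: list[MutationCall] = []

    def collect_location(node: ParseTree) -> None:
        loc_sym = None
        specific = "none"
        for sub in node.iter_nodes():
            if sub.label in LOCATION_NAMES:
                loc_sym = sub.label
            elif sub.label in _SPECIFIC_NAMES:
                specific = _SPECIFIC_NAMES[sub.label]
            elif sub.label not in ("Location", "Specific_Result") and sub.children == () and not sub.label[:1].isupper():
                specific = f"other:{sub.label}"  # wildcard-matched modifier
        if loc_sym is not None:
            mutations.append(MutationCall(location=LOCATION_NAMES[loc_sym], specific=specific))

    def walk(node: ParseTree) -> None:
        if node.label == "Location":
            collect_location(node)
            return
        if node.label.endswith("_result"):
            results.append(node.label)
            return
        if node.label.endswith("_status"):
            statuses.append(node.label)
            return
        for child in node.children:
            walk(child)

    walk(tree)

    # De-duplicate repeated identical locations, keeping a non-none specific.
    merged: dict[str, MutationCall] = {}
    for call in mutations:
        prev = merged.get(call.location)
        if prev is None or (prev.specific == "none" and call.specific != "none"):
            merged[call.location] = call
    calls = tuple(merged.values())

    if "cancelled_status" in statuses:
        return "cancelled", (), ""
    if "insufficient_dna_status" in statuses:
        return "insufficient_dna", (), ""
    has_pos = "identified_result" in results
    has_neg = "not_detected_result" in results
    if has_pos and has_neg:
        return "unparseable", (), "mixed polarity: identified and not detected in one sentence"
    if has_pos:
        if calls:
            return "identified", calls, ""
        return "unparseable", (), "identified without a location"
    if has_neg:
        # "Not detected" negates the whole panel; any mentioned locations
        # are part of the negation, not positive calls.
        return "not_detected", (), ""
    return "unparseable", (), "no result terminal in parse"


_SENTENCE_SPLIT = re.compile(r"[.\n;]+")


def extract_sentence(
    sentence: str, lexicon: Lexicon, grammar: Grammar
) -> tuple[str, tuple[MutationCall, ...], str] | None:
    """Extract from a single normalized sentence.

    Returns None when the sentence contains no lexicon tokens at all;
    otherwise (status, mutations, reason), with unparseable status for
    sentences whose token stream the grammar rejects or whose tokens fall
    outside the grammar's terminal alphabet.
    """
    tokens: list[Token] = tokenize(sentence, lexicon)
    if not tokens:
        return None
    symbols = [t.symbol for t in tokens]
    unknown = [s for s in symbols if s not in grammar.terminals]
    if unknown:
        return "unparseable", (), f"token(s) outside grammar alphabet: {', '.join(sorted(set(unknown)))}"
    outcome = parse(symbols, grammar)
    if isinstance(outcome, Rejection):
        return "unparseable", (), f"parse rejected at token {outcome.index}"
    return interpret_tree(outcome)


def _candidate_sections(report: SectionedReport, priority: Sequence[str]) -> list[tuple[str, str]]:
    """Section (label, body) candidates in dialect priority order.

    Duplicate-header sections (``label#2`` ...) follow their base label.
    """
    out: list[tuple[str, str]] = []
    for label in priority:
        base = label.strip().lower().rstrip()
        for key, body in report.sections.items():
            if key == base or key.startswith(base + "#"):
                out.append((key, body))
    if not out and report.residual:
        out.append(("", report.residual))
    return out


def extract_result(
    report: SectionedReport,
    lexicon: Lexicon,
    grammar: Grammar,
    result_section_priority: Sequence[str],
) -> EGFRResult:
    """Extract the structured EGFR result from a sectioned report.

    Candidate sections are tried in dialect priority order; within a
    section, sentences are tried in order and the first parseable one wins.
    A report with token-bearing but unparseable sentences yields
    ``status="unparseable"`` with the text retained; a report with no
    candidate section (and empty residual) yields the same with reason
    ``"no result section"``.
    """
    candidates = _candidate_sections(report, result_section_priority)
    if not candidates:
        return EGFRResult(status="unparseable", reason="no result section")

    first_failure: EGFRResult | None = None
    for label, body in candidates:
        for sentence in _SENTENCE_SPLIT.split(body):
            sentence = sentence.strip()
            if not sentence:
                continue
            extracted = extract_sentence(sentence, lexicon, grammar)
            if extracted is None:
                continue
            status, calls, reason = extracted
            result = EGFRResult(
                status=status,
                mutations=calls,
                source_section=label,
                raw_sentence=sentence,
                reason=reason,
            )
            if status != "unparseable":
                return result
            if first_failure is None:
                first_failure = result
    if first_failure is not None:
        return first_failure
    return EGFRResult(status="unparseable", reason="no result tokens in any section")


def result_to_records(
    result: EGFRResult, result_id: str = "", patient_id: str = ""
) -> list[dict[str, str]]:
    """Serialize one result into flat long-format records.

    Identified results emit one record per mutation call; every other
    status emits exactly one record with empty location fields.
    """
    base = {
        "result_id": result_id,
        "patient_id": patient_id,
        "status": result.status,
        "source_section": result.source_section,
    }
    if result.status == "identified":
        return [
            {**base, "location": call.location, "specific": call.specific}
            for call in result.mutations
        ]
    return [{**base, "location": "", "specific": ""}]
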