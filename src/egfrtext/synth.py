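"""Synthetic laboratory-report generator with known ground truth.

The real laboratory exports this package targets are governed by health
data privacy law and cannot ship with the code.  This module generates
corpora that emulate their structure — sectioned report bodies, two export
dialects (a multi-column layout with RTF-encoded bodies, and a single
plain-text results column), and result sentences drawn from the four
general result forms: not detected; identified at one location; identified
at two or more locations; insufficient DNA (phrased as a cancelled test in
the single-column dialect).

Every generated report carries a ground-truth record, so round-trip tests
can demand exact recovery.  The template inventory is deliberately richer
than the grammar — optional filler words, word-order variants, synonym
phrasings ("positive"/"negative") — so the tokenizer's ignore-unknown-words
behaviour is exercised.  Templates tagged out-of-grammar produce sentences
the parser must reject; their ground-truth status is "unparseable".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "generate_corpus", "rtf_wrap", "STATUS_KINDS", "LOCATIONS"]

STATUS_KINDS = ("not_detected", "identified_1", "identified_multi", "insufficient_dna", "cancelled")

#: Canonical location names with display surfaces for sentence rendering.
LOCATIONS = ("exon19", "L858R", "G719X", "T790M", "S768I", "L861Q", "exon20")
_DISPLAY = {
    "exon19": "Exon 19",
    "exon20": "Exon 20",
    "T790M": "T790M",
    "L858R": "L858R",
    "L861Q": "L861Q",
    "G719X": "G719X",
    "S768I": "S768I",
}

# Default weights follow the relative per-location frequencies seen in a
# population-scale assay series (exon 19 deletions and L858R dominate).
_DEFAULT_LOCATION_WEIGHTS = (536, 354, 170, 149, 37, 27, 19)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    status_mix
        Probabilities over (not detected, identified at 1 location,
        identified at 2+ locations, insufficient DNA, cancelled).  The
        default approximates the status proportions of a real population
        assay series: ~74% not detected, ~24% identified, ~1–2% failed.
    location_weights
        Sampling weights over :data:`LOCATIONS` for identified results.
    multi_k_weights
        Probabilities of 2, 3, 4 locations within multi-location results.
    phrasing_variant_rate
        Probability a sentence uses the synonym phrasing
        ("positive"/"negative" instead of "identified"/"not detected").
    noise_rate
        Probability a report's result sentence is out-of-grammar; such
        reports have ground-truth status "unparseable".
    """

    n_reports: int = 100
    status_mix: tuple[float, ...] = (0.74, 0.18, 0.06, 0.01, 0.01)
    location_weights: tuple[float, ...] = _DEFAULT_LOCATION_WEIGHTS
    multi_k_weights: tuple[float, ...] = (257 / 310, 33 / 310, 20 / 310)
    dialect: str = "sad"
    rtf_wrap: bool = True
    phrasing_variant_rate: float = 0.2
    specific_rate: float = 0.8  # P(exon19 carries "deletion" / exon20 "insertion")
    empty_uli_rate: float = 0.02
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if self.dialect not in ("sad", "nad"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        for name, vec, expect in (
            ("status_mix", self.status_mix, len(STATUS_KINDS)),
            ("multi_k_weights", self.multi_k_weights, 3),
        ):
            if len(vec) != expect:
                raise ValueError(f"{name} must have {expect} entries")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if len(self.location_weights) != len(LOCATIONS):
            raise ValueError(f"location_weights must have {len(LOCATIONS)} entries")
        for rate in (self.phrasing_variant_rate, self.noise_rate, self.specific_rate, self.empty_uli_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Sentence rendering
# ---------------------------------------------------------------------------

def _mutation_phrase(loc: str, specific: str, rng: np.random.Generator) -> str:
    disp = _DISPLAY[loc]
    if specific == "deletion":
        word = rng.choice(["deletion", "deletions"])
        return rng.choice([f"{word} in {disp}", f"{disp} {word}"])
    if specific == "insertion":
        word = rng.choice(["insertion", "insertions"])
        return rng.choice([f"{word} in {disp}", f"{disp} {word}"])
    return rng.choice([f"{disp}", f"{disp} mutation", f"mutation in {disp}"])


def _join_phrases(phrases: Sequence[str], rng: np.random.Generator) -> str:
    if len(phrases) == 1:
        return phrases[0]
    sep_last = " and " if rng.random() < 0.7 else ", "
    return ", ".join(phrases[:-1]) + sep_last + phrases[-1]


def _render_sentence(
    status: str,
    mutations: Sequence[tuple[str, str]],
    rng: np.random.Generator,
    variant: bool,
) -> tuple[str, str]:
    """Render one in-grammar result sentence; returns (sentence, template tag)."""
    if status == "not_detected":
        if variant:
            return rng.choice(
                ["Negative for EGFR mutation.", "The EGFR assay was negative."]
            ), "nd_variant"
        return rng.choice(
            ["Not Detected.", "The EGFR mutation was Not Detected.", "EGFR mutation: not detected."]
        ), "nd_plain"
    if status == "insufficient_dna":
        return rng.choice(
            ["There was insufficient DNA for the test.", "Insufficient DNA."]
        ), "insufficient"
    if status == "cancelled":
        return rng.choice(
            ["Test cancelled due to insufficient DNA.", "Test cancelled."]
        ), "cancelled"
    # identified
    phrases = [_mutation_phrase(loc, spec, rng) for loc, spec in mutations]
    joined = _join_phrases(phrases, rng)
    if variant:
        return f"{joined}: positive.", "id_variant"
    verb = "was" if len(mutations) == 1 else "were"
    return rng.choice(
        [
            f"The {joined} {verb} identified.",
            f"{joined} identified.",
        ]
    ), "id_plain"


_NOISE_SENTENCES = (
    "Specimen forwarded to the reference laboratory, see addendum.",
    "Quantity not sufficient for analysis and repeat collection is advised.",
    "EGFR exon 19 region evaluated by PCR.",
    "Molecular findings discussed at tumor board and documented separately.",
)

_INTERPRETATION_BOILERPLATE = (
    "EGFR mutation assessment was performed on formalin-fixed paraffin-embedded tumor tissue.",
    "This specimen was analyzed for EGFR mutations by real-time PCR (therascreen EGFR kit).",
    "EGFR mutation analysis was requested by Dr. Côté on the submitted block.",
)

_NOTE_BOILERPLATE = (
    "This assay screens Exon 18-21 hotspot regions of the EGFR gene.",
    "Results should be interpreted in the context of clinical findings.",
)

_COMMENT_LOW_CELLULARITY = "Low tumor cellularity; interpret with caution."


# ---------------------------------------------------------------------------
# RTF envelope
# ---------------------------------------------------------------------------

def _rtf_escape(text: str) -> str:
    out: list[str] = []
    for ch in text:
        if ch in "\\{}":
            out.append("\\" + ch)
        elif ord(ch) < 128:
            out.append(ch)
        else:
            try:
                byte = ch.encode("cp1252")
                out.append(f"\\'{byte[0]:02x}")
            except UnicodeEncodeError:
                out.append(f"\\u{ord(ch)}?")
    return "".join(out)


def rtf_wrap(text: str) -> str:
    """Wrap plain report text in a minimal valid RTF envelope.

    The envelope carries a font table, colour table and an ignorable
    generator destination — metadata a stripper must discard — and encodes
    each report line as a paragraph.
    """
    lines = text.split("\n")
    body = "\\par ".join(_rtf_escape(line) for line in lines)
    return (
        "{\\rtf1\\ansi\\ansicpg1252\\deff0"
        "{\\fonttbl{\\f0\\fswiss Arial;}{\\f1\\froman Times New Roman;}}"
        "{\\colortbl ;\\red0\\green0\\blue0;}"
        "{\\*\\generator synthetic lab export;}"
        "\\f0\\fs20 " + body + "\\par}"
    )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _draw_mutations(config: GeneratorConfig, rng: np.random.Generator, k: int) -> list[tuple[str, str]]:
    weights = np.asarray(config.location_weights, dtype=float)
    probs = weights / weights.sum()
    idx = rng.choice(len(LOCATIONS), size=k, replace=False, p=probs)
    mutations = []
    for i in sorted(idx):
        loc = LOCATIONS[i]
        if loc == "exon19" and rng.random() < config.specific_rate:
            spec = "deletion"
        elif loc == "exon20" and rng.random() < config.specific_rate:
            spec = "insertion"
        else:
            spec = "none"
        mutations.append((loc, spec))
    return mutations


def _assemble_sad_body(sentence: str, rng: np.random.Generator, commented: bool) -> str:
    return "\n".join(
        [
            "Interpretation and Comments:",
            str(rng.choice(_INTERPRETATION_BOILERPLATE)),
            "EGFR Mutation Assay:",
            sentence,
            "Note:",
            str(rng.choice(_NOTE_BOILERPLATE)),
            "Comment:",
            _COMMENT_LOW_CELLULARITY if commented else "None.",
        ]
    )


def _assemble_nad_body(sentence: str, rng: np.random.Generator) -> str:
    preamble = str(rng.choice(_INTERPRETATION_BOILERPLATE))
    return f"{preamble}\nResult: {sentence}"


def generate_corpus(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (report table, ground-truth table) for the configured dialect.

    The report table mimics the dialect's column layout; the truth table
    has one row per report with its record id, true status, true mutation
    calls (``"loc:specific"`` joined by ``;``), and the template used.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    prefix = config.dialect.upper()
    rows: list[dict[str, str]] = []
    truths: list[dict[str, str]] = []

    for i in range(config.n_reports):
        rid = f"{prefix}-{i + 1:06d}"
        uli = "" if rng.random() < config.empty_uli_rate else f"ULI{rng.integers(10**8, 10**9 - 1)}"
        noisy = rng.random() < config.noise_rate
        if noisy:
            sentence = str(rng.choice(_NOISE_SENTENCES))
            template = "noise"
            true_status = "unparseable"
            mutations: list[tuple[str, str]] = []
        else:
            kind = STATUS_KINDS[rng.choice(len(STATUS_KINDS), p=config.status_mix)]
            if kind == "identified_1":
                mutations = _draw_mutations(config, rng, 1)
                true_status = "identified"
            elif kind == "identified_multi":
                k = int(rng.choice([2, 3, 4], p=config.multi_k_weights))
                mutations = _draw_mutations(config, rng, k)
                true_status = "identified"
            else:
                mutations = []
                true_status = kind
            variant = rng.random() < config.phrasing_variant_rate
            sentence, template = _render_sentence(
                true_status if true_status != "identified" else "identified",
                mutations,
                rng,
                variant,
            )
        commented = rng.random() < 0.03

        if config.dialect == "sad":
            body = _assemble_sad_body(sentence, rng, commented)
            if config.rtf_wrap:
                body = rtf_wrap(body)
            rows.append(
                {
                    "RESULT_ID": rid,
                    "ULI": uli,
                    "SPECIMEN_ACCN": f"S{rng.integers(10, 99)}-{rng.integers(10000, 99999)}",
                    "SPECIMEN_SOURCE": str(
                        rng.choice(["Lung, right upper lobe, biopsy", "Lung, left lower lobe, biopsy", "Pleural fluid"])
                    ),
                    "TEST_NAME": "EGFR Result",
                    "TEST_TASK": str(rng.choice(["EGFR (Interpretation)", "EGFR (Qualitative)"])),
                    "RTF_RESULT": body,
                    "RESULT_SHORT": "See report",
                }
            )
        else:
            rows.append(
                {
                    "RESULT_ID": rid,
                    "ULI": uli,
                    "RESULTS": _assemble_nad_body(sentence, rng),
                }
            )
        truths.append(
            {
                "record_id": rid,
                "true_status": true_status,
                "true_mutations": ";".join(f"{loc}:{spec}" for loc, spec in mutations),
                "template": template,
            }
        )

    columns = (
        ["RESULT_ID", "ULI", "SPECIMEN_ACCN", "SPECIMEN_SOURCE", "TEST_NAME", "TEST_TASK", "RTF_RESULT", "RESULT_SHORT"]
        if config.dialect == "sad"
        else ["RESULT_ID", "ULI", "RESULTS"]
    )
    corpus = pd.DataFrame(rows, columns=columns)
    truth = pd.DataFrame(truths, columns=["record_id", "true_status", "true_mutations", "template"])
    return corpus, truth
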