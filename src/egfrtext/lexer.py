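"""Lexical analysis: normalization, section splitting and tokenization.

A molecular-pathology report is free text with a loose internal structure:
named sections ("EGFR Mutation Assay:", "Result:", ...) whose bodies contain
short result sentences.  Lexical analysis reduces that text to a symbol
stream the grammar stage can parse:

1. :func:`normalize` — lowercase, trim, collapse whitespace runs (newlines
   are kept so section headers stay anchored to line starts).
2. :func:`split_sections` — exact, line-start matching of a configured
   header list, producing a :class:`SectionedReport`.
3. :func:`tokenize` — longest-match scan of a section body against a small
   :class:`Lexicon` of domain key words (mutation locations, result words,
   specific-result modifiers, status phrases, conjunctions).  All other
   English words are ignored: the result language is small enough that the
   intervening prose carries no signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Lexicon",
    "Token",
    "SectionedReport",
    "normalize",
    "split_sections",
    "tokenize",
    "load_lexicon",
    "default_lexicon",
    "LexiconError",
]

#: The seven genomic locations screened by the assay.
LOCATION_SYMBOLS = frozenset(
    {
        "exon_19_location",
        "exon_20_location",
        "t790m_location",
        "l858r_location",
        "l861q_location",
        "g719x_location",
        "s768i_location",
    }
)

CATEGORIES = ("location", "result", "specific_result", "conjunction", "status")


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon definitions."""


def _category_of(symbol: str) -> str:
    if symbol == "conjunction":
        return "conjunction"
    if symbol.endswith("_specific_result"):
        return "specific_result"
    if symbol.endswith("_location"):
        return "location"
    if symbol.endswith("_status"):
        return "status"
    if symbol.endswith("_result"):
        return "result"
    raise LexiconError(f"cannot infer category for token symbol {symbol!r}")


@dataclass(frozen=True)
class Lexicon:
    """Surface-form → (token symbol, category) mapping.

    Surface forms are stored lowercase and whitespace-normalized; multi-word
    forms ("exon 19", "not detected") are supported and matched greedily.
    """

    entries: dict[str, tuple[str, str]]
    max_words: int = field(init=False, default=1)

    def __post_init__(self) -> None:
        maxw = 1
        for surface, (symbol, category) in self.entries.items():
            if surface != " ".join(surface.lower().split()):
                raise LexiconError(f"surface form {surface!r} is not normalized")
            if category not in CATEGORIES:
                raise LexiconError(f"unknown category {category!r} for {surface!r}")
            if category == "location" and symbol not in LOCATION_SYMBOLS:
                raise LexiconError(f"unknown location symbol {symbol!r}")
            maxw = max(maxw, len(surface.split()))
        object.__setattr__(self, "max_words", maxw)

    def symbols(self) -> frozenset[str]:
        return frozenset(sym for sym, _ in self.entries.values())


@dataclass(frozen=True)
class Token:
    """One lexical unit of a result sentence.

    ``span`` is a 0-based half-open character range into the normalized text
    the token was scanned from, so ``text[span[0]:span[1]] == surface``.
    """

    symbol: str
    category: str
    surface: str
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError("token span must be non-empty")


@dataclass(frozen=True)
class SectionedReport:
    """Report body split on recognized headers.

    ``sections`` maps header label → body text in document order; duplicate
    headers get suffixed keys (``label#2``, ...).  ``residual`` is any text
    before the first recognized header (the whole text when no header
    matches).
    """

    sections: dict[str, str]
    residual: str
    _segments: tuple[str, ...] = ()  # raw text chunks, header line included

    def reconstruct(self) -> str:
        """Re-concatenate residual + headers + bodies into the input text."""
        parts = ([self.residual] if self.residual else []) + list(self._segments)
        return "\n".join(parts)


def normalize(text: str) -> str:
    """Lowercase, trim, and collapse internal whitespace runs.

    Newlines survive as line separators (section headers are matched at
    line starts); every other whitespace run becomes a single space.
    """
    lines = [" ".join(line.split()) for line in text.lower().splitlines()]
    return "\n".join(lines).strip()


def split_sections(text: str, headers: Iterable[str]) -> SectionedReport:
    """Split normalized *text* into sections on exact header matches.

    A header opens a section when a line starts with it; the body runs to
    the next header or end of text.  The body may begin on the header line
    itself ("egfr mutation assay: not detected") or on following lines.
    """
    header_list = sorted({normalize(h) for h in headers}, key=len, reverse=True)
    if not header_list:
        raise ValueError("headers must be non-empty")

    lines = text.split("\n")
    # (label or None for residual, raw lines of the chunk incl. header line)
    segments: list[tuple[str | None, list[str]]] = [(None, [])]
    for line in lines:
        matched = None
        for h in header_list:
            if line.startswith(h):
                matched = h
                break
        if matched is None:
            segments[-1][1].append(line)
        else:
            segments.append((matched, [line]))

    sections: dict[str, str] = {}
    chunks: list[str] = []
    residual = "\n".join(segments[0][1]).strip()
    for label, chunk_lines in segments[1:]:
        assert label is not None
        body = "\n".join([chunk_lines[0][len(label):]] + chunk_lines[1:]).strip()
        key = label
        k = 2
        while key in sections:
            key = f"{label}#{k}"
            k += 1
        sections[key] = body
        chunks.append("\n".join(chunk_lines))
    return SectionedReport(sections=sections, residual=residual, _segments=tuple(chunks))


# Units are words (which may contain '/' for combined variants like
# g719s/g719a/g719c) or a bare comma; sentence punctuation is a separator.
_UNIT_RE = re.compile(r",|[^\s,.;:!?()\[\]{}\"'“”‘’]+")


def tokenize(text: str, lexicon: Lexicon) -> list[Token]:
    """Longest-match, left-to-right tokenization against *lexicon*.

    Multi-word lexicon entries win over their prefixes ("exon 19" is never
    emitted as a bare "exon"; "not detected" shadows "detected").  Units
    matching no entry are silently skipped.
    """
    units = list(_UNIT_RE.finditer(text))
    tokens: list[Token] = []
    i = 0
    while i < len(units):
        emitted = False
        for length in range(min(lexicon.max_words, len(units) - i), 0, -1):
            candidate = " ".join(u.group(0) for u in units[i : i + length])
            entry = lexicon.entries.get(candidate)
            if entry is not None:
                symbol, category = entry
                span = (units[i].start(), units[i + length - 1].end())
                tokens.append(
                    Token(symbol=symbol, category=category, surface=text[span[0] : span[1]], span=span)
                )
                i += length
                emitted = True
                break
        if not emitted:
            i += 1
    return tokens


def load_lexicon(source: str | Path) -> Lexicon:
    """Load a lexicon from two-column tab-separated text.

    Each line is ``surface form<TAB>token_symbol``; ``#`` starts a comment.
    The category is inferred from the symbol suffix (``_location``,
    ``_result``, ``_specific_result``, ``_status``) or the literal symbol
    ``conjunction``.
    """
    if isinstance(source, Path):
        content = source.read_text(encoding="utf-8")
    elif "\t" in source or "\n" in source:
        content = source
    else:
        content = Path(source).read_text(encoding="utf-8")

    entries: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(content.splitlines(), start=1):
        line = line.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"line {lineno}: expected 'surface<TAB>symbol', got {line!r}")
        surface = " ".join(parts[0].lower().split())
        symbol = parts[1].strip()
        if surface in entries:
            raise LexiconError(f"line {lineno}: duplicate surface form {surface!r}")
        entries[surface] = (symbol, _category_of(symbol))
    return Lexicon(entries=entries)


def default_lexicon() -> Lexicon:
    """The packaged EGFR vocabulary."""
    text = resources.files("egfrtext.data").joinpath("egfr_lexicon.tsv").read_text("utf-8")
    return load_lexicon(text)
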