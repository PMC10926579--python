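"""Rich Text Format stripping.

Laboratory information systems frequently export report bodies wrapped in
RTF markup.  Downstream lexical analysis needs readable plain text, so this
module removes control words, group braces and non-text destination groups
(font tables, colour tables, stylesheets, embedded images) while decoding
the escape sequences that carry actual characters.

The stripper is deliberately lossy with respect to formatting: bold, fonts
and layout carry no information for result extraction.  It is conservative
with respect to text: every character-producing construct (``\\'hh`` hex
escapes, ``\\uN`` Unicode escapes, literal brace/backslash escapes, ``\\par``
/ ``\\line`` breaks) is decoded, and malformed input degrades to best-effort
text plus a warning rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["RtfPayload", "PlainText", "RtfConfig", "rtf_to_text", "looks_like_rtf"]

#: Destination groups whose content is metadata, not document text.
DEFAULT_SKIP_DESTINATIONS = frozenset(
    {
        "fonttbl",
        "colortbl",
        "stylesheet",
        "info",
        "pict",
        "header",
        "footer",
        "generator",
    }
)

# Control words that produce a character or break rather than formatting.
_SPECIAL_WORDS = {
    "par": "\n",
    "line": "\n",
    "sect": "\n",
    "page": "\n",
    "row": "\n",
    "tab": "\t",
    "cell": " ",
    "emdash": "—",
    "endash": "–",
    "emspace": " ",
    "enspace": " ",
    "qmspace": " ",
    "bullet": "•",
    "lquote": "‘",
    "rquote": "’",
    "ldblquote": "“",
    "rdblquote": "”",
}


@dataclass(frozen=True)
class RtfPayload:
    """A raw report body that may or may not be RTF-encoded."""

    raw: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.raw:
            raise ValueError("RtfPayload.raw must be non-empty")


@dataclass(frozen=True)
class PlainText:
    """Stripped report text.

    ``had_rtf`` records whether stripping was actually applied; ``warnings``
    lists recoverable problems (unbalanced braces, truncated escapes) so a
    batch pipeline can flag the record for review without aborting.
    """

    text: str
    had_rtf: bool
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class RtfConfig:
    """Knobs for the stripper.

    encoding
        Code page used for ``\\'hh`` byte escapes.  Windows-1252 is the
        dominant dialect in clinical exports.
    skip_destinations
        Group-opening control words whose whole group is dropped, in
        addition to any ``\\*``-prefixed (ignorable) destination.
    """

    encoding: str = "cp1252"
    skip_destinations: frozenset[str] = field(default=DEFAULT_SKIP_DESTINATIONS)


def looks_like_rtf(raw: str) -> bool:
    """True if *raw* starts (after optional whitespace) with an RTF opener."""
    return raw.lstrip().startswith("{\\rtf")


@dataclass
class _GroupState:
    suppress: bool = False
    uc: int = 1  # chars to skip after a \uN escape


def rtf_to_text(payload: RtfPayload, config: RtfConfig | None = None) -> PlainText:
    """Convert an RTF report body to readable plain text.

    Non-RTF input (anything not opening with ``{\\rtf``) passes through
    unchanged with ``had_rtf=False``.  Unknown control words are dropped
    silently; destination groups in ``config.skip_destinations`` and
    ``\\*``-prefixed groups are skipped entirely.
    """
    config = config or RtfConfig()
    raw = payload.raw
    if not looks_like_rtf(raw):
        return PlainText(text=raw, had_rtf=False)

    src = raw.lstrip()
    out: list[str] = []
    warnings: list[str] = []
    stack: list[_GroupState] = []
    state = _GroupState()
    pending_skip = 0  # \uN fallback characters still to swallow
    group_just_opened = False

    def emit(ch: str) -> None:
        nonlocal pending_skip
        if pending_skip > 0:
            pending_skip -= 1
            return
        if not state.suppress:
            out.append(ch)

    i = 0
    n = len(src)
    while i < n:
        ch = src[i]
        if ch == "{":
            stack.append(state)
            state = _GroupState(suppress=state.suppress, uc=state.uc)
            group_just_opened = True
            i += 1
            continue
        if ch == "}":
            if stack:
                state = stack.pop()
            else:
                warnings.append("unbalanced closing brace")
            group_just_opened = False
            i += 1
            continue
        if ch != "\\":
            if ch not in "\r\n":  # raw newlines in RTF source are ignored
                emit(ch)
            group_just_opened = False
            i += 1
            continue

        # ch == "\\": control word or control symbol
        if i + 1 >= n:
            warnings.append("trailing backslash dropped")
            break
        nxt = src[i + 1]
        if nxt in "\\{}":
            emit(nxt)
            group_just_opened = False
            i += 2
            continue
        if nxt == "~":
            emit(" ")
            i += 2
            continue
        if nxt == "-":  # optional hyphen: no text
            i += 2
            continue
        if nxt == "_":
            emit("-")
            i += 2
            continue
        if nxt in "\r\n":  # escaped newline is a paragraph break
            emit("\n")
            i += 2
            continue
        if nxt == "*":
            # Ignorable destination: drop the enclosing group.
            if group_just_opened:
                state.suppress = True
            i += 2
            continue
        if nxt == "'":
            hexpart = src[i + 2 : i + 4]
            if len(hexpart) == 2 and all(c in "0123456789abcdefABCDEF" for c in hexpart):
                try:
                    emit(bytes([int(hexpart, 16)]).decode(config.encoding))
                except UnicodeDecodeError:
                    warnings.append(f"undecodable byte \\'{hexpart}")
                i += 4
            else:
                warnings.append("truncated hex escape dropped")
                i += 2
            group_just_opened = False
            continue
        if not nxt.isalpha():
            # Unknown control symbol: drop it.
            i += 2
            continue

        # Control word: letters then optional signed integer then optional space.
        j = i + 1
        while j < n and src[j].isalpha():
            j += 1
        word = src[i + 1 : j]
        param: int | None = None
        k = j
        if k < n and (src[k] == "-" or src[k].isdigit()):
            m = k + 1 if src[k] == "-" else k
            while m < n and src[m].isdigit():
                m += 1
            if m > k and src[k:m].lstrip("-"):
                param = int(src[k:m])
                k = m
        if k < n and src[k] == " ":  # delimiter space belongs to the control word
            k += 1
        i = k

        if word in config.skip_destinations and group_just_opened:
            state.suppress = True
        elif word == "uc":
            state.uc = param if param is not None else 1
        elif word == "u" and param is not None:
            cp = param if param >= 0 else 65536 + param
            try:
                emit(chr(cp))
            except ValueError:
                warnings.append(f"invalid unicode escape \\u{param}")
            pending_skip += state.uc
        elif word in _SPECIAL_WORDS:
            emit(_SPECIAL_WORDS[word])
        # every other control word is formatting: dropped silently
        group_just_opened = False

    if stack:
        warnings.append("unbalanced opening brace")

    text = "".join(out).replace("\r\n", "\n").replace("\r", "\n")
    return PlainText(text=text, had_rtf=True, warnings=tuple(warnings))
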