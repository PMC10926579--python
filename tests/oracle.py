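"""Independent brute-force oracles used by the test suite.

These deliberately avoid the chart parser's code path: language membership
is decided by exhaustively constructing every terminal string a grammar can
derive up to a length bound, via a fixpoint over the production rules.
The fixpoint is exact for the bounded language (it keeps iterating until no
rule adds a new bounded string), so it terminates even on grammars with
nullable cycles and left recursion.
"""

from __future__ import annotations

from egfrtext import Grammar


def bounded_language(grammar: Grammar, max_len: int) -> set[tuple[str, ...]]:
    """All terminal strings of length <= max_len derivable from the start symbol."""
    lang: dict[str, set[tuple[str, ...]]] = {t: {(t,)} for t in grammar.terminals}
    for v in grammar.variables:
        lang[v] = set()

    def combinations(parts, max_len):
        out: set[tuple[str, ...]] = set()

        def go(idx, cur):
            if idx == len(parts):
                out.add(tuple(cur))
                return
            for piece in parts[idx]:
                if len(cur) + len(piece) <= max_len:
                    go(idx + 1, cur + list(piece))

        go(0, [])
        return out

    changed = True
    while changed:
        changed = False
        for rule in grammar.rules:
            if not rule.rhs:
                cand = {()}
            else:
                cand = combinations([lang.get(s, set()) for s in rule.rhs], max_len)
            new = cand - lang[rule.lhs]
            if new:
                lang[rule.lhs] |= new
                changed = True
    return lang[grammar.start]
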