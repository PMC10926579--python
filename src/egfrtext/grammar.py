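"""Context-free grammar representation and chart parsing.

The language of assay result sentences is small but not regular-friendly:
its natural grammar is both left-recursive (a result can extend an earlier
result with ``, <location>``) and ambiguous (a conjunction chain admits
several derivations).  A general chart parser (Earley's algorithm) handles
both without any grammar transformation, terminates on every input, and
runs in cubic time — trivially fast at the sentence lengths seen here.

A grammar is the classical 4-tuple (V, Σ, R, S): variables, terminals,
productions and a start symbol.  Grammars are loaded from a line-oriented
text format (see :func:`load_grammar`) and are immutable once built, which
lets nullable sets be computed once and cached.

When a sentence is ambiguous, :func:`parse` returns a canonical derivation:
alternatives are tried in rule order (lowest production index first) and
each child consumes the shortest viable span (leftmost completion).  Result
extraction is required to be derivation-invariant, so the choice of
canonical tree never changes the extracted record — but a deterministic
tree makes runs reproducible and trees comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "Grammar",
    "Rule",
    "ParseTree",
    "Rejection",
    "GrammarError",
    "load_grammar",
    "default_grammar",
    "packaged_grammar",
    "parse",
    "recognize",
    "enumerate_trees",
    "WILDCARD",
]

#: Reserved rhs symbol that matches any single terminal (used by grammar
#: variants to model an arbitrary unrecognized modifier; the packaged
#: default grammar does not use it).
WILDCARD = "WILDCARD"

_EPSILON = "EPSILON"


class GrammarError(ValueError):
    """Raised for malformed grammar sources or contract violations."""


@dataclass(frozen=True)
class Rule:
    """One production lhs → rhs.  An empty rhs is an ε-production."""

    lhs: str
    rhs: tuple[str, ...]
    index: int

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.lhs} -> {' '.join(self.rhs) or 'ε'}"


@dataclass(frozen=True)
class Grammar:
    """An immutable CFG 4-tuple (variables, terminals, rules, start)."""

    variables: frozenset[str]
    terminals: frozenset[str]
    rules: tuple[Rule, ...]
    start: str
    _by_lhs: dict[str, tuple[Rule, ...]] = field(init=False, repr=False)
    _nullable: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.variables & self.terminals:
            raise GrammarError("variables and terminals must be disjoint")
        if self.start not in self.variables:
            raise GrammarError(f"start symbol {self.start!r} is not a variable")
        by_lhs: dict[str, list[Rule]] = {}
        for rule in self.rules:
            if rule.lhs not in self.variables:
                raise GrammarError(f"rule lhs {rule.lhs!r} is not a variable")
            for sym in rule.rhs:
                if sym not in self.variables and sym not in self.terminals and sym != WILDCARD:
                    raise GrammarError(f"undefined symbol {sym!r} in rule for {rule.lhs!r}")
            by_lhs.setdefault(rule.lhs, []).append(rule)
        object.__setattr__(self, "_by_lhs", {k: tuple(v) for k, v in by_lhs.items()})
        object.__setattr__(self, "_nullable", self._compute_nullable())

    def _compute_nullable(self) -> frozenset[str]:
        nullable: set[str] = set()
        changed = True
        while changed:
            changed = False
            for rule in self.rules:
                if rule.lhs not in nullable and all(s in nullable for s in rule.rhs):
                    nullable.add(rule.lhs)
                    changed = True
        return frozenset(nullable)

    def rules_for(self, variable: str) -> tuple[Rule, ...]:
        return self._by_lhs.get(variable, ())

    def is_terminal(self, symbol: str) -> bool:
        return symbol in self.terminals or symbol == WILDCARD

    def is_nullable(self, symbol: str) -> bool:
        return symbol in self._nullable


@dataclass(frozen=True)
class ParseTree:
    """A derivation tree; leaves carry terminal symbols, internal nodes variables.

    ε-productions yield internal nodes with no children.
    """

    label: str
    children: tuple["ParseTree", ...] = ()

    def leaves(self) -> list[str]:
        """Terminal leaf symbols, left to right (ε nodes contribute nothing)."""
        if not self.children:
            return [self.label] if _is_leaf_terminal(self) else []
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def iter_nodes(self) -> Iterator["ParseTree"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def pretty(self, indent: int = 0) -> str:
        pad = "  " * indent
        if not self.children:
            return f"{pad}{self.label}"
        lines = [f"{pad}{self.label}"]
        for child in self.children:
            lines.append(child.pretty(indent + 1))
        return "\n".join(lines)

    def validate(self, grammar: Grammar) -> None:
        """Check every internal node corresponds to a production of *grammar*."""
        if grammar.is_terminal(self.label) or self.label in grammar.terminals:
            if self.children:
                raise GrammarError(f"terminal node {self.label!r} has children")
            return
        if self.label not in grammar.variables:
            raise GrammarError(f"unknown node label {self.label!r}")
        child_labels = tuple(c.label for c in self.children)
        for rule in grammar.rules_for(self.label):
            if _rhs_matches(rule.rhs, child_labels, grammar):
                for child in self.children:
                    child.validate(grammar)
                return
        raise GrammarError(f"no production {self.label} -> {' '.join(child_labels) or 'ε'}")


def _is_leaf_terminal(node: ParseTree) -> bool:
    # Internal ε nodes are variables; leaf terminals are lowercase token symbols
    # by the grammar format convention (variables are capitalized identifiers).
    return not node.label[:1].isupper()


def _rhs_matches(rhs: tuple[str, ...], child_labels: tuple[str, ...], grammar: Grammar) -> bool:
    if len(rhs) != len(child_labels):
        return False
    return all(r == c or (r == WILDCARD and grammar.is_terminal(c)) for r, c in zip(rhs, child_labels))


@dataclass(frozen=True)
class Rejection:
    """A failed parse: *index* is the position of the first token at which
    no partial derivation survives (``len(tokens)`` when every prefix was
    viable but no complete derivation exists)."""

    index: int
    reason: str


# ---------------------------------------------------------------------------
# Grammar file format
# ---------------------------------------------------------------------------

def load_grammar(source: str | Path) -> Grammar:
    """Load a grammar from its line-oriented text format.

    Format: ``Lhs -> Alt1 | Alt2 | ...`` with whitespace-separated symbols;
    terminals are single-quoted, ``EPSILON`` denotes the empty alternative,
    ``WILDCARD`` matches any single terminal, ``#`` starts a comment, and a
    rule may continue over indented lines starting with ``|``.  The first
    rule's lhs is the start symbol.
    """
    if isinstance(source, Path):
        content = source.read_text(encoding="utf-8")
    elif "->" in source or "\n" in source:
        content = source
    else:
        content = Path(source).read_text(encoding="utf-8")

    # Join continuation lines, strip comments.
    logical: list[str] = []
    for raw in content.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.lstrip().startswith("|") and logical:
            logical[-1] += " " + line.strip()
        else:
            logical.append(line.strip())

    variables: list[str] = []
    terminals: set[str] = set()
    raw_rules: list[tuple[str, tuple[str, ...]]] = []
    for line in logical:
        if "->" not in line:
            raise GrammarError(f"expected 'Lhs -> ...': {line!r}")
        lhs, rhs_text = (part.strip() for part in line.split("->", 1))
        if not lhs.isidentifier():
            raise GrammarError(f"invalid variable name {lhs!r}")
        if lhs not in variables:
            variables.append(lhs)
        for alt in rhs_text.split("|"):
            symbols = alt.split()
            if not symbols:
                raise GrammarError(f"empty alternative in rule for {lhs!r}")
            if symbols == [_EPSILON]:
                raw_rules.append((lhs, ()))
                continue
            rhs: list[str] = []
            for sym in symbols:
                if sym == _EPSILON:
                    raise GrammarError(f"EPSILON must be the sole symbol of its alternative ({lhs!r})")
                if sym.startswith("'") and sym.endswith("'") and len(sym) > 2:
                    term = sym[1:-1]
                    terminals.add(term)
                    rhs.append(term)
                else:
                    rhs.append(sym)
            raw_rules.append((lhs, tuple(rhs)))

    if not raw_rules:
        raise GrammarError("grammar source contains no rules")
    var_set = frozenset(variables)
    for lhs, rhs in raw_rules:
        for sym in rhs:
            if sym not in var_set and sym not in terminals and sym != WILDCARD:
                raise GrammarError(f"undefined symbol {sym!r} in rule for {lhs!r}")
    rules = tuple(Rule(lhs=lhs, rhs=rhs, index=i) for i, (lhs, rhs) in enumerate(raw_rules))
    return Grammar(variables=var_set, terminals=frozenset(terminals), rules=rules, start=variables[0])


def packaged_grammar(name: str) -> Grammar:
    """Load one of the packaged grammar files (``egfr``, ``egfr_base``, ...)."""
    text = resources.files("egfrtext.data").joinpath(f"{name}.cfg").read_text("utf-8")
    return load_grammar(text)


def default_grammar() -> Grammar:
    """The packaged EGFR result grammar including the status extensions."""
    return packaged_grammar("egfr")


# ---------------------------------------------------------------------------
# Earley recognition
# ---------------------------------------------------------------------------

def _earley_chart(tokens: Sequence[str], grammar: Grammar) -> list[set[tuple[int, int, int]]]:
    """Build the Earley chart.  Items are (rule_index, dot, origin)."""
    n = len(tokens)
    chart: list[set[tuple[int, int, int]]] = [set() for _ in range(n + 1)]
    start_rules = grammar.rules_for(grammar.start)
    for rule in start_rules:
        chart[0].add((rule.index, 0, 0))

    for i in range(n + 1):
        agenda = list(chart[i])
        while agenda:
            item = agenda.pop()
            rule_idx, dot, origin = item
            rule = grammar.rules[rule_idx]
            if dot < len(rule.rhs):
                sym = rule.rhs[dot]
                if grammar.is_terminal(sym):
                    if i < n and (sym == WILDCARD or tokens[i] == sym):
                        chart[i + 1].add((rule_idx, dot + 1, origin))
                else:
                    for r in grammar.rules_for(sym):
                        new = (r.index, 0, i)
                        if new not in chart[i]:
                            chart[i].add(new)
                            agenda.append(new)
                    # Aycock–Horspool fix: a nullable predictee completes here.
                    if grammar.is_nullable(sym):
                        new = (rule_idx, dot + 1, origin)
                        if new not in chart[i]:
                            chart[i].add(new)
                            agenda.append(new)
            else:
                # Completion: advance every item waiting on rule.lhs at origin.
                for waiting in list(chart[origin]):
                    w_rule = grammar.rules[waiting[0]]
                    if waiting[1] < len(w_rule.rhs) and w_rule.rhs[waiting[1]] == rule.lhs:
                        new = (waiting[0], waiting[1] + 1, waiting[2])
                        if new not in chart[i]:
                            chart[i].add(new)
                            agenda.append(new)
    return chart


def recognize(tokens: Sequence[str], grammar: Grammar) -> bool:
    """Membership test: is *tokens* in L(grammar)?"""
    _check_alphabet(tokens, grammar)
    chart = _earley_chart(tokens, grammar)
    return _accepted(chart, tokens, grammar)


def _accepted(chart, tokens, grammar) -> bool:
    n = len(tokens)
    for rule_idx, dot, origin in chart[n]:
        rule = grammar.rules[rule_idx]
        if rule.lhs == grammar.start and origin == 0 and dot == len(rule.rhs):
            return True
    return False


def _check_alphabet(tokens: Sequence[str], grammar: Grammar) -> None:
    for tok in tokens:
        if tok not in grammar.terminals:
            raise GrammarError(f"token symbol {tok!r} is not in the grammar's terminal alphabet")


def parse(tokens: Sequence[str], grammar: Grammar) -> ParseTree | Rejection:
    """Parse a token-symbol sequence; return the canonical tree or a Rejection.

    Tokens outside the terminal alphabet are a contract violation (callers
    filter them upstream) and raise :class:`GrammarError`.
    """
    tokens = list(tokens)
    _check_alphabet(tokens, grammar)
    chart = _earley_chart(tokens, grammar)

    if not _accepted(chart, tokens, grammar):
        # First position whose chart set died: token index where progress stopped.
        for i in range(1, len(tokens) + 1):
            if not chart[i]:
                return Rejection(index=i - 1, reason=f"no derivation covers token {i - 1}")
        return Rejection(index=len(tokens), reason="input is a viable prefix but not a sentence")

    tree = _build_tree(grammar.start, 0, len(tokens), tokens, grammar, frozenset(), {})
    assert tree is not None, "recognizer accepted but tree extraction failed"
    return tree


def _build_tree(
    sym: str,
    start: int,
    end: int,
    tokens: Sequence[str],
    grammar: Grammar,
    path: frozenset[tuple[str, int, int]],
    memo: dict[tuple[str, int, int], "ParseTree | None"],
) -> ParseTree | None:
    """Canonical derivation of tokens[start:end] from *sym*, or None.

    Rules are tried in index order; each rhs element greedily takes the
    shortest viable span first.  ``path`` guards against unary/ε cycles
    (e.g. Location → Location Specific_Result with Specific_Result → ε),
    which would otherwise recurse forever; the guarded derivations are
    exactly the non-minimal ones, so no sentence is lost.
    """
    if grammar.is_terminal(sym):
        if end == start + 1 and (sym == WILDCARD or tokens[start] == sym):
            return ParseTree(label=tokens[start])
        return None

    key = (sym, start, end)
    if key in path:
        return None
    if key in memo:
        return memo[key]

    result: ParseTree | None = None
    new_path = path | {key}
    for rule in grammar.rules_for(sym):
        children = _assign_spans(rule.rhs, 0, start, end, tokens, grammar, new_path, memo)
        if children is not None:
            result = ParseTree(label=sym, children=tuple(children))
            break
    # Only safe to memoize when no cycle guard was involved in pruning;
    # failures on the guard path may succeed from a different path, so only
    # successes and unguarded failures are cached.
    if result is not None or not path:
        memo[key] = result
    return result


def _assign_spans(
    rhs: tuple[str, ...],
    idx: int,
    start: int,
    end: int,
    tokens: Sequence[str],
    grammar: Grammar,
    path: frozenset[tuple[str, int, int]],
    memo: dict,
) -> list[ParseTree] | None:
    if idx == len(rhs):
        return [] if start == end else None
    sym = rhs[idx]
    if idx == len(rhs) - 1:
        split_points: Sequence[int] = (end,)
    else:
        split_points = range(start, end + 1)
    for mid in split_points:
        child = _build_tree(sym, start, mid, tokens, grammar, path, memo)
        if child is None:
            continue
        rest = _assign_spans(rhs, idx + 1, mid, end, tokens, grammar, path, memo)
        if rest is not None:
            return [child] + rest
    return None


def enumerate_trees(
    tokens: Sequence[str], grammar: Grammar, limit: int = 1000
) -> list[ParseTree]:
    """All distinct parse trees of *tokens* (cycle-free derivations only).

    Derivations that revisit the same (variable, span) on one path — the
    infinite families introduced by nullable cycles — are excluded; every
    minimal derivation is produced.  Used to check derivation invariance of
    the extraction stage on ambiguous sentences.
    """
    tokens = list(tokens)
    _check_alphabet(tokens, grammar)
    out: list[ParseTree] = []

    def derive(sym: str, start: int, end: int, path: frozenset) -> list[ParseTree]:
        if grammar.is_terminal(sym):
            if end == start + 1 and (sym == WILDCARD or tokens[start] == sym):
                return [ParseTree(label=tokens[start])]
            return []
        key = (sym, start, end)
        if key in path:
            return []
        new_path = path | {key}
        trees: list[ParseTree] = []
        for rule in grammar.rules_for(sym):
            for children in assign(rule.rhs, 0, start, end, new_path):
                trees.append(ParseTree(label=sym, children=tuple(children)))
                if len(trees) > limit:
                    return trees
        return trees

    def assign(rhs: tuple[str, ...], idx: int, start: int, end: int, path: frozenset):
        if idx == len(rhs):
            if start == end:
                yield []
            return
        sym = rhs[idx]
        splits = (end,) if idx == len(rhs) - 1 else range(start, end + 1)
        for mid in splits:
            for child in derive(sym, start, mid, path):
                for rest in assign(rhs, idx + 1, mid, end, path):
                    yield [child] + rest

    for tree in derive(grammar.start, 0, len(tokens), frozenset()):
        out.append(tree)
        if len(out) >= limit:
            break
    return out
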