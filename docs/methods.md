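# Methods

This note documents the models, rules and design choices behind
`egfrtext`, the assumptions they rest on, and what the test suite does and
does not demonstrate.

## Problem setting

A molecular-pathology laboratory reports EGFR hotspot testing for lung
cancer as free text. The outcome space is small and stereotyped: the
mutation was *not detected*; it was *identified* at one location; it was
identified at two or more locations; or the test failed (*insufficient
DNA*, sometimes phrased as a *cancelled* test). Locations are the panel's
hotspots: exon 19 (deletions), exon 20 (insertions), T790M, L858R, L861Q,
G719X (the PCR assay detects G719S/G719A/G719C without distinguishing
them) and S768I. Because the language of the result sentence is this
constrained, a deterministic rule-based extractor is adequate and
auditable; no statistical NLP is involved anywhere in the pipeline.

## RTF stripping

One export dialect stores report bodies in Rich Text Format. The stripper
is a single-pass tokenizer over the RTF source: group braces maintain a
state stack; control words are dropped unless they produce text (`\par`,
`\line` → newline; `\tab`; dash/quote entities); `\'hh` byte escapes decode
through a configurable code page (default Windows-1252, the dominant
dialect in clinical exports); `\uN` emits the code point and swallows the
`\ucN`-controlled fallback characters; destination groups carrying
metadata (font/colour tables, stylesheets, `info`, `pict`, and any
`\*`-prefixed group) are suppressed wholesale. Malformed input —
unbalanced braces, truncated escapes — degrades to best-effort text plus a
warning on the record rather than an exception, because a batch pipeline
must never lose a report to markup damage. Whitespace produced by
stripping is left alone; collapsing is the normalizer's job. Non-RTF input
(no `{\rtf` opener) passes through byte-identically.

No reference RTF implementation is bundled; fidelity is pinned by a
hand-derived fixture (every construct's expected rendering worked out from
the RTF specification) plus property tests: stripping is idempotent,
control-free text is untouched, and wrapping any report in the generator's
RTF envelope and stripping recovers it exactly.

## Lexical analysis

Normalization applies the bare minimum: lowercase, trim, collapse internal
whitespace runs to single spaces. Newlines survive because section headers
are anchored at line starts — an exact-match rule on a configured header
list. Anchoring at line starts is a deliberate tightening: it prevents
narrative text ("the note: ...") from opening a section. Duplicate headers
get suffixed keys (`note:#2`); text before the first header is kept as the
residual, which doubles as a fallback result section for header-less
reports.

Tokenization is longest-match, left-to-right over a small lexicon mapping
surface forms to token symbols in five categories (location, result,
specific_result, status, conjunction). Longest-match is the only
deterministic policy consistent with multi-word keys: "exon 19" never
tokenizes as bare "exon", "not detected" shadows "detected", and the
six-word phrase "test cancelled due to insufficient dna" beats its
"insufficient dna" substring. Everything else — articles, verbs, assay
boilerplate — is ignored. Morphology is handled by enumerating surface
variants ("deletion"/"deletions"/"del") rather than stemming; the
vocabulary is tiny and enumeration is exact. Synonyms fold at the symbol
level: "positive"→identified, "negative"→not detected. "S78I" is accepted
as an alias of S768I (the form appears in some documentation as a typo).
The negation vocabulary is deliberately limited to "negative"/"not
detected"; general negation-scope handling (NegEx-style) is out of scope,
so a hypothetical "no mutation detected" phrasing would mis-tokenize — a
known limitation of the lexicon, acceptable for this report language.

## The grammar and parser

The result language is modeled as a CFG over token symbols. The core
productions (see `src/egfrtext/data/egfr_base.cfg`) say: a sentence is one
or more locations joined by conjunctions with an identified/not-detected
outcome, and a location may carry a deletion/insertion modifier on either
side (`Location → Location Specific_Result | Specific_Result Location`,
with `Specific_Result → ε`). The default grammar (`egfr.cfg`) adds three
status extensions: a bare `Result` sentence ("not detected" with no
location — the most common report), `InsufficientDNA`, and `Cancelled`.
Without the cancelled production, cancelled-test reports are the
extractor's blind spot; the regression suite runs both grammar variants
and asserts the failure reappears when the extension is removed.

The grammar is left-recursive (`S → S Conjunction Location`) and
ambiguous, which rules out recursive descent. Recognition uses an Earley
chart parser with the standard nullable-prediction completion, cubic in
sentence length and terminating on every input. A rejected sentence
reports the index of the first token at which no partial derivation
survives. Canonical trees are extracted by a memoized top-down search over
the accepted span: alternatives in production order, each child taking the
shortest viable span first, with a path guard that prunes derivations
revisiting the same (variable, span) — exactly the non-minimal cycles
introduced by the nullable `Specific_Result`, so no sentence is lost.
Correctness is pinned two ways: an independent brute-force oracle
(a fixpoint construction of the bounded language, exact up to the length
bound) must agree with the recognizer on *every* token string up to length
4 over the full alphabet (41 371 strings), and every returned tree must
validate against the grammar with leaves equal to the input.

A `WILDCARD` right-hand-side symbol (one arbitrary terminal) is supported
for grammar variants that want to capture unrecognized modifiers adjacent
to a location; the default grammar does not use it, since the lexer
already drops unknown words.

## Extraction semantics

The extractor reads the result off the canonical tree: status terminals
decide the overall status, and each maximal `Location` subtree contributes
one mutation call pairing its single location terminal with any modifier
in the same subtree. A modifier therefore binds to the location it shares
a `Location` node with and can never cross a conjunction. Although the
canonical tree is one of possibly many derivations, a property test
enumerates *all* derivations of every ambiguous short string and asserts
they produce the identical (status, calls) interpretation, so the choice
of canonical tree is immaterial to the output.

Resolution rules, in order: a cancelled status terminal wins, then
insufficient DNA; an identified result requires at least one location
(a bare "identified" with no location violates the record invariant and is
routed to `unparseable` for review); "not detected" negates the whole
panel, so any locations mentioned in a negative sentence are part of the
negation and yield no calls; repeated identical locations collapse to one
call, keeping a non-none modifier. Within a report, candidate sections are
tried in dialect priority order (assay section, then interpretation; the
plain-text dialect's `Result:`; residual as last resort) and the first
parseable sentence wins — the simplest auditable rule. Every report yields
exactly one result; `unparseable` results retain the raw sentence.

"Inconclusive" is deliberately not an extraction status: reports qualified
by non-definitive clinician comments still carry a definitive result
sentence, and comment analysis is out of scope (a test asserts extraction
is invariant to comment-section content). In the evaluation mapping,
`unparseable` predictions fall into the review's *inconclusive* column.

## Batch pipeline

Dialects are configuration, not code: each names its filter columns, body
column, RTF flag, header list and result-section priority. Filtering keeps
rows where the biomarker keyword occurs case-insensitively as a substring
in any filter column — substring, not word-boundary, so "EGFR Mutation
Assessment/Assay" variants match — and rows with missing patient
identifiers are retained. The short-result column is intentionally not a
filter or extraction source (it lacks location specificity). Duplicate
result identifiers are merged by grouping location records; conflicting
statuses within one identifier raise a data-quality warning rather than a
silent choice. The pipeline contains no unseeded randomness; two runs on
identical input produce byte-identical outputs, asserted bitwise in tests.

## Synthetic corpus generator

Ground-truthed corpora stand in for the private source data. The
generator's defaults are the study conditions: status mix
(0.74, 0.18, 0.06, 0.01, 0.01) over (not detected, identified at one
location, identified at 2+ locations, insufficient DNA, cancelled),
matching the proportions of a population-scale assay series; location
weights proportional to that series' per-location counts
(536 : 354 : 170 : 149 : 37 : 27 : 19 for exon 19, L858R, G719X, T790M,
S768I, L861Q, exon 20); multi-location split 257 : 33 : 20 over 2/3/4
locations; deletions attach to exon 19 and insertions to exon 20 with
probability 0.8. Reports are assembled in either dialect's column layout,
with the four-section body (optionally RTF-wrapped in a minimal envelope
with font/colour tables and an ignorable generator destination) or the
single `Result:` section. Sentence templates are deliberately richer than
the grammar — filler words, word-order variants, synonym phrasings at rate
0.2 — to exercise the ignore-unknown-words path; `noise_rate` injects
out-of-grammar sentences whose ground-truth status is `unparseable`.
Everything derives from one seeded generator, so corpora are byte-stable.

What the generator does *not* emulate: genuine clinician narrative,
report-to-patient multiplicity, spelling errors, mixed-polarity sentences,
or phrasing conventions beyond its template inventory. Passing round-trip
tests therefore demonstrate internal consistency of the pipeline on the
modeled report structure, not performance on any real laboratory's text.

## Evaluation protocol

Validation mimics a manual chart review: a seeded uniform simple random
sample without replacement (the accuracy study design this reproduces
reviewed 362 of 8 900 tests, ≈4.1%), a 4×4 actual-by-predicted confusion
matrix over (detected, not detected, inconclusive, not tested), and
accuracy, sensitivity and specificity. The correctness convention scores
detected→detected, not_detected→not_detected and inconclusive→not_detected
cells as correct; on the reference review counts this gives 353/362 =
97.5% accuracy with 100% sensitivity and specificity, the nine misses
being cancelled tests — the failure mode the grammar extension closes.
Because the matrix alone cannot verify *which* location was detected,
`compute_metrics` accepts per-sample correctness flags that override the
cell rule when full predictions are available, and a supplementary
per-location precision/recall table is provided. Zero-denominator metrics
are reported as undefined, never as zero.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for interactive runs: exhaustive
parser–oracle comparison at string length ≤ 4 (41 371 strings, seconds),
round-trip corpora of 1 000 reports per dialect, and a 200-report
enriched corpus for the extension regression. Offsets are 0-based
half-open; probability vectors must sum to 1 within 1e-9; sampling uses
numpy's PCG64 generator seeded explicitly everywhere.

## Known limitations

Single-language (English) lexicon; no spell correction; negation handling
limited to the enumerated vocabulary; mixed-polarity sentences are
unrepresentable by design and surface as unparseable; registry linkage of
extracted results to cancer-cohort identifiers is out of scope (an
allowlist hook on patient ids stands in for it); the wildcard modifier
semantics are a convention, disabled by default.
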