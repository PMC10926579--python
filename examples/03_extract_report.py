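"""Extract a structured EGFR result from a sectioned report.

The extractor picks the dialect's result section, tries its sentences in
order, and reads status plus (location, specific-result) pairs off the
first parseable sentence.
"""

from egfrtext import default_grammar, default_lexicon, extract_result, normalize, split_sections

body = """Interpretation and Comments:
EGFR mutation assessment was performed on the submitted biopsy.
EGFR Mutation Assay:
Deletions in Exon 19 and T790M identified.
Note:
Hotspot panel, exons 18-21.
Comment:
None."""

headers = ["interpretation and comments:", "egfr mutation assay:", "note:", "comment:"]
report = split_sections(normalize(body), headers)
result = extract_result(
    report, default_lexicon(), default_grammar(),
    ["egfr mutation assay:", "interpretation and comments:"],
)
print("status:", result.status)
for call in result.mutations:
    print(f"  mutation at {call.location} (specific result: {call.specific})")
# Two mutation calls: the deletion binds to exon 19; T790M carries none.
print("from section:", result.source_section)
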