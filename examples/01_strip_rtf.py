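"""Strip RTF markup from a laboratory report body.

Laboratory exports often wrap the report in Rich Text Format; the first
pipeline stage removes control words, braces and metadata destinations and
decodes character escapes, leaving readable plain text.
"""

from egfrtext import RtfPayload, rtf_to_text
from egfrtext.synth import rtf_wrap

report = "EGFR Mutation Assay:\nThe deletions in Exon 19 was identified.\nComment:\nNone."
wrapped = rtf_wrap(report)

print("--- RTF input (first 120 chars) ---")
print(wrapped[:120] + "...")
out = rtf_to_text(RtfPayload(raw=wrapped, source_id="demo-1"))
print("--- stripped plain text ---")
print(out.text)
# had_rtf confirms stripping ran; warnings would flag malformed markup.
print(f"had_rtf={out.had_rtf}, warnings={out.warnings}")
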