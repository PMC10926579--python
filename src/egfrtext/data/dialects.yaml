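# Dataset dialect presets: how each laboratory export stores its reports.
keyword: egfr
dialects:
  sad:
    # Southern-style export: multi-column layout, RTF-encoded report body,
    # four named sections; the assay section holds the result.
    filter_columns: [SPECIMEN_ACCN, SPECIMEN_SOURCE, TEST_NAME, TEST_TASK, RTF_RESULT]
    body_column: RTF_RESULT
    body_is_rtf: true
    headers:
      - "interpretation and comments:"
      - "egfr mutation assay:"
      - "note:"
      - "comment:"
    result_section_priority:
      - "egfr mutation assay:"
      - "interpretation and comments:"
    result_id_column: RESULT_ID
    patient_id_column: ULI
    # Documented source-specific filters (kept as reference; the generic
    # keyword filter is what runs):
    #   TEST_NAME contains "EGFR Result"
    #   TEST_TASK contains "EGFR (Interpretation)" or "EGFR (Qualitative)"
  nad:
    # Northern-style export: a single plain-text RESULTS column with one
    # "Result:" section.
    filter_columns: [RESULTS]
    body_column: RESULTS
    body_is_rtf: false
    headers:
      - "result:"
    result_section_priority:
      - "result:"
    result_id_column: RESULT_ID
    patient_id_column: ULI
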