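# EGFR grammar WITHOUT the cancelled / insufficient-DNA extension
# productions.  Status phrases then fall outside the terminal alphabet and
# such reports surface as unparseable — kept as a regression reference for
# the failure mode the extensions close.
S -> Location Result | Location Conjunction S | S Conjunction Location | Result
Location -> Location Specific_Result | Specific_Result Location
  | 'exon_19_location' | 'exon_20_location' | 't790m_location'
  | 'l858r_location' | 'l861q_location' | 'g719x_location' | 's768i_location'
Conjunction -> 'conjunction'
Result -> 'identified_result' | 'not_detected_result'
Specific_Result -> 'deletion_specific_result' | 'insertion_specific_result' | EPSILON
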