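# Simplified EGFR result-sentence grammar: the five core variables only.
# A result is one or more locations (each optionally carrying a specific
# result such as a deletion or insertion) joined by conjunctions, with an
# identified / not-detected outcome.
S -> Location Result | Location Conjunction S | S Conjunction Location
Location -> Location Specific_Result | Specific_Result Location
  | 'exon_19_location' | 'exon_20_location' | 't790m_location'
  | 'l858r_location' | 'l861q_location' | 'g719x_location' | 's768i_location'
Conjunction -> 'conjunction'
Result -> 'identified_result' | 'not_detected_result'
Specific_Result -> 'deletion_specific_result' | 'insertion_specific_result' | EPSILON
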