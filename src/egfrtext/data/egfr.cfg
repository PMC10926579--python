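# Default EGFR result-sentence grammar.
# Extends the core grammar with status-only sentences: a bare result
# ("not detected"), insufficient-DNA statements, and cancelled tests.
S -> Location Result | Location Conjunction S | S Conjunction Location
  | Result | InsufficientDNA | Cancelled
Location -> Location Specific_Result | Specific_Result Location
  | 'exon_19_location' | 'exon_20_location' | 't790m_location'
  | 'l858r_location' | 'l861q_location' | 'g719x_location' | 's768i_location'
Conjunction -> 'conjunction'
Result -> 'identified_result' | 'not_detected_result'
Specific_Result -> 'deletion_specific_result' | 'insertion_specific_result' | EPSILON
InsufficientDNA -> 'insufficient_dna_status'
Cancelled -> 'cancelled_status'
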