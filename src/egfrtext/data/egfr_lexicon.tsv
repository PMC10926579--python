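# EGFR result-sentence lexicon: surface form <TAB> token symbol.
# Categories are inferred from the symbol suffix.
# -- genomic locations screened by the assay --
exon 19	exon_19_location
exon19	exon_19_location
exon 20	exon_20_location
exon20	exon_20_location
t790m	t790m_location
l858r	l858r_location
l861q	l861q_location
# the assay detects G719S/G719A/G719C but does not distinguish them
g719x	g719x_location
g719s	g719x_location
g719a	g719x_location
g719c	g719x_location
g719s/g719a/g719c	g719x_location
g719s/a/c	g719x_location
s768i	s768i_location
s78i	s768i_location
# -- test results (synonyms fold to one symbol) --
identified	identified_result
positive	identified_result
detected	identified_result
not detected	not_detected_result
negative	not_detected_result
# -- specific results attached to locations --
deletion	deletion_specific_result
deletions	deletion_specific_result
del	deletion_specific_result
insertion	insertion_specific_result
insertions	insertion_specific_result
ins	insertion_specific_result
duplication	insertion_specific_result
# -- status phrases (whole-phrase matches beat their parts) --
insufficient dna	insufficient_dna_status
insufficient tumor for testing	insufficient_dna_status
test cancelled	cancelled_status
test canceled	cancelled_status
test cancelled due to insufficient dna	cancelled_status
test canceled due to insufficient dna	cancelled_status
# -- conjunctions joining multiple locations --
and	conjunction
,	conjunction
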