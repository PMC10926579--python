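{\rtf1\ansi\ansicpg1252\deff0
{\fonttbl{\f0\fswiss\fcharset0 Arial;}{\f1\froman Times New Roman;}}
{\colortbl ;\red0\green0\blue0;\red255\green0\blue0;}
{\stylesheet{\s0 Normal;}{\s1 Heading;}}
{\*\generator LabSys 9.1;}
\f0\fs20\b Interpretation and Comments:\b0\par
EGFR mutation assessment was requested by Dr. Cot\'e9.\par
Specimen: lung biopsy \endash  right upper lobe.\par
\b EGFR Mutation Assay:\b0\par
The deletions in Exon 19 was identified.\par
\b Note:\b0\par
This assay screens exons 18\_21 of the EGFR gene.\par
Melting temperature 60\u176?C.\par
\b Comment:\b0\par
None.\par
}
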