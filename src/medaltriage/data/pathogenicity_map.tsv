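# raw_label	standardized_code
# Case-insensitive mapping of free-form pathogenicity labels (as observed in
# ClinVar and locus-specific databases) onto the five-tier codes B/LB/VUS/LP/P.
# Labels not listed here are reported as "unmapped", never silently promoted.
pathogenic	P
pathogenic/likely pathogenic	LP
likely pathogenic	LP
probably pathogenic	LP
possibly pathogenic	LP
uncertain significance	VUS
variant of uncertain significance	VUS
variant of unknown significance	VUS
uncertain	VUS
unknown	VUS
unknown significance	VUS
unclassified	VUS
vus	VUS
likely benign	LB
probably benign	LB
probably not pathogenic	LB
likely neutral	LB
benign	B
benign/likely benign	LB
neutral	B
non-pathogenic	B
not pathogenic	B
no known pathogenicity	B
polymorphism	B
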