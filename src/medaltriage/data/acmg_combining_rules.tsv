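# ACMG/AMP evidence-combining rules, transcribed as data so the transcription
# is auditable. Each row is one disjunct: the outcome fires when the tag set
# contains at least the listed number of codes of each strength class.
# Strength classes by code prefix: PVS (very strong), PS (strong),
# PM (moderate), PP (supporting), BA (stand-alone benign), BS (strong benign),
# BP (supporting benign).
# Final call: pathogenic-side and benign-side disjuncts are evaluated
# independently; if both sides fire (or neither does), the result is VUS.
outcome	min_pvs	min_ps	min_pm	min_pp	min_ba	min_bs	min_bp
P	1	1	0	0	0	0	0
P	1	0	2	0	0	0	0
P	1	0	1	1	0	0	0
P	1	0	0	2	0	0	0
P	0	2	0	0	0	0	0
P	0	1	3	0	0	0	0
P	0	1	2	2	0	0	0
P	0	1	1	4	0	0	0
LP	1	0	1	0	0	0	0
LP	0	1	1	0	0	0	0
LP	0	1	0	2	0	0	0
LP	0	0	3	0	0	0	0
LP	0	0	2	2	0	0	0
LP	0	0	1	4	0	0	0
B	0	0	0	0	1	0	0
B	0	0	0	0	0	2	0
LB	0	0	0	0	0	1	1
LB	0	0	0	0	0	0	2
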