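# Training-corpus group sizes per wild-type residue (cancer-related / neutral
# SAV counts) with the printed cancer:neutral ratio delta, plus the total row.
wt	n_cancer	n_neutral	delta_printed
ALA	187	657	0.2846
CYS	45	97	0.4639
ASP	216	412	0.5243
GLU	254	408	0.6225
PHE	85	127	0.6693
GLY	236	437	0.5400
HIS	77	188	0.4096
ILE	116	437	0.2654
LYS	98	263	0.3726
LEU	178	321	0.5545
MET	63	202	0.3119
ASN	90	340	0.2647
PRO	200	363	0.5510
GLN	83	212	0.3915
ARG	328	1248	0.2628
SER	217	432	0.5023
THR	150	505	0.2970
VAL	156	695	0.2245
TRP	24	42	0.5714
TYR	64	176	0.3636
TOTAL	2867	7562	0.3791
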