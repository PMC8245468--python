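# Reference cancer-probability scores and confusion calls for the 14 SAVs of
# the PI3K catalytic subunit case study (structure 5DXU). Inputs for checking
# the largest-probability decision rule (cancer iff score >= 0.5).
sav	type	score	call
P57S	cancer	0.8590	TP
Q75K	cancer	0.9973	TP
R104C	neutral	0.1016	TN
K111E	cancer	0.6590	TP
P134L	cancer	0.7545	TP
S361F	cancer	0.9408	TP
N380H	cancer	0.9521	TP
L634F	cancer	0.8879	TP
H677R	cancer	0.0507	FN
E713K	cancer	0.8438	TP
A723V	cancer	0.8595	TP
I776T	cancer	0.9656	TP
G890R	cancer	0.9350	TP
L977I	cancer	0.8000	TP
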