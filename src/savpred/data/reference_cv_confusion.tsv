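# Five-fold cross-validation confusion counts of the trained wild-type+mutant
# grouped system on its reference training corpus, with the printed metric
# values (4 d.p.) they correspond to. Used as worked-example inputs for the
# metric formulas.
wt	tp	tn	fp	fn	accuracy	sensitivity	specificity	mcc	precision	f1
ALA	119	616	41	68	0.8709	0.6364	0.9376	0.6081	0.7438	0.6859
CYS	43	93	4	2	0.9577	0.9556	0.9588	0.9040	0.9149	0.9348
ASP	160	375	37	56	0.8519	0.7407	0.9102	0.6664	0.8122	0.7748
GLU	212	341	67	42	0.8353	0.8346	0.8358	0.6602	0.7599	0.7955
PHE	67	118	9	18	0.8726	0.7882	0.9291	0.7331	0.8816	0.8323
GLY	192	406	31	44	0.8886	0.8136	0.9291	0.7528	0.8610	0.8366
HIS	69	182	6	8	0.9472	0.8961	0.9681	0.8710	0.9200	0.9079
ILE	97	428	9	19	0.9494	0.8362	0.9794	0.8436	0.9151	0.8739
LYS	80	258	5	18	0.9363	0.8163	0.9810	0.8357	0.9412	0.8743
LEU	154	292	29	24	0.8938	0.8652	0.9097	0.7702	0.8415	0.8532
MET	55	199	3	8	0.9585	0.8730	0.9851	0.8835	0.9483	0.9091
ASN	78	333	7	12	0.9558	0.8667	0.9794	0.8643	0.9176	0.8914
PRO	150	324	39	50	0.8419	0.7500	0.8926	0.6512	0.7937	0.7712
GLN	68	200	12	15	0.9085	0.8193	0.9434	0.7714	0.8500	0.8344
ARG	216	1189	59	112	0.8915	0.6585	0.9527	0.6538	0.7855	0.7164
SER	202	376	56	15	0.8906	0.9309	0.8704	0.7724	0.7829	0.8505
THR	118	490	15	32	0.9282	0.7867	0.9703	0.7907	0.8872	0.8339
VAL	97	681	14	59	0.9142	0.6218	0.9799	0.6912	0.8739	0.7266
TRP	23	41	1	1	0.9697	0.9583	0.9762	0.9345	0.9583	0.9583
TYR	47	169	7	17	0.9000	0.7344	0.9602	0.7356	0.8704	0.7966
TOTAL	2247	7111	451	620	0.8973	0.7837	0.9404	0.7382	0.8328	0.8075
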