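gene	aa_length
TP53	393
APC	2843
KRAS	189
NRAS	189
BRAF	766
PIK3CA	1068
SMAD4	552
FBXW7	707
CTNNB1	781
KMT2C	4911
BCL9	1426
ERBB3	1342
EP300	2414
FAT3	4589
FAT4	4981
CARD11	1154
MSH2	934
MSH6	1360
MLH1	756
PMS2	862
POLD1	1107
POLE	2286
TTN	34350
MUC16	14507
SYNE1	8797
OBSCN	7968
NEB	8525
RYR1	5038
RYR2	4967
PCLO	5142
LRP1B	4599
CSMD1	3564
CSMD3	3707
DNAH5	4624
ZFHX4	3567
FLG	4061
TCF7L2	619
ATM	3056
ARID1A	2285
SOX9	509
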