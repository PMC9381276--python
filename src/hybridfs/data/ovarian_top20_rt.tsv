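feature	chi2_rank	f_stat_rank	mi_rank
MZ244.36855	5	18	25
MZ244.66041	4	5	8
MZ244.95245	2	2	1
MZ245.24466	1	1	2
MZ245.53704	3	3	3
MZ245.8296	6	4	4
MZ246.12233	7	6	5
MZ246.41524	8	7	10
MZ246.70832	9	8	11
MZ247.00158	11	12	13
MZ247.295	10	17	16
MZ247.58861	12	25	18
MZ247.88239	13	29	20
MZ261.88643	58	9	15
MZ417.73207	38	10	14
MZ434.68588	110	13	12
MZ435.07512	91	11	7
MZ435.46452	89	14	6
MZ463.95962	18	24	30
MZ464.36174	19	21	22
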