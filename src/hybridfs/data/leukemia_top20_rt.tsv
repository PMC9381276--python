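feature	chi2_rank	f_stat_rank	mi_rank
D88422_at	4	41	6
M11722_at	21	51	9
M16038_at	9	8	23
M19507_at	5	20	29
M22960_at	23	9	37
M23197_at	7	3	1
M27891_at	1	7	3
M63138_at	12	10	17
M84526_at	8	4	7
M92287_at	30	26	12
M96326_rna1_at	14	28	16
U05259_rna1_at	28	37	24
U46499_at	3	6	8
X17042_at	6	2	19
X59417_at	43	21	22
X61587_at	44	14	25
X62654_rna1_at	55	24	10
X95735_at	10	1	2
L09209_s_at	11	5	5
M31523_at	49	32	4
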