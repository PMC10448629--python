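row	algorithm_label	Cd4	Cd8a	Cd44	Sell	Ccr7	Gzmk	corrected_label
1	CD8_naive	0	4	5	0	0	2	CD8_Tem
2	CD8_Tem	0	1	3	3	1	4	CD8_Tcm
3	CD8_Tem	0	3	0	2	2	3	CD8_Tcm
4	CD8_Tem	0	3	2	1	1	6	CD8_Tcm
5	CD8_Tem	3	0	1	0	0	0	CD4_Tem
6	CD8_Tem	1	0	1	0	0	0	CD4_Tem
7	CD8_Tcm	2	0	0	0	0	0	CD4_Tcm
8	CD4_naive	3	0	4	0	0	0	CD4_Tem
9	CD4_naive	0	0	2	0	0	0	CD4_Tem
10	CD4_naive	1	0	1	0	0	0	CD4_Tem
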