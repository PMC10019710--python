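gene	g_s_ra	g_s_sle
ACO1	-0.590595045	-0.50551105
ACVR2A	0.709280042	-0.435212793
ALDOC	-0.546658025	-0.597643286
ANXA3	0.822525971	1.202492528
B4GALT5	0.418552469	0.829685649
CAMP	0.772005697	0.912300975
CBX7	-0.408857983	-0.672227052
CCNA2	0.455750226	0.866349784
DEFA4	0.540173033	0.767698011
EIF4B	-0.53424793	-1.122590172
GPS2	-0.728550581	-0.504034151
HIVEP2	-0.553931641	-0.408378921
ID3	-0.675277845	-0.745779182
IDH3B	-0.634854843	-0.423003627
IMPDH2	-0.930897806	-0.680928042
KLHL25	-0.547159894	-0.553192794
LDOC1	-0.459418035	-0.561365132
LHFPL2	0.545276617	0.830655827
MAPRE1	-0.476053704	0.40891743
NFIL3	0.523637677	1.073913485
NMT2	-0.627008356	-0.772803087
OASL	0.405973339	1.889199094
POLG2	-0.462825481	-0.632403304
RBL2	-0.820817384	-0.664047724
SERTAD2	-0.626126151	-0.608594971
SLC22A4	0.601572511	0.829446154
SRGN	0.589594132	0.90767445
TNFAIP6	0.723657312	1.336283459
USP13	-0.408076457	-0.726185249
VEGFB	-0.436833473	-0.517527546
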