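dataset_id	source	case	control	used	disease
GSE11909	PBMC	63	12	75	SLE
GSE50772	PBMC	61	20	81	SLE
GSE22098	Whole blood	40	43	83	SLE
GSE4588-SLE	CD4 T and B cells	26	15	41	SLE
GSE61635	Whole blood	99	30	129	SLE
GSE17755-SLE	PBMC	22	53	75	SLE
GSE24060	PBMC	6	18	24	SLE
GSE15573	PBMC	18	15	33	RA
GSE4588-RA	CD4 T and B cells	15	19	34	RA
GSE17755-RA	PBMC	112	53	165	RA
GSE1402	PBMC	15	15	30	RA
GSE56649	CD4 T cells	13	9	22	RA
GSE93272	Whole blood	232	43	275	RA
GSE68689	Whole blood	10	11	21	RA
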