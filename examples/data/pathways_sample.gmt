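PW0001	colorectal cancer signaling (sample)	EGFR	MTOR	GSK3B	CTNNB1	BRAF	MYC	AKT1	KRAS
PW0002	neurotransmitter receptor signaling (sample)	GABRA1	GABRA2	GABRB2	HTR2A	DRD2
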