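ENTITYA	TYPEA	ENTITYB	TYPEB	EFFECT	MECHANISM
EGFR	protein	MTOR	protein	up-regulates activity	phosphorylation
GSK3B	protein	CTNNB1	protein	down-regulates quantity by destabilization	phosphorylation
CTNNB1	protein	MYC	protein	up-regulates expression	transcriptional regulation
caffeine	chemical	EGFR	protein	down-regulates activity	binding
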