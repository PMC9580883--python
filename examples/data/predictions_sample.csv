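Common name,Uniprot ID,Probability*
EGFR,P00533,1.0
MTOR,P42345,0.41
GSK3B,P49841,0.12
CTNNB1,P35222,0.0
BRAF,P15056,0.0
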