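protein,compartment
EGFR,plasma membrane
MTOR,cytoplasm
GSK3B,cytoplasm
CTNNB1,nucleus
MYC,nucleus
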