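protein,function
CTNNB1,oncogene
BRAF,oncogene
GSK3B,tumor suppressor
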