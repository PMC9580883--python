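Molecule,Bioavailability Score,GI absorption,Consensus Log P
salicin,0.55,Low,-1.22
quercetin,0.55,High,1.63
saligenin,0.55,High,0.88
sorafenib,0.55,Low,4.2
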