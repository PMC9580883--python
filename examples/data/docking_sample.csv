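ligand_id,protein,energy,probability
sorafenib,EGFR,-8.4,1.0
sorafenib,BRAF,-7.8,1.0
quercetin,EGFR,-8.1,0.41
quercetin,MTOR,-7.5,0.12
quercetin,GSK3B,-7.0,0.12
saligenin,EGFR,-5.9,0.07
saligenin,GSK3B,-6.2,0.45
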