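name,smiles,class,role
salicin,OC[C@H]1O[C@@H](Oc2ccccc2CO)[C@H](O)[C@@H](O)[C@@H]1O,phenolic glycoside,phytochemical
quercetin,O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12,flavonoid,phytochemical
saligenin,OCc1ccccc1O,phenolic,phytochemical
sorafenib,CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1,drug-control,positive-control
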