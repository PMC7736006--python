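pathogen,MIC50,MIC90
Haemophilus influenzae,0.016,0.125
Streptococcus agalactiae,0.5,0.5
Streptococcus pneumoniae,0.016,0.5
Neisseria meningitidis,0.5,0.5
Listeria monocytogenes,2,4
Staphylococcus aureus,1,4
Escherichia coli,2,8
Staphylococcus epidermidis,2,16
Pseudomonas aeruginosa,8,128
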