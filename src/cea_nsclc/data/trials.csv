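study,treat_a,treat_b,hr,ci_low,ci_high
PARAMOUNT,PC,pemetrexed_maintenance,0.59,0.47,0.74
CONVINCE,pemetrexed_maintenance,icotinib,0.67,0.49,0.90
IPASS,chemo_doublet,gefitinib,0.48,0.36,0.64
NEJ002,chemo_doublet,gefitinib,0.30,0.22,0.41
WJTOG3405,chemo_doublet,gefitinib,0.49,0.33,0.71
PEM_DOUBLET_META,chemo_doublet,PC,0.90,0.80,1.01
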