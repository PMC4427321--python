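study_name,n_tumor,n_normal,in_individual_analysis,in_pancan
BRCA,914,106,1,1
KIRC,480,71,1,1
HNSC,303,37,0,1
LIHC,103,49,0,1
LUAD,446,57,0,1
PRAD,176,44,0,1
THCA,482,58,0,1
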