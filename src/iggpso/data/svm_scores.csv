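dataset,direction,ALL,IG,Chis,Pearson,PSO,GA,ACA,IG-PSO,IG-GA,IG-ACA,Chis-PSO,Pearson-PSO,IG-GPSO
Prostate-GE,higher_better,91.2,94.1,93.1,91.2,96.1,92.2,93.1,98.0,97.1,98.0,98.0,95.1,98.0
TOX-171,higher_better,95.9,97.7,97.7,98.8,99.4,100.0,98.8,100.0,98.8,100.0,100.0,100.0,100.0
GLIOMA,higher_better,76.0,82.0,82.0,82.0,84.0,84.0,82.0,90.0,88.0,90.0,95.0,84.0,96.0
Lung-discrete,higher_better,89.0,89.0,91.8,89.0,94.5,93.2,95.9,97.3,94.5,98.6,94.5,94.5,100.0
Prostate-GE,lower_better,5966,677,677,2983,2525,2927,2380,283,331,285,130,1141,63
TOX-171,lower_better,5748,769,769,2874,1732,2325,2314,338,388,364,363,1198,305
GLIOMA,lower_better,4434,1398,1398,2217,1561,1856,2010,426,590,530,317,1076,138
Lung-discrete,lower_better,325,111,111,163,142,153,139,52,48,53,50,59,77
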