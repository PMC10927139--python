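dataset,direction,ALL,IG,Chis,Pearson,PSO,GA,ACA,IG-PSO,IG-GA,IG-ACA,Chis-PSO,Pearson-PSO,IG-GPSO
Prostate-GE,higher_better,85.3,91.2,90.2,87.3,90.2,88.2,91.2,94.1,92.2,95.1,94.1,91.2,96.1
TOX-171,higher_better,85.4,89.5,90.6,89.5,95.3,91.2,93.6,97.1,94.7,95.9,97.7,95.9,97.7
GLIOMA,higher_better,72.0,82.0,82.0,78.0,86.0,76.0,84.0,82.0,90.0,92.0,86.0,86.0,94.0
Lung-discrete,higher_better,83.6,86.3,84.9,83.6,93.2,90.4,91.8,94.5,94.5,97.3,97.3,94.5,97.3
Prostate-GE,lower_better,5966,677,677,2983,2630,2506,2685,269,299,267,224,1283,27
TOX-171,lower_better,5748,769,769,2874,1800,2144,1890,287,376,336,282,1038,305
GLIOMA,lower_better,4434,1398,1398,2217,1305,968,1319,1398,486,480,726,982,60
Lung-discrete,lower_better,325,111,111,163,112,113,126,59,52,49,57,61,27
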