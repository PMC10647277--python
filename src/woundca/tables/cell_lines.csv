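cell_line,id,rho,alpha,b0,td,tm,reference,derived
HT-1080,1,2.7e-3,0.012,468,24,0.063,B5,b0
HT-1080,2,2.9e-3,0.128,371,24,0.075,B5,b0
HT-1080,3,1.6e-3,0.078,532,24,0.107,B5,b0
HT-1080,4,2.1e-3,0.078,638,24,0.075,B5,b0
HT-1080,5,1.5e-3,0.069,548,24,0.129,B5,b0
HT-1080,6,1.2e-3,0.069,687,24,0.082,B5,b0
HT-1080,7,,0.110,288,24,0.110,B58,
MDA-MB-231,8,1.0e-3,0.023,800,38,0.338,B31;B51,
MDA-MB-231,9,1.2e-3,0.042,930,38,0.075,B31;B51,
MDA-MB-231,10,2.3e-3,0.044,800,38,0.095,B31;B51,
MDA-MB-231,11,,0.040,288,38,0.476,B58,
MDA-MB-468,12,1.2e-3,0.031,800,47,0.154,B51,
HaCaT,13,1.2e-3,0.043,900,19,0.156,B49;B50,
HaCaT,14,1.7e-3,0.132,900,19,0.017,B49;B50,
HaCaT,15,2.5e-2,0.029,,19,0.078,B21,rho
Saos-2: HTB 85,16,,0.010,800,37,5.851,B59;B60,
Caco-2,17,1.2e-3,0.014,882,80,0.385,B61,rho;b0
BEAS,18,,0.054,500,26,0.188,B18,
MCF-7,19,,0.031,500,38,0.741,,
MCF-7,20,,0.040,287,38,0.54,B58,
NIH/3T3,21,1.3e-4,0.062,933,20,0.002,,
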