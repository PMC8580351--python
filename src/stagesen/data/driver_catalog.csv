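cancer_code,drivers_iranzo,drivers_bailey,k_stages,non_driver_iranzo,non_driver_bailey
ACC,1.61,0.52,5.10,3.48,4.58
BLCA,3.09,5.10,8.47,5.38,3.37
BRCA,1.62,1.84,3.72,2.10,1.88
CESC,1.02,1.89,1.57,0.55,-0.32
COADREAD,3.24,3.84,6.32,3.09,2.48
ESCA,1.72,1.87,6.64,4.92,4.77
GBM,1.51,1.84,5.65,4.15,3.81
HNSC,2.27,3.21,4.87,2.59,1.66
KICH,0.64,0.48,5.17,4.53,4.69
KIRC,1.63,1.45,4.69,3.06,3.24
KIRP,1.14,0.35,5.05,3.91,4.70
LAML,2.13,0.77,7.77,5.64,7.00
LIHC,1.38,1.84,4.69,3.30,2.85
LUAD,1.95,2.19,7.07,5.12,4.88
LUSC,2.19,2.68,7.69,5.50,5.01
MESO,1.24,0.87,10.2,8.97,9.33
OV,1.31,1.19,4.07,2.76,2.88
PAAD,2.44,2.19,7.02,4.58,4.83
PRAD,0.84,0.55,5.11,4.27,4.56
SARC,1.26,0.63,6.06,4.79,5.43
SKCM,2.15,2.45,5.67,3.52,3.22
STAD,1.05,1.92,7.02,5.97,5.10
TGCT,1.19,0.34,1.52,0.33,1.18
THCA,1.06,0.77,2.69,1.64,1.92
THYM,1.10,0.63,5.54,4.44,4.91
UCEC,3.71,7.34,3.40,-0.31,-3.94
UCS,2.51,3.13,5.59,3.09,2.46
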