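sex,cancer_code,u_mu,k,b,peak_rate_seer,peak_rate_model,peak_age_seer,peak_age_model,pc_seer,pc_model,pc_twovar,ratio_seer_twovar
female,ACC,0.005,4.42,0.0105,0.396,0.343,77.5,73.7,0.00015,0.00014,0.0077,0.02
female,BLCA,0.030,8.08,0.0097,64.6,72.7,92.5,90.2,0.022,0.021,0.0071,3.1
female,COAD,0.030,7.23,0.0095,193,188,87.5,90.2,0.062,0.061,0.0086,7.2
female,COADREAD,0.028,6.55,0.0093,220,213,87.5,90.6,0.075,0.076,0.010,7.1
female,ESCA,0.020,7.09,0.0098,11.7,12.1,87.5,88.1,0.0043,0.0039,0.0075,0.58
female,GBM,0.015,5.56,0.0101,12.6,11.1,77.5,81.4,0.0042,0.0042,0.0075,0.56
female,HNSC,0.015,5.13,0.0092,31.4,29.5,92.5,87.1,0.013,0.013,0.013,1.0
female,KICH,0.0083,4.74,0.0104,2.21,1.86,77.5,75.6,0.00081,0.00075,0.0074,0.11
female,KIRC,0.013,4.63,0.0104,23.2,18,72.5,75.6,0.0073,0.0075,0.0078,0.94
female,KIRP,0.011,5.22,0.0105,3.56,2.98,77.5,77.3,0.0011,0.0011,0.0065,0.17
female,LAML,0.023,7.33,0.0097,22.0,23.1,82.5,88.8,0.0082,0.0072,0.0075,1.1
female,LGG,0.00093,2.65,0.0101,0.364,0.213,32.5,61.4,0.00022,0.00013,0.013,0.017
female,LIHC,0.018,6.06,0.0101,17.3,16.2,82.5,82.4,0.0057,0.0056,0.0067,0.85
female,LUAD,0.029,6.73,0.0101,162,144,77.5,84.0,0.047,0.046,0.0060,7.8
female,LUSC,0.028,7.65,0.0102,69.0,51.9,77.5,85.3,0.016,0.015,0.0051,3.1
female,MESO,0.018,7.85,0.0091,2.29,2.15,102.5,96.3,0.00065,0.00068,0.012,0.052
female,PAAD,0.027,7.18,0.0100,60.7,59.5,82.5,86.0,0.019,0.018,0.0062,3.0
female,PCPG,0.004,4.45,0.0109,0.182,0.111,72.5,71.1,6.10E-05,4.50E-05,0.0064,0.0094
female,READ,0.0043,2.82,0.0038,28.3,49.3,82.5,170,0.013,0.076,0.20,0.063
female,SARC,0.0093,5.01,0.0077,7.67,6.65,97.5,104,0.0023,0.0035,0.031,0.074
female,SKCM,0.012,4.08,0.0083,59.4,58.8,82.5,91.0,0.029,0.033,0.022,1.3
female,STAD,0.022,6.98,0.0094,34.4,33.1,102.5,91.2,0.012,0.011,0.0099,1.2
female,THCA,0.0053,2.36,0.0102,38.3,36.6,52.5,56.3,0.022,0.022,0.013,1.7
female,THYM,0.0087,5.34,0.0107,0.793,0.658,67.5,75.7,0.00025,0.00024,0.0056,0.045
female,BRCA,0.023,3.72,0.0115,435,428,77.5,78.5,0.19,0.18,0.0065,30
female,CESC,0.0011,1.57,0.0105,13.8,11.9,42.5,49.5,0.0071,0.0078,0.0094,0.76
female,OV,0.011,4.07,0.0121,12.7,11.9,72.5,77.5,0.0045,0.0046,0.0048,0.96
female,UCEC,0.013,3.4,0.0121,84.0,73.1,67.5,73.2,0.03,0.032,0.0061,5.0
female,UCS,0.010,5.59,0.0125,0.711,0.519,82.5,80.6,0.00018,0.00016,0.0022,0.081
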