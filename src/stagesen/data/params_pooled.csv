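sex,cancer_code,u_mu,k,b,peak_rate_seer,peak_rate_model,peak_age_seer,peak_age_model,pc_seer,pc_model,pc_twovar,ratio_seer_twovar
pooled,ACC,0.0067,5.1,0.0105,0.329,0.319,77.5,76.6,0.00014,0.00012,0.0064,0.021
pooled,BLCA,0.036,8.47,0.0098,161,183,87.5,89.6,0.052,0.050,0.013,4.1
pooled,COAD,0.030,7.03,0.0095,203,203,87.5,90.1,0.068,0.067,0.014,5.0
pooled,COADREAD,0.027,6.32,0.0093,238,235,87.5,90.2,0.084,0.086,0.014,6.0
pooled,ESCA,0.022,6.64,0.0100,24.1,26,82.5,84.7,0.009,0.0085,0.0092,0.98
pooled,GBM,0.016,5.65,0.0101,15.7,14.3,77.5,81.6,0.0052,0.0053,0.0082,0.63
pooled,HNSC,0.017,4.87,0.0098,52.6,54.3,77.5,80.9,0.024,0.023,0.0088,2.7
pooled,KICH,0.010,5.17,0.0105,3.05,2.58,72.5,77.0,0.001,0.00098,0.0065,0.16
pooled,KIRC,0.014,4.69,0.0104,31.7,26.1,72.5,75.8,0.010,0.011,0.0066,1.5
pooled,KIRP,0.012,5.05,0.0105,8.04,6.33,72.5,76.4,0.0024,0.0024,0.0064,0.37
pooled,LAML,0.026,7.77,0.0098,29.6,31.4,82.5,88.8,0.010,0.0093,0.012,0.85
pooled,LGG,0.00064,2.34,0.0099,0.404,0.279,32.5,57.9,0.00026,0.00018,0.0026,0.10
pooled,LIHC,0.014,4.69,0.0102,28.4,28.7,77.5,77.5,0.011,0.012,0.0073,1.5
pooled,LUAD,0.030,7.07,0.0101,177,165,77.5,85.0,0.051,0.051,0.0091,5.7
pooled,LUSC,0.030,7.69,0.0101,95.8,81.4,77.5,85.8,0.024,0.023,0.0092,2.6
pooled,MESO,0.030,10.2,0.0099,5.09,5.69,87.5,90.8,0.0014,0.0013,0.014,0.10
pooled,PAAD,0.026,7.02,0.0100,66.5,65.7,82.5,85.5,0.020,0.021,0.0095,2.2
pooled,PCPG,0.0032,4.11,0.0103,0.188,0.133,92.5,73.4,7.30E-05,6.00E-05,0.0065,0.011
pooled,READ,0.011,4.12,0.0087,37.0,35.8,82.5,87.5,0.016,0.019,0.013,1.2
pooled,SARC,0.014,6.06,0.0084,8.74,8.96,97.5,98.9,0.0029,0.0037,0.025,0.12
pooled,SKCM,0.021,5.67,0.0094,107,107,82.5,87.9,0.045,0.043,0.013,3.6
pooled,STAD,0.024,7.02,0.0096,43.3,46.5,87.5,89.5,0.016,0.015,0.013,1.3
pooled,THCA,0.0059,2.69,0.0101,28.6,26.4,67.5,62.4,0.016,0.016,0.0042,3.7
pooled,THYM,0.0094,5.54,0.0106,0.747,0.705,67.5,77.0,0.00026,0.00025,0.0061,0.043
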