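sex,cancer_code,u_mu,k,b,peak_rate_seer,peak_rate_model,peak_age_seer,peak_age_model,pc_seer,pc_model,pc_twovar,ratio_seer_twovar
male,ACC,0.011,6.44,0.0107,0.347,0.301,87.5,79.2,0.00012,9.50E-05,0.010,0.011
male,BLCA,0.040,9,0.0098,344,380,92.5,91.0,0.10,0.10,0.017,6.1
male,COAD,0.029,6.9,0.0094,228,230,92.5,90.9,0.08,0.078,0.023,3.5
male,COADREAD,0.027,6.19,0.0092,274,279,92.5,91.2,0.10,0.11,0.026,3.9
male,ESCA,0.025,6.91,0.0101,42.5,47.4,82.5,84.9,0.016,0.015,0.014,1.1
male,GBM,0.019,6.16,0.0103,19.7,19.3,77.5,81.7,0.0067,0.0065,0.013,0.5
male,HNSC,0.019,5.07,0.0100,110,90.4,102.5,80.6,0.041,0.037,0.017,2.4
male,KICH,0.014,5.88,0.0106,4.13,3.65,72.5,78.2,0.0013,0.0012,0.011,0.12
male,KIRC,0.017,5.13,0.0105,41.9,37.9,72.5,76.9,0.014,0.014,0.013,1.0
male,KIRP,0.016,5.62,0.0106,13.5,11.4,72.5,77.2,0.0039,0.004,0.011,0.34
male,LAML,0.030,8.37,0.0098,42.0,45.5,87.5,89.5,0.014,0.013,0.016,0.85
male,LGG,9.20E-05,1.52,0.0085,0.502,0.363,82.5,40.3,0.0003,0.00030,0.032,0.0094
male,LIHC,0.015,4.57,0.0102,47.3,46.1,62.5,76.7,0.018,0.020,0.017,1.1
male,LUAD,0.035,7.81,0.0102,202,206,82.5,85.6,0.059,0.058,0.012,4.8
male,LUSC,0.035,8.4,0.0102,135,134,82.5,85.9,0.036,0.036,0.011,3.1
male,MESO,0.038,11.42,0.0100,11.0,12.7,92.5,91.5,0.0027,0.0027,0.014,0.19
male,PAAD,0.027,7.09,0.0101,74.9,75.7,82.5,85.1,0.023,0.023,0.014,1.7
male,PCPG,7.00E-06,1.33,-0.0168,0.407,NaN,92.5,-14.8,9.30E-05,NaN,NaN,NaN
male,READ,0.014,4.49,0.0089,51.0,49.9,97.5,87.8,0.023,0.025,0.031,0.73
male,SARC,0.015,6.4,0.0071,12.6,24.4,87.5,119,0.0042,0.012,0.13,0.031
male,SKCM,0.027,6.52,0.0093,220,195,102.5,91.0,0.075,0.070,0.024,3.1
male,STAD,0.026,7.24,0.0096,71.4,70.2,97.5,90.2,0.024,0.023,0.020,1.2
male,THCA,0.011,4.14,0.0103,19.8,18.3,72.5,73.6,0.0087,0.0082,0.017,0.52
male,THYM,0.012,6.11,0.0107,1.00,0.795,82.5,78.1,0.00028,0.00026,0.010,0.027
male,PRAD,0.035,5.11,0.0125,746,642,72.5,79.5,0.22,0.21,0.0055,40
male,TGCT,0.0013,1.52,0.0237,14.7,12.5,27.5,29.3,0.0040,0.0036,0.0067,0.60
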