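variety,temperature_C,duration_h,length_mean,length_sd,width_mean,width_sd,dvi_mean,dvi_sd,lw_mean,lw_sd
cabernet_sauvignon,,,5.81,0.20,3.81,0.13,0.96,0.10,1.52,0.08
cabernet_sauvignon,200,2,5.57,0.21,3.65,0.13,0.95,0.09,1.52,0.07
cabernet_sauvignon,200,8,5.31,0.27,3.54,0.15,0.95,0.08,1.49,0.09
cabernet_sauvignon,250,2,5.17,0.29,3.48,0.20,1.00,0.09,1.48,0.09
cabernet_sauvignon,250,8,4.97,0.22,3.43,0.19,0.89,0.07,1.47,0.13
cabernet_sauvignon,300,2,4.20,0.24,3.18,0.30,1.19,0.32,1.31,0.10
cabernet_sauvignon,300,8,4.46,0.24,3.45,0.28,1.40,0.26,1.31,0.12
cabernet_sauvignon,350,2,3.20,0.19,2.70,0.20,1.01,0.18,1.19,0.15
cabernet_sauvignon,350,8,2.70,0.19,2.43,0.24,1.12,0.21,1.13,0.14
tzuriman,,,5.83,0.27,4.27,0.21,1.14,0.09,1.36,0.07
tzuriman,200,2,5.61,0.23,4.04,0.19,1.11,0.08,1.39,0.07
tzuriman,200,8,5.62,0.38,4.08,0.20,1.21,0.09,1.38,0.08
tzuriman,250,2,5.40,0.27,3.88,0.23,1.15,0.12,1.39,0.08
tzuriman,250,8,5.28,0.20,3.78,0.16,1.16,0.08,1.40,0.08
tzuriman,300,2,4.66,0.25,3.76,0.21,1.48,0.14,1.24,0.09
tzuriman,300,8,4.45,0.36,3.56,0.21,1.28,0.21,1.29,0.11
tzuriman,350,2,3.51,0.22,2.90,0.20,1.21,0.15,1.25,0.11
tzuriman,350,8,3.27,0.24,2.73,0.24,1.14,0.16,1.13,0.13
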