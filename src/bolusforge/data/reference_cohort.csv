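patient,cw_dmean_norm_Gy,lung_dmean_conv_Gy,lung_dmean_3d_Gy,heart_dmean_conv_Gy,heart_dmean_3d_Gy,ci_conv,ci_3d,cw_dstd_conv_Gy,cw_dstd_3d_Gy
1,48.13,7.00,6.88,5.24,5.19,0.65,0.70,2.98,2.93
2,48.62,10.28,9.22,2.38,2.22,0.86,0.86,2.38,2.35
3,49.60,5.19,5.17,4.40,4.30,0.78,0.92,3.06,2.79
4,46.33,8.09,7.96,1.66,1.71,0.90,0.93,2.43,2.30
5,48.00,10.02,8.02,5.44,4.65,0.65,0.71,2.53,2.62
6,50.31,14.13,12.17,5.67,4.73,0.53,0.76,2.29,2.04
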