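sample,phase,glycyrrhizic_acid,liquiritin,isoliquiritin,total_flavonoids
e1a,1,1.82,1.72,8.84,0.86
e1b,1,1.69,3.46,12.25,3.19
e1c,1,2.28,0.97,1.78,3.17
e1d,1,3.17,2.41,16.86,0.06
e1e,1,5.65,3.38,0.58,1.48
e1f,1,5.22,5.15,3.86,7.75
e1g,1,6.01,4.76,15.47,3.75
e1h,1,1.78,3.10,38.09,3.93
e1i,1,5.54,4.99,NA,NA
e1j,1,1.51,NA,NA,NA
e1k,1,2.76,NA,NA,NA
e2a,2,2.78,3.09,4.76,2.88
e2b,2,4.29,3.30,29.87,6.78
e2c,2,0.04,10.11,36.90,9.42
e2d,2,6.36,8.65,15.08,9.49
e2e,2,0.81,5.88,5.46,15.34
e2f,2,4.46,14.83,5.44,11.11
e2g,2,0.85,1.55,36.67,13.23
e2h,2,3.36,4.04,0.09,17.39
e2i,2,0.83,1.24,2.97,14.29
e2j,2,12.58,19.25,8.48,11.51
e2k,2,5.31,5.16,4.78,10.28
e2l,2,4.29,15.46,4.64,2.86
e2m,2,13.78,5.71,22.78,3.04
e2n,2,2.30,12.58,18.42,6.68
e2o,2,NA,NA,1.61,9.11
e3a,3,51.19,14.08,4.01,9.60
e3b,3,4.64,11.55,92.73,2.82
e3c,3,7.92,22.88,78.88,2.76
e3d,3,1.65,10.59,55.67,21.92
e3e,3,18.76,7.47,74.38,12.41
e3f,3,6.53,25.21,99.38,22.22
e3g,3,NA,5.99,3.78,34.93
e3h,3,NA,10.84,49.16,10.74
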