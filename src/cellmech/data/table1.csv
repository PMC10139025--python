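line_id,morph_class,mean_E_kPa,sd_E_kPa,pattern,invasiveness_score,invasiveness_sd,ic50_uM,cv_percent
OAW42,epithelial,0.37,0.14,Gaussian,17,4,5.94,56.03
IGROV1,epithelial,0.66,0.21,Gaussian,8,3,1.01,45.25
SKOV3,fibroblastic,0.69,0.24,Bimodal,125,45,31.11,36.00
HEY,fibroblastic,0.96,0.58,Bimodal,176,26,55.00,40.81
TYKNU,fibroblastic,0.28,0.12,Gaussian,63,22,7.86,61.65
TYKNU_CpR,fibroblastic,0.52,0.23,Bimodal,91,22,30.58,42.43
OVCAR8,epithelial,0.58,0.28,Bimodal,38,24,12.69,13.34
OVCAR4,epithelial,1.13,0.50,Bimodal,16,4,37.7,27.69
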