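# Ready-function registry: linear SEP dose predictors D[cGy] = a * I_pivot + b
# a is stored with the x1e6 convention of the published table
# (a_x1e6 = 5.89 means a = 5.89e-6 cGy sr cm^2 MeV); b in cGy.
# Uncertainties are the published +/- values; r_squared is the fit Pcc^2.
region,shield,pivot_energy_MeV,a_x1e6,a_err_x1e6,b_cGy,b_err_cGy,r_squared
head,none,20,2.42,0.04,15.69,8.60,0.985
head,2mm,40,5.89,0.03,2.048,1.05,0.998
head,5mm,63,14.5,0.08,0.721,0.44,0.998
head,2cm,131,45.3,0.25,0.114,0.10,0.998
head,5cm,208,70.6,0.33,0.021,0.03,0.999
head,10cm,300,77.6,0.46,0.011,0.01,0.998
frontal,2mm,75,18.0,0.13,0.57,0.36,0.997
parietal,2mm,90,28.4,0.23,0.40,0.33,0.996
temporal,2mm,90,27.4,0.20,0.38,0.27,0.997
occipital,2mm,90,28.3,0.18,0.38,0.26,0.997
hippocampus,2mm,120,26.8,0.35,0.18,0.11,0.990
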