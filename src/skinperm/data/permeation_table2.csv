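drug,treatment,tlag_mean,tlag_sd,c_mean,c_sd,jss_mean,jss_sd,q8h_mean,q8h_sd,qer_printed,qer_sd_printed
Ferulic acid,control,2.40,0.15,307.06,10.12,14.79,0.77,83.50,5.48,1,
Ferulic acid,3% PEK,1.81,0.23,467.53,20.31,28.15,5.29,139.45,7.93,1.67,0.10
Ferulic acid,5% PEK,2.01,0.21,546.45,29.57,31.06,5.64,154.48,10.56,1.85,0.13
Rutin,control,1.47,0.69,29.82,3.05,0.60,0.04,3.69,0.51,1.00,
Rutin,3% PEK,2.43,0.3,37.55,5.63,1.67,0.20,10.70,1.23,2.90,0.33
Rutin,5% PEK,2.19,0.17,35.61,4.42,1.82,0.12,11.51,0.62,3.12,0.17
Paeoniflorin,control,1.32,0.46,62.42,5.70,2.07,0.05,14.05,1.10,1,
Paeoniflorin,3% PEK,1.60,0.29,72.93,6.89,3.99,0.87,31.05,4.25,2.21,0.30
Paeoniflorin,5% PEK,1.49,0.33,99.09,8.15,5.98,0.43,34.56,3.11,2.46,0.22
Puerarin,control,2.29,0.32,875.52,7.56,4.17,0.45,23.58,1.43,1,
Puerarin,3% PEK,1.22,0.2,948.70,5.68,13.50,0.05,69.80,1.68,2.96,0.07
Puerarin,5% PEK,1.84,0.29,1138.95,10.87,16.64,0.64,79.94,4.90,3.39,0.21
Luteolin,control,0.94,0.19,38.84,1.05,0.87,0.01,1.72,0.03,1,
Luteolin,3% PEK,1.77,0.43,36.03,2.13,1.26,0.08,4.35,0.32,2.53,0.19
Luteolin,5% PEK,1.71,0.44,40.11,3.95,2.39,0.07,4.40,0.26,2.56,0.15
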