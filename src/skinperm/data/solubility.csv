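name,delta,delta_diff
NP,18.68,
PEK,18.1,-0.58
Ferulic acid,23.54,4.86
Rutin,43.74,25.06
Paeoniflorin,25.02,6.34
Puerarin,45.34,26.66
Luteolin,43.82,25.14
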