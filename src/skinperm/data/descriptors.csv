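drug,mw,mp_c,logp,psa,hba,hbd
Ferulic acid,194.18,168-172,1.64,66.76,4,2
Rutin,610.52,195,-0.87,269.43,16,10
Paeoniflorin,480.46,124,-0.39,164.37,11,5
Puerarin,416.38,187-189,0.48,160.82,9,6
Luteolin,286.23,330,2.4,111.13,6,4
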