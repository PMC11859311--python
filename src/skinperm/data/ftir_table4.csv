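sample,band,position_cm1,peak_area,decrease_printed
control,asym_ch2,2918.07,106.28,
3% PEK,asym_ch2,,104.69,1.50
5% PEK,asym_ch2,,103.76,2.37
control,sym_ch2,2849.99,70.54,
3% PEK,sym_ch2,,69.22,1.87
5% PEK,sym_ch2,,69.10,2.04
control,amide_i,1648.69,,
3% PEK,amide_i,1646.92,,
5% PEK,amide_i,1645.14,,
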