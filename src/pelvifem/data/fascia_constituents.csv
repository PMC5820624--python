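name,c10_mpa,c01_mpa,c20_mpa
collagen_elastin_fascia,0,0.64785,0
adipose,0.000835,0,0.0128
smooth_muscle,0.0035,0,0.0155
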