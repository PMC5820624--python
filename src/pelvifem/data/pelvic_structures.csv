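name,c10_mpa,c01_mpa,c20_mpa
vesica_urethra,0.0835,0,0.092
uterus_vagina,0.4,0,3.2
rectum,0.73,0,1.4
cardinal_ligament,0.834,0,6.779
uterosacral_ligament,1.6,0,8.0
pubourethral_ligament,0.68,0,5.0
collagen_rich_fascia,0,0.64785,0
elastin_rich_fascia,0,0.1619625,0
pelvic_muscle,0.0625,0,0
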