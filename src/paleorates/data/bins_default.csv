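name,older,younger
Berriasian,145.0,139.8
Valanginian,139.8,132.6
Hauterivian,132.6,125.77
Barremian,125.77,121.4
Aptian,121.4,113.0
Albian,113.0,100.5
Cenomanian,100.5,93.9
Turonian,93.9,89.8
Coniacian,89.8,86.3
Santonian,86.3,83.6
Campanian,83.6,72.1
Maastrichtian,72.1,66.0
Puercan,66.0,63.3
Torrejonian,63.3,60.2
Tiffanian,60.2,56.8
Clarkforkian,56.8,55.8
Wasatchian,55.8,50.3
Bridgerian,50.3,46.2
Uintan,46.2,40.0
Duchesnean,40.0,37.5
Chadronian,37.5,33.9
Orellan,33.9,33.3
Whitneyan,33.3,30.6
Arikareean,30.6,18.5
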