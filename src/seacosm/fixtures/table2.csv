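group,season,percent,sd
EUB,winter,73.7,
EUB,spring,76.8,2.2
EUB,summer,52.1,2.2
EUB,fall,73.3,
EUB,average,74.1,10.2
CFB,winter,15.9,
CFB,spring,12.9,1.0
CFB,summer,8.4,1.1
CFB,fall,11.9,
CFB,average,11.6,3.0
ROSEO,winter,4.5,
ROSEO,spring,3.1,1.4
ROSEO,summer,3.0,0.1
ROSEO,fall,2.4,
ROSEO,average,3.6,1.9
SAR11,winter,43.5,
SAR11,spring,38.9,1.6
SAR11,summer,35.0,6.7
SAR11,fall,45.1,
SAR11,average,27.7,14.1
GAMMA,winter,2.0,
GAMMA,spring,3.2,0.6
GAMMA,summer,3.3,1.3
GAMMA,fall,5.8,
GAMMA,average,7.7,11.0
ALT,winter,1.9,
ALT,spring,0.1,0.0
ALT,summer,2.6,0.4
ALT,fall,4.3,
ALT,average,2.0,1.6
NOR5,winter,1.2,
NOR5,spring,0.7,0.4
NOR5,summer,2.0,0.5
NOR5,fall,1.7,
NOR5,average,2.4,1.5
AAP,winter,8.9,
AAP,spring,4.9,1.8
AAP,summer,16.7,5.0
AAP,fall,10.4,
AAP,average,6.0,1.4
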