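date,group,k_min,k_max,printed_spread
June 09,PRK,0.7,1.7,
June 09,EUB,0.7,1.7,
June 09,ROSEO,0.9,2.9,
June 09,SAR11,0.1,1.8,
June 09,GAMMA,1.0,3.6,
June 09,ALT,2.3,5.4,
June 09,NOR5,1.7,2.8,
June 09,CFB,0.7,1.5,
June 09,AAP,1.6,3.7,
July 09,PRK,0.2,1.3,
July 09,EUB,0.2,1.3,
July 09,ROSEO,0.3,1.9,
July 09,SAR11,0.1,1.5,
July 09,GAMMA,1.0,3.4,
July 09,ALT,1.4,5.8,
July 09,NOR5,1.3,2.9,
July 09,CFB,0.5,1.6,
July 09,AAP,0.3,2.4,
May 10,PRK,0.3,1.7,
May 10,EUB,0.2,1.5,
May 10,ROSEO,0.5,3.7,
May 10,SAR11,0.5,1.5,
May 10,GAMMA,1.0,2.7,
May 10,ALT,1.0,4.7,
May 10,NOR5,0.6,2.3,
May 10,CFB,0.2,2.2,
May 10,AAP,1.2,5.9,
July 11,PRK,0.2,0.6,
July 11,EUB,0.2,0.7,
July 11,ROSEO,0.4,1.8,
July 11,SAR11,0.1,0.5,
July 11,GAMMA,0.5,1.5,
July 11,ALT,0.4,3.4,
July 11,NOR5,0.2,1.3,
July 11,CFB,0.2,0.6,
July 11,AAP,0.5,2.2,
February 17,PRK,0.1,0.8,
February 17,EUB,0.0,0.8,
February 17,ROSEO,0.5,1.0,
February 17,SAR11,0.0,0.9,
February 17,GAMMA,0.2,4.5,
February 17,ALT,0.1,4.9,
February 17,NOR5,0.2,0.6,
February 17,CFB,0.1,1.6,
February 17,AAP,0.8,1.4,
April 17,PRK,0.1,0.3,
April 17,EUB,0.1,0.3,
April 17,ROSEO,0.1,0.6,
April 17,SAR11,0.2,0.6,
April 17,GAMMA,0.3,1.2,
April 17,ALT,0.5,3.0,
April 17,NOR5,0.3,1.3,
April 17,CFB,0.2,1.0,
April 17,AAP,0.2,0.6,
July 17,PRK,0.4,0.8,
July 17,EUB,0.6,0.9,
July 17,ROSEO,0.4,0.8,
July 17,SAR11,0.2,0.4,
July 17,GAMMA,1.0,2.4,
July 17,ALT,0.4,1.9,
July 17,NOR5,0.7,1.1,
July 17,CFB,0.4,0.7,
July 17,AAP,0.4,0.5,
November 17,PRK,0.1,0.4,
November 17,EUB,0.1,0.4,
November 17,ROSEO,0.2,0.6,
November 17,SAR11,0.0,0.5,
November 17,GAMMA,0.1,1.3,
November 17,ALT,0.0,1.8,
November 17,NOR5,0.3,0.7,
November 17,CFB,0.1,0.5,
November 17,AAP,0.5,1.2,
Range,PRK,0.1,1.7,1.6
Range,EUB,0.02,1.7,1.7
Range,ROSEO,0.1,2.9,2.8
Range,SAR11,0.03,1.8,1.8
Range,GAMMA,0.2,4.5,4.3
Range,ALT,0.1,5.8,5.7
Range,NOR5,0.2,2.9,2.7
Range,CFB,0.1,2.2,2.1
Range,AAP,0.2,5.9,5.7
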