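mixture,frequency_THz,intensity,origin
M1,0.70,0.3,BNL
M1,1.16,0.8,BCM
M1,1.35,0.9,BCM
M1,2.32,1.0,BCM
M2,1.24,1.0,TBZ
M2,1.95,0.9,TBZ
M2,2.58,0.8,TBZ
M3,1.24,1.0,TBZ
M3,1.66,0.6,TBZ
M3,1.95,0.9,TBZ
M3,2.32,1.0,BCM
M4,1.24,1.0,TBZ
M4,1.95,0.9,TBZ
M4,2.32,1.0,BCM
M4,2.58,0.8,TBZ
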