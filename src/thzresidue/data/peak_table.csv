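molecule,source,frequency_THz,intensity,vibration_mode
BNL,dft,0.66,1.0,vring
BNL,dft,1.13,1.0,d(C-N)oop
BNL,dft,2.18,1.0,d(C-O)ip
BNL,experiment,0.70,1.0,vring
BNL,experiment,1.07,0.6,d(C-N)oop
BNL,experiment,2.20,0.5,d(C-O)ip
BCM,dft,0.49,1.0,"d(C-O)ip, d(C-)ip"
BCM,dft,1.15,1.0,"d(C-O)ip, d(C-)ip"
BCM,dft,1.36,1.0,dring
BCM,dft,2.32,1.0,d(C-O)ip
BCM,dft,2.64,1.0,dring
BCM,experiment,1.16,0.8,"d(C-O)ip, d(C-)ip"
BCM,experiment,1.35,0.9,dring
BCM,experiment,2.32,1.0,d(C-O)ip
TBZ,dft,0.23,1.0,d(C-C)ip
TBZ,dft,0.91,1.0,dring
TBZ,dft,1.35,1.0,dring
TBZ,dft,1.56,1.0,v(C-C)ip
TBZ,dft,1.90,1.0,d(C-C)ip
TBZ,dft,2.62,1.0,d(C-H)ip
TBZ,experiment,0.92,0.7,dring
TBZ,experiment,1.24,1.0,dring
TBZ,experiment,1.66,0.6,v(C-C)ip
TBZ,experiment,1.95,0.9,d(C-C)ip
TBZ,experiment,2.58,0.8,d(C-H)ip
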