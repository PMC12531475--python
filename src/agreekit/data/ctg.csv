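patient_id,A,B,C,D,E
p01,1,1,1,1,1
p02,1,1,1,1,1
p03,1,1,1,1,1
p04,1,1,1,1,1
p05,1,1,1,1,0
p06,1,0,1,0,1
p07,0,1,1,1,0
p08,0,0,1,1,0
p09,0,0,1,0,0
p10,0,0,0,0,1
p11,0,0,0,0,1
p12,0,0,0,0,1
p13,0,0,0,0,1
p14,0,0,0,0,1
p15,0,0,0,0,1
p16,0,0,0,0,1
p17,0,0,0,0,0
p18,0,0,0,0,0
p19,0,0,0,0,0
p20,0,0,0,0,0
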