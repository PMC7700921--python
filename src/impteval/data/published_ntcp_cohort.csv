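group,patient,pericarditis,liver_failure,pneumonitis
S-I,1,0.0002,0.0000,0.0000
S-I,2,0.0029,0.0000,0.0000
S-I,3,0.0002,0.0013,0.0000
S-I,4,0.0000,0.0000,0.0000
S-I,5,0.0001,0.0000,0.0000
S-I,6,0.0007,0.0001,0.0000
S-I,7,0.0650,0.0014,0.0000
S-I,8,0.0002,0.0000,0.0000
S-I,9,0.0173,0.0000,0.0000
S-I,10,0.0008,0.0001,0.0000
R-L,1,0.0039,0.0351,0.0004
R-L,2,0.0046,0.0009,0.0000
R-L,3,0.0027,0.0043,0.0000
R-L,4,0.0006,0.0000,0.0000
R-L,5,0.0072,0.0050,0.0000
R-L,6,0.0032,0.0000,0.0000
R-L,7,0.0095,0.0857,0.0000
R-L,8,0.0003,0.0011,0.0000
R-L,9,0.0050,0.0266,0.0000
R-L,10,0.0001,0.0000,0.0000
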