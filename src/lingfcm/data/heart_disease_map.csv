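# concepts: E;FH;C;BW;BP;HD
source,target,signed_weight
E,E,1.000000
E,C,-1.000000
E,BW,-1.000000
E,HD,-1.000000
FH,FH,1.000000
FH,C,1.000000
FH,BW,1.000000
FH,BP,1.000000
C,C,1.000000
C,HD,1.000000
BW,BW,1.000000
BW,BP,1.000000
BW,HD,1.000000
BP,C,1.000000
BP,BP,1.000000
BP,HD,1.000000
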