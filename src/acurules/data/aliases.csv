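alias,canonical
L,LU
P,PC
H,HT
K,KI
UB,BL
DU,GV
RN,CV
REN,CV
SJ,TE
LIV,LR
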