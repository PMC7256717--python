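Jia-2004: BL13,BL43,LU9,KI3,BL23,ST36,LU7,LU5,CV17,EXB1
Deering-2011: LI11,LI10,TE10,TE6,L5,L7
Fan-2011: EXB1,BL13,BL12,BL43,BL15,CV17,CV22,BL20,BL23,ST36
Gao-2011: EXB1,BL13,ST36,BL12,GV14,BL43,BL15,CV17,CV22,BL20,BL23
Xie-2014: ST36,BL13,EXB1,BL43,BL15,GV14,BL12
Yu-2014: BL13,BL12,CV17,EXB1,BL43,BL23,ST36,LU7,LU5,ST40,SP10
Lee-2015: GV14,BL13,BL20,BL23,BL17
Liu-2015: BL13,BL23,CV6,CV4,EXB1,CV17,ST36
Yang-2016: GV14,BL13,BL20,BL23,BL17
Chu-2017: ST36,BL23,BL43,EXB1,CV17,BL12,BL13,SP10,ST40,LU5,LU7
Lee-2017: BL13,BL12,CV17,EXB1,BL43,BL23,ST36,LU5,ST40,SP10
Shi-2017: CV17,CV12,CV6,GV20,LI6,LU7,LU9,ST36
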