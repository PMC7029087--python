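location,n_analyzed,admixture_hybrids,local_hybrids,n_assigned,class_hybrids,class_detail
BUR,15,0,0,15,0,
MOR,9,0,0,8,0,
ABE,24,1,0,23,0,
MURN,40,0,0,38,0,
MURS,24,0,0,24,0,
LANN,44,0,0,43,0,
LANS,23,0,0,23,0,
SEI,77,2,0,74,0,
ALDN,40,1,0,40,0,
ALDS,20,0,0,20,0,
BOR,42,0,0,41,0,
TIR,49,0,0,49,0,
CAG,55,0,0,54,0,
RED,40,0,0,37,0,
GUI,47,1,0,47,0,
ALC,42,0,0,42,0,
CAN,24,0,0,24,0,
MAR,24,0,0,24,0,
MOU,24,2,1,24,2,F2:2
VIA,39,0,0,39,0,
MOI,35,0,0,35,0,
POV,23,0,0,23,0,
MIN,70,2,2,70,3,BCO:3
AGU,32,0,0,32,0,
CMU,111,52,63,77,27,F2:3;BCO:18;BCF:6
LEC,46,0,0,46,0,
MAD,40,0,0,40,0,
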