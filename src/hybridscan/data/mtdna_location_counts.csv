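location,context,n,n_fabalis,n_obtusata,clade_I,clade_II,intro_fab_n,intro_obt_n
BUR,sympatric,15,14,1,15,0,0,1
MOR,undetermined,9,0,9,6,3,0,6
ABE,sympatric,17,17,0,15,2,2,0
MURN,sympatric,35,30,5,30,5,0,0
MURS,allopatric,15,15,0,15,0,0,0
LANN,sympatric,39,19,20,9,30,10,0
LANS,allopatric,22,22,0,15,7,7,0
SEI,sympatric,49,25,24,13,36,12,0
ALDN,allopatric,19,0,19,0,19,0,0
ALDS,sympatric,18,12,6,1,17,11,0
BOR,sympatric,42,27,15,23,19,9,5
TIR,sympatric,40,39,1,35,5,4,0
CAG,sympatric,41,22,19,27,14,4,9
RED,allopatric,23,0,23,5,18,0,5
GUI,sympatric,36,13,23,20,16,2,9
ALC,sympatric,35,14,21,16,19,1,3
CAN,allopatric,21,21,0,21,0,0,0
MAR,allopatric,19,19,0,12,7,7,0
MOU,allopatric,18,18,0,9,9,9,0
VIA,allopatric,20,0,20,0,20,0,0
MOI,allopatric,30,0,30,0,30,0,0
POV,allopatric,21,21,0,21,0,0,0
MIN,sympatric,66,34,32,34,32,0,0
AGU,allopatric,19,19,0,19,0,0,0
CMU,sympatric,54,19,35,23,31,7,11
LEC,allopatric,23,23,0,23,0,0,0
MAD,allopatric,16,16,0,16,0,0,0
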