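location,n,clade_I,clade_II
ABE,1,0,1
LANN,1,0,1
SEI,2,2,0
CAG,1,0,1
GUI,1,1,0
MOU,2,0,2
MIN,2,1,1
CMU,47,9,38
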