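hybrid_class,n,clade_I,clade_II
F2,5,0,5
BCO,17,4,13
BCF,5,1,4
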