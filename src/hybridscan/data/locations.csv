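code,name,context,species_present,ecotype,lat,lon
BUR,Burela,sympatric,both,ME/FI,43.666667,-7.356389
MOR,Moras,undetermined,obtusata,,43.718889,-7.473611
ABE,Abelleira,sympatric,both,FI,42.798056,-9.025
MURN,Muros North,sympatric,both,FI,42.773611,-9.051667
MURS,Muros South,allopatric,fabalis,FI,42.742778,-8.981389
LANN,Lanzada North,sympatric,both,ZS,42.464444,-8.867222
LANS,Lanzada South,allopatric,fabalis,ZS,42.460556,-8.871944
SEI,Seixinos,sympatric,both,ZS,42.457778,-8.823056
ALDN,Aldan North,allopatric,obtusata,,42.279722,-8.820278
ALDS,Aldan South,sympatric,both,FI,42.276667,-8.824722
BOR,Borna,sympatric,both,FI,42.280833,-8.696944
TIR,Tiran,sympatric,both,FI,42.263611,-8.754444
CAG,Cangas,sympatric,both,FI,42.255833,-8.787778
RED,Redondela,allopatric,obtusata,,42.2875,-8.622778
GUI,La Guia,sympatric,both,FI,42.258611,-8.703611
ALC,Alcabre,sympatric,both,FI,42.223611,-8.765833
CAN,Canido,allopatric,fabalis,FI,42.192222,-8.805278
MAR,As Marinas,allopatric,fabalis,ME,42.100278,-8.895278
MOU,Mougas,allopatric,fabalis,ME,42.060833,-8.890833
VIA,Viana do Castelo,allopatric,obtusata,,41.695833,-8.850556
MOI,Rio de Moinhos,allopatric,obtusata,,41.566667,-8.797222
POV,Povoa de Varzim,allopatric,fabalis,ME,41.384722,-8.774722
MIN,Mindelo,sympatric,both,ME,41.31,-8.7425
AGU,Agudela,allopatric,fabalis,ME,41.242778,-8.728889
CMU,Cabo do Mundo,sympatric,both,ME/FI,41.225833,-8.7175
LEC,Leca da Palmeira,allopatric,fabalis,ME,41.198333,-8.711944
MAD,Madalena,allopatric,fabalis,ME,41.102222,-8.662778
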