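residue,n_rotamers,max_sasa
ALA,1,129
ARG,9,274
ASN,9,195
ASP,9,193
CYS,3,167
GLN,27,225
GLU,27,223
GLY,1,104
HIS,6,224
ILE,9,197
LEU,9,201
LYS,9,236
MET,27,224
PHE,6,240
PRO,1,159
SER,3,155
THR,3,172
TRP,6,285
TYR,6,263
VAL,3,174
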