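# Reference heavy-atom topology of the 20 standard amino acids.
# Backbone N, CA, C, O plus side-chain heavy atoms; OXT and hydrogens are
# never part of the intactness check.
GLY: [N, CA, C, O]
ALA: [N, CA, C, O, CB]
SER: [N, CA, C, O, CB, OG]
CYS: [N, CA, C, O, CB, SG]
VAL: [N, CA, C, O, CB, CG1, CG2]
THR: [N, CA, C, O, CB, OG1, CG2]
ILE: [N, CA, C, O, CB, CG1, CG2, CD1]
LEU: [N, CA, C, O, CB, CG, CD1, CD2]
PRO: [N, CA, C, O, CB, CG, CD]
MET: [N, CA, C, O, CB, CG, SD, CE]
PHE: [N, CA, C, O, CB, CG, CD1, CD2, CE1, CE2, CZ]
TYR: [N, CA, C, O, CB, CG, CD1, CD2, CE1, CE2, CZ, OH]
TRP: [N, CA, C, O, CB, CG, CD1, CD2, NE1, CE2, CE3, CZ2, CZ3, CH2]
ASP: [N, CA, C, O, CB, CG, OD1, OD2]
GLU: [N, CA, C, O, CB, CG, CD, OE1, OE2]
ASN: [N, CA, C, O, CB, CG, OD1, ND2]
GLN: [N, CA, C, O, CB, CG, CD, OE1, NE2]
LYS: [N, CA, C, O, CB, CG, CD, CE, NZ]
ARG: [N, CA, C, O, CB, CG, CD, NE, CZ, NH1, NH2]
HIS: [N, CA, C, O, CB, CG, ND1, CD2, CE1, NE2]
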