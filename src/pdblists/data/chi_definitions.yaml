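# IUPAC side-chain torsion atom quadruples.
# chi_k for a residue type is the dihedral over the four named atoms;
# residue types absent from a chi level have that chi undefined.
chi1:
  SER: [N, CA, CB, OG]
  CYS: [N, CA, CB, SG]
  THR: [N, CA, CB, OG1]
  VAL: [N, CA, CB, CG1]
  ILE: [N, CA, CB, CG1]
  LEU: [N, CA, CB, CG]
  PRO: [N, CA, CB, CG]
  MET: [N, CA, CB, CG]
  PHE: [N, CA, CB, CG]
  TYR: [N, CA, CB, CG]
  TRP: [N, CA, CB, CG]
  ASP: [N, CA, CB, CG]
  GLU: [N, CA, CB, CG]
  ASN: [N, CA, CB, CG]
  GLN: [N, CA, CB, CG]
  LYS: [N, CA, CB, CG]
  ARG: [N, CA, CB, CG]
  HIS: [N, CA, CB, CG]
chi2:
  ILE: [CA, CB, CG1, CD1]
  LEU: [CA, CB, CG, CD1]
  PRO: [CA, CB, CG, CD]
  MET: [CA, CB, CG, SD]
  PHE: [CA, CB, CG, CD1]
  TYR: [CA, CB, CG, CD1]
  TRP: [CA, CB, CG, CD1]
  ASP: [CA, CB, CG, OD1]
  GLU: [CA, CB, CG, CD]
  ASN: [CA, CB, CG, OD1]
  GLN: [CA, CB, CG, CD]
  LYS: [CA, CB, CG, CD]
  ARG: [CA, CB, CG, CD]
  HIS: [CA, CB, CG, ND1]
chi3:
  MET: [CB, CG, SD, CE]
  GLU: [CB, CG, CD, OE1]
  GLN: [CB, CG, CD, OE1]
  LYS: [CB, CG, CD, CE]
  ARG: [CB, CG, CD, NE]
chi4:
  LYS: [CG, CD, CE, NZ]
  ARG: [CG, CD, NE, CZ]
chi5:
  ARG: [CD, NE, CZ, NH1]
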