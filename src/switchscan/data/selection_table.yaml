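# Rigid-body atom selection per residue type.
#
# Atoms are listed in topological order: N, CA, CB, side chain outward,
# then C, O.  The selection keeps backbone N/CA/C/O, CB, side-chain branch
# points and terminal heteroatoms, and drops intermediate ring carbons
# (TYR drops CD1/CE1/CZ/CE2/CD2; ARG drops CZ).  Users may edit this file
# (or point the pipeline at another one) to substitute their own table.
ALA: [N, CA, CB, C, O]
ARG: [N, CA, CB, CG, CD, NE, NH1, NH2, C, O]
ASN: [N, CA, CB, CG, OD1, ND2, C, O]
ASP: [N, CA, CB, CG, OD1, OD2, C, O]
CYS: [N, CA, CB, SG, C, O]
GLN: [N, CA, CB, CG, CD, OE1, NE2, C, O]
GLU: [N, CA, CB, CG, CD, OE1, OE2, C, O]
GLY: [N, CA, C, O]
HIS: [N, CA, CB, CG, ND1, NE2, C, O]
ILE: [N, CA, CB, CG1, CG2, CD1, C, O]
LEU: [N, CA, CB, CG, CD1, CD2, C, O]
LYS: [N, CA, CB, CG, CD, CE, NZ, C, O]
MET: [N, CA, CB, CG, SD, CE, C, O]
PHE: [N, CA, CB, CG, CZ, C, O]
PRO: [N, CA, CB, CG, CD, C, O]
SER: [N, CA, CB, OG, C, O]
THR: [N, CA, CB, OG1, CG2, C, O]
TRP: [N, CA, CB, CG, NE1, CH2, C, O]
TYR: [N, CA, CB, CG, OH, C, O]
VAL: [N, CA, CB, CG1, CG2, C, O]
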