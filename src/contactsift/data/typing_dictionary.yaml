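# Physicochemical typing dictionary for standard polymer residues and water.
# Flags per (residue, atom name). Backbone entries apply to every peptide
# residue unless overridden in the residue block (e.g. Pro N). Hydrogens carry
# no flags. Hetero groups are typed by connectivity rules plus SMARTS patterns
# (see patterns.yaml), not by this dictionary.
#
# Flag vocabulary: hbond_donor, hbond_acceptor, weak_donor, weak_acceptor,
# pos_ionisable, neg_ionisable, hydrophobe, aromatic, halogen, xbond_donor,
# xbond_acceptor, metal, carbonyl_oxygen, carbonyl_carbon.
#
# Hydrophobe rule applied throughout: carbon or sulphur with no N/O/P
# neighbour in the canonical residue topology. Weak donors are carbons that
# bear at least one hydrogen in the canonical residue.

water_names: [HOH, WAT, DOD]
water_atoms:
  O: [hbond_donor, hbond_acceptor]

peptide_backbone:
  N: [hbond_donor]
  CA: [weak_donor]
  C: [carbonyl_carbon]
  O: [hbond_acceptor, carbonyl_oxygen]
  OXT: [hbond_acceptor, neg_ionisable]

residues:
  ALA:
    atoms:
      CB: [hydrophobe, weak_donor]
  ARG:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [hydrophobe, weak_donor]
      CD: [weak_donor]
      NE: [hbond_donor, pos_ionisable]
      CZ: [pos_ionisable]
      NH1: [hbond_donor, pos_ionisable]
      NH2: [hbond_donor, pos_ionisable]
  ASN:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [carbonyl_carbon]
      OD1: [hbond_acceptor, carbonyl_oxygen]
      ND2: [hbond_donor]
    amides: [[CG, OD1, ND2]]
  ASP:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: []
      OD1: [hbond_acceptor, neg_ionisable]
      OD2: [hbond_acceptor, neg_ionisable]
  CYS:
    atoms:
      CB: [hydrophobe, weak_donor]
      SG: [hbond_donor, weak_acceptor, hydrophobe]
  GLN:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [hydrophobe, weak_donor]
      CD: [carbonyl_carbon]
      OE1: [hbond_acceptor, carbonyl_oxygen]
      NE2: [hbond_donor]
    amides: [[CD, OE1, NE2]]
  GLU:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [hydrophobe, weak_donor]
      CD: []
      OE1: [hbond_acceptor, neg_ionisable]
      OE2: [hbond_acceptor, neg_ionisable]
  GLY:
    atoms: {}
  HIS:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [aromatic]
      ND1: [aromatic, hbond_acceptor]
      CD2: [aromatic, weak_donor]
      CE1: [aromatic, weak_donor]
      NE2: [aromatic, hbond_acceptor]
    rings: [[CG, ND1, CE1, NE2, CD2]]
  ILE:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG1: [hydrophobe, weak_donor]
      CG2: [hydrophobe, weak_donor]
      CD1: [hydrophobe, weak_donor]
  LEU:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [hydrophobe, weak_donor]
      CD1: [hydrophobe, weak_donor]
      CD2: [hydrophobe, weak_donor]
  LYS:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [hydrophobe, weak_donor]
      CD: [hydrophobe, weak_donor]
      CE: [weak_donor]
      NZ: [hbond_donor, pos_ionisable]
  MET:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [hydrophobe, weak_donor]
      SD: [weak_acceptor, hydrophobe]
      CE: [hydrophobe, weak_donor]
  PHE:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [aromatic, hydrophobe]
      CD1: [aromatic, hydrophobe, weak_donor]
      CD2: [aromatic, hydrophobe, weak_donor]
      CE1: [aromatic, hydrophobe, weak_donor]
      CE2: [aromatic, hydrophobe, weak_donor]
      CZ: [aromatic, hydrophobe, weak_donor]
    rings: [[CG, CD1, CE1, CZ, CE2, CD2]]
  PRO:
    atoms:
      N: []
      CB: [hydrophobe, weak_donor]
      CG: [hydrophobe, weak_donor]
      CD: [weak_donor]
  SER:
    atoms:
      CB: [weak_donor]
      OG: [hbond_donor, hbond_acceptor]
  THR:
    atoms:
      CB: [weak_donor]
      OG1: [hbond_donor, hbond_acceptor]
      CG2: [hydrophobe, weak_donor]
  TRP:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [aromatic]
      CD1: [aromatic, weak_donor]
      NE1: [aromatic, hbond_donor]
      CD2: [aromatic]
      CE2: [aromatic]
      CE3: [aromatic, hydrophobe, weak_donor]
      CZ2: [aromatic, hydrophobe, weak_donor]
      CZ3: [aromatic, hydrophobe, weak_donor]
      CH2: [aromatic, hydrophobe, weak_donor]
    rings:
      - [CG, CD1, NE1, CE2, CD2]
      - [CD2, CE2, CZ2, CH2, CZ3, CE3]
  TYR:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG: [aromatic, hydrophobe]
      CD1: [aromatic, hydrophobe, weak_donor]
      CD2: [aromatic, hydrophobe, weak_donor]
      CE1: [aromatic, hydrophobe, weak_donor]
      CE2: [aromatic, hydrophobe, weak_donor]
      CZ: [aromatic]
      OH: [hbond_donor, hbond_acceptor]
    rings: [[CG, CD1, CE1, CZ, CE2, CD2]]
  VAL:
    atoms:
      CB: [hydrophobe, weak_donor]
      CG1: [hydrophobe, weak_donor]
      CG2: [hydrophobe, weak_donor]

nucleic_backbone:
  P: []
  OP1: [hbond_acceptor, neg_ionisable]
  OP2: [hbond_acceptor, neg_ionisable]
  OP3: [hbond_acceptor, neg_ionisable]
  "O5'": [hbond_acceptor]
  "O4'": [hbond_acceptor]
  "O3'": [hbond_acceptor]
  "O2'": [hbond_donor, hbond_acceptor]
  "C1'": [weak_donor]
  "C2'": [weak_donor]
  "C3'": [weak_donor]
  "C4'": [weak_donor]
  "C5'": [weak_donor]

# Residue name -> base block; covers both ribo- and deoxyribonucleotides.
nucleotides:
  A: adenine
  DA: adenine
  G: guanine
  DG: guanine
  C: cytosine
  DC: cytosine
  U: uracil
  DT: thymine

bases:
  adenine:
    atoms:
      N9: [aromatic]
      C8: [aromatic, weak_donor]
      N7: [aromatic, hbond_acceptor]
      C5: [aromatic]
      C6: [aromatic]
      N6: [hbond_donor]
      N1: [aromatic, hbond_acceptor]
      C2: [aromatic, weak_donor]
      N3: [aromatic, hbond_acceptor]
      C4: [aromatic]
    rings:
      - [N9, C8, N7, C5, C4]
      - [C4, C5, C6, N1, C2, N3]
  guanine:
    atoms:
      N9: [aromatic]
      C8: [aromatic, weak_donor]
      N7: [aromatic, hbond_acceptor]
      C5: [aromatic]
      C6: [aromatic]
      O6: [hbond_acceptor, carbonyl_oxygen]
      N1: [aromatic, hbond_donor]
      C2: [aromatic]
      N2: [hbond_donor]
      N3: [aromatic, hbond_acceptor]
      C4: [aromatic]
    rings:
      - [N9, C8, N7, C5, C4]
      - [C4, C5, C6, N1, C2, N3]
  cytosine:
    atoms:
      N1: [aromatic]
      C2: [aromatic]
      O2: [hbond_acceptor, carbonyl_oxygen]
      N3: [aromatic, hbond_acceptor]
      C4: [aromatic]
      N4: [hbond_donor]
      C5: [aromatic, weak_donor]
      C6: [aromatic, weak_donor]
    rings: [[N1, C2, N3, C4, C5, C6]]
  uracil:
    atoms:
      N1: [aromatic]
      C2: [aromatic]
      O2: [hbond_acceptor, carbonyl_oxygen]
      N3: [aromatic, hbond_donor]
      C4: [aromatic]
      O4: [hbond_acceptor, carbonyl_oxygen]
      C5: [aromatic, weak_donor]
      C6: [aromatic, weak_donor]
    rings: [[N1, C2, N3, C4, C5, C6]]
  thymine:
    atoms:
      N1: [aromatic]
      C2: [aromatic]
      O2: [hbond_acceptor, carbonyl_oxygen]
      N3: [aromatic, hbond_donor]
      C4: [aromatic]
      O4: [hbond_acceptor, carbonyl_oxygen]
      C5: [aromatic]
      C6: [aromatic, weak_donor]
      C7: [hydrophobe, weak_donor]
      C5M: [hydrophobe, weak_donor]
    rings: [[N1, C2, N3, C4, C5, C6]]
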