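# SMARTS patterns for hetero-group (HETATM ligand) atom typing. Applied with
# RDKit when a chemically sensible molecule can be built from the inferred
# connectivity of the group; the connectivity rule layer (see chemo_typing)
# always runs and guarantees baseline typing when pattern matching is not
# possible (e.g. fragmentary ligands without hydrogens).
#
# Each entry: a SMARTS string, the 0-based index of the matched atom that
# receives the flags, and the flags to add.
patterns:
  - name: hydroxyl_oxygen
    smarts: "[OX2H1]"
    atom_index: 0
    flags: [hbond_donor, hbond_acceptor]
  - name: ether_oxygen
    smarts: "[OX2H0](C)C"
    atom_index: 0
    flags: [hbond_acceptor]
  - name: carbonyl_oxygen
    smarts: "[OX1]=[CX3]"
    atom_index: 0
    flags: [hbond_acceptor, carbonyl_oxygen]
  - name: carbonyl_carbon
    smarts: "[CX3]=[OX1]"
    atom_index: 0
    flags: [carbonyl_carbon]
  - name: carboxylate_oxygen
    smarts: "[CX3](=[OX1])[OX1,OX2H1]"
    atom_index: 1
    flags: [hbond_acceptor, neg_ionisable]
  - name: carboxylate_oxygen_2
    smarts: "[CX3](=[OX1])[OX1,OX2H1]"
    atom_index: 2
    flags: [hbond_acceptor, neg_ionisable]
  - name: phosphate_oxygen
    smarts: "[PX4]=,-[OX1]"
    atom_index: 1
    flags: [hbond_acceptor, neg_ionisable]
  - name: sulfate_oxygen
    smarts: "[SX4](=[OX1])(=[OX1])"
    atom_index: 1
    flags: [hbond_acceptor, neg_ionisable]
  - name: primary_secondary_amine
    smarts: "[NX3;H2,H1;!$(NC=[OX1])]"
    atom_index: 0
    flags: [hbond_donor]
  - name: amide_nitrogen
    smarts: "[NX3][CX3]=[OX1]"
    atom_index: 0
    flags: [hbond_donor]
  - name: quaternary_ammonium
    smarts: "[NX4+,NX4]"
    atom_index: 0
    flags: [pos_ionisable]
  - name: guanidinium_carbon
    smarts: "[NX3][CX3](=[NX2,NX3])[NX3]"
    atom_index: 1
    flags: [pos_ionisable]
  - name: aromatic_carbon
    smarts: "c"
    atom_index: 0
    flags: [aromatic]
  - name: aromatic_nitrogen_acceptor
    smarts: "[nX2]"
    atom_index: 0
    flags: [aromatic, hbond_acceptor]
  - name: aromatic_nh_donor
    smarts: "[nX3;H1]"
    atom_index: 0
    flags: [aromatic, hbond_donor]
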