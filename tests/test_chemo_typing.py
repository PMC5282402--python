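"""Atom typing, terminus correction, leniency, ring and amide perception."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import contactsift as cs
from contactsift import chemo_typing as ct
from conftest import analyse, assemble_pdb, atom_record, benzene_atoms, gly_gly_atoms, imidazole_ring

# Canonical heavy-atom inventories of the 20 standard amino acids (side
# chains; the backbone N/CA/C/O applies to all).
SIDE_CHAINS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}


def flags_of(res_name, atom_name, **kwargs):
    pdb = assemble_pdb([atom_record(atom_name, res_name, "A", 1, atom_name[0], (0, 0, 0))])
    result = analyse(pdb, **kwargs)
    return result.structure.atoms[0].type_flags


class TestDictionaryTyping:
    @pytest.mark.parametrize(
        "res_name, atom_name, expected",
        [
            ("SER", "OG", {ct.HBOND_DONOR, ct.HBOND_ACCEPTOR}),
            ("ASP", "OD1", {ct.HBOND_ACCEPTOR, ct.NEG_IONISABLE}),
            ("ASP", "OD2", {ct.HBOND_ACCEPTOR, ct.NEG_IONISABLE}),
            ("GLU", "OE1", {ct.HBOND_ACCEPTOR, ct.NEG_IONISABLE}),
            ("LYS", "NZ", {ct.HBOND_DONOR, ct.POS_IONISABLE}),
            ("ARG", "CZ", {ct.POS_IONISABLE}),
            ("LEU", "CD1", {ct.HYDROPHOBE, ct.WEAK_DONOR}),
            ("MET", "SD", {ct.WEAK_ACCEPTOR, ct.HYDROPHOBE}),
            ("GLY", "O", {ct.HBOND_ACCEPTOR, ct.CARBONYL_OXYGEN}),
            ("GLY", "C", {ct.CARBONYL_CARBON}),
        ],
    )
    def test_standard_residue_flags(self, res_name, atom_name, expected):
        assert expected <= flags_of(res_name, atom_name)

    def test_carboxyl_oxygens_keep_acceptor_character(self):
        # the lenient rule: delocalised carboxylate oxygens are acceptors
        for res, atom in [("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")]:
            flags = flags_of(res, atom)
            assert ct.HBOND_ACCEPTOR in flags
            assert ct.HBOND_DONOR not in flags

    def test_dictionary_covers_every_standard_heavy_atom(self, dictionary):
        for res_name, side_chain in SIDE_CHAINS.items():
            for atom_name in ["N", "CA", "C", "O", "OXT", *side_chain]:
                assert dictionary.lookup(res_name, atom_name) is not None, (
                    res_name,
                    atom_name,
                )

    def test_typing_is_idempotent(self, config, gly_gly_pdb):
        structure = cs.read_structure(gly_gly_pdb)
        bonds = cs.infer_bonds(structure, config)
        cs.assign_atom_types(structure, bonds, config)
        first = [set(a.type_flags) for a in structure.atoms]
        cs.assign_atom_types(structure, bonds, config)
        assert [set(a.type_flags) for a in structure.atoms] == first


class TestHeteroTyping:
    def test_chlorobenzene_chlorine(self, config):
        atoms = benzene_atoms(res_name="CLB")
        atoms.append(atom_record("CL", "CLB", "A", 1, "CL", (1.39 + 1.74, 0, 0), hetatm=True))
        result = analyse(assemble_pdb(atoms), config)
        cl = result.structure.residues[0].atom("CL")
        assert {ct.HALOGEN, ct.XBOND_DONOR, ct.HYDROPHOBE} <= cl.type_flags

    def test_fluorine_is_not_a_halogen_bond_donor(self, config):
        atoms = [
            atom_record("C1", "FLM", "A", 1, "C", (0, 0, 0), hetatm=True),
            atom_record("F1", "FLM", "A", 1, "F", (1.35, 0, 0), hetatm=True),
        ]
        result = analyse(assemble_pdb(atoms), config)
        f1 = result.structure.residues[0].atom("F1")
        assert ct.HALOGEN in f1.type_flags
        assert ct.XBOND_DONOR not in f1.type_flags

    def test_carboxylate_ligand_oxygens_are_acceptors_and_negative(self, config):
        # acetate: CH3-COO(-), both oxygens terminal on the carboxyl carbon
        atoms = [
            atom_record("C1", "ACT", "A", 1, "C", (-1.5, 0, 0), hetatm=True),
            atom_record("C", "ACT", "A", 1, "C", (0, 0, 0), hetatm=True),
            atom_record("O1", "ACT", "A", 1, "O", (0.62, 1.07, 0), hetatm=True),
            atom_record("O2", "ACT", "A", 1, "O", (0.62, -1.07, 0), hetatm=True),
        ]
        result = analyse(assemble_pdb(atoms), config)
        res = result.structure.residues[0]
        for name in ("O1", "O2"):
            flags = res.atom(name).type_flags
            assert {ct.HBOND_ACCEPTOR, ct.NEG_IONISABLE} <= flags

    def test_metal_flag_is_exclusive(self, config):
        atoms = [atom_record("ZN", "ZN", "A", 1, "ZN", (0, 0, 0), hetatm=True)]
        result = analyse(assemble_pdb(atoms), config)
        assert result.structure.atoms[0].type_flags == {ct.METAL}


class TestTerminusCorrection:
    def test_cterm_missing_oxt_typed_carboxylate_not_hydroxyl(self, config):
        pdb = assemble_pdb(gly_gly_atoms(oxt=False))
        result = analyse(pdb, config)
        o = result.structure.residues[1].atom("O")
        assert {ct.HBOND_ACCEPTOR, ct.NEG_IONISABLE} <= o.type_flags
        assert ct.HBOND_DONOR not in o.type_flags

    def test_nterm_nitrogen_is_protonated_amine(self, config, gly_gly_pdb):
        result = analyse(gly_gly_pdb, config)
        n = result.structure.residues[0].atom("N")
        assert {ct.HBOND_DONOR, ct.POS_IONISABLE} <= n.type_flags

    def test_nterm_proline_donor_requires_explicit_hydrogen(self, config):
        base = gly_gly_atoms(oxt=True)
        base[0] = atom_record("N", "PRO", "A", 1, "N", (0.0, 0.0, 0.0))
        pro = [atom_record(n, "PRO", "A", 1, e, xyz) for (n, _, _, _, e, xyz, _) in base[:4]]
        rest = base[4:]
        no_h = analyse(assemble_pdb(pro + rest), config)
        n = no_h.structure.residues[0].atom("N")
        assert n.type_flags == {ct.POS_IONISABLE}
        with_h = analyse(
            assemble_pdb(pro + [atom_record("H", "PRO", "A", 1, "H", (-0.95, 0.3, 0.0))] + rest),
            config,
        )
        n = with_h.structure.residues[0].atom("N")
        assert {ct.POS_IONISABLE, ct.HBOND_DONOR} <= n.type_flags

    def test_internal_residues_unchanged_by_terminus_pass(self, config):
        atoms = gly_gly_atoms(oxt=True)
        # extend to a tripeptide so residue 2 is internal
        atoms = atoms[:-1] + [
            atom_record("N", "GLY", "A", 3, "N", (6.63, 1.3, 0.0)),
            atom_record("CA", "GLY", "A", 3, "C", (7.6, 2.3, 0.0)),
            atom_record("C", "GLY", "A", 3, "C", (9.0, 2.3, 0.0)),
            atom_record("O", "GLY", "A", 3, "O", (9.0, 3.53, 0.0)),
        ]
        result = analyse(assemble_pdb(atoms), config)
        middle = result.structure.residues[1]
        assert middle.is_terminal == "none"
        assert ct.CARBONYL_OXYGEN in middle.atom("O").type_flags
        assert ct.NEG_IONISABLE not in middle.atom("O").type_flags


class TestHistidineLeniency:
    def make_his(self, with_hd1: bool = False) -> str:
        atoms = imidazole_ring("A", 1, (0, 0, 0))
        if with_hd1:
            # HD1 radially outward from ND1 (pentagon vertex at 72 degrees)
            direction = np.array([math.cos(math.radians(72)), math.sin(math.radians(72)), 0.0])
            atoms.append(atom_record("HD1", "HIS", "A", 1, "H", direction * (1.166 + 1.01)))
        return assemble_pdb(atoms)

    def test_lenient_makes_both_ring_nitrogens_donor_and_acceptor(self, config):
        result = analyse(self.make_his(), config, lenient=True)
        res = result.structure.residues[0]
        for name in ("ND1", "NE2"):
            assert {ct.HBOND_DONOR, ct.HBOND_ACCEPTOR} <= res.atom(name).type_flags

    def test_strict_follows_explicit_protonation(self, config):
        result = analyse(self.make_his(with_hd1=True), config, lenient=False)
        res = result.structure.residues[0]
        assert ct.HBOND_DONOR in res.atom("ND1").type_flags
        assert ct.HBOND_ACCEPTOR not in res.atom("ND1").type_flags
        assert ct.HBOND_ACCEPTOR in res.atom("NE2").type_flags
        assert ct.HBOND_DONOR not in res.atom("NE2").type_flags

    def test_strict_without_hydrogens_gives_acceptors_only(self, config):
        result = analyse(self.make_his(), config, lenient=False)
        res = result.structure.residues[0]
        for name in ("ND1", "NE2"):
            flags = res.atom(name).type_flags
            assert ct.HBOND_ACCEPTOR in flags and ct.HBOND_DONOR not in flags

    def test_non_his_residues_unaffected(self, config):
        assert flags_of("SER", "OG", lenient=True) == flags_of("SER", "OG", lenient=False)


class TestRingPerception:
    def test_ideal_benzene_centroid_and_normal(self, config):
        result = analyse(assemble_pdb(benzene_atoms()), config)
        assert len(result.rings) == 1
        ring = result.rings[0]
        assert np.allclose(ring.centroid, [0, 0, 0], atol=1e-12)
        assert abs(abs(ring.normal[2]) - 1.0) < 1e-12
        assert ring.planarity_rms < 1e-12

    def test_puckered_cyclohexane_is_not_aromatic(self, config):
        atoms = []
        for i in range(6):
            a = math.radians(60 * i)
            atoms.append(
                atom_record(
                    f"C{i+1}", "CHX", "A", 1, "C",
                    (1.46 * math.cos(a), 1.46 * math.sin(a), 0.25 * (-1) ** i),
                    hetatm=True,
                )
            )
        result = analyse(assemble_pdb(atoms), config)
        assert result.rings == []

    def test_tryptophan_has_two_rings(self, config):
        # fused 5+6 indole built from a pentagon and a hexagon sharing CD2-CE2
        pent_r, hex_edge = 1.166, 1.371
        pent_apothem = pent_r * math.cos(math.radians(36))
        half_edge = pent_r * math.sin(math.radians(36))
        hex_apothem = half_edge * math.sqrt(3)
        centre6 = np.array([pent_apothem + hex_apothem, 0.0, 0.0])
        positions = {
            "CE2": np.array([pent_apothem, half_edge, 0.0]),
            "CD2": np.array([pent_apothem, -half_edge, 0.0]),
        }
        # remaining pentagon vertices (CG adjacent to CD2, then CD1, NE1)
        for name, angle in [("NE1", 36 + 72), ("CD1", 36 + 144), ("CG", 36 + 216)]:
            a = math.radians(angle)
            positions[name] = np.array([pent_r * math.cos(a), pent_r * math.sin(a), 0.0])
        for name, angle in [("CZ2", 90), ("CH2", 30), ("CZ3", -30), ("CE3", -90)]:
            a = math.radians(angle)
            positions[name] = centre6 + hex_edge * np.array([math.cos(a), math.sin(a), 0.0])
        atoms = [
            atom_record(name, "TRP", "A", 1, "N" if name.startswith("N") else "C", xyz)
            for name, xyz in positions.items()
        ]
        result = analyse(assemble_pdb(atoms), config)
        assert len(result.rings) == 2
        assert sorted(len(r.atoms) for r in result.rings) == [5, 6]

    def test_ring_with_missing_member_skipped_with_warning(self, config):
        atoms = [a for a in imidazole_ring("A", 1, (0, 0, 0)) if a[0] != "CD2"]
        result = analyse(assemble_pdb(atoms), config)
        assert result.rings == []
        assert any("missing member" in w for w in result.warnings)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(perm=st.permutations(list(range(6))))
    def test_normal_invariant_under_member_permutation(self, perm):
        coords = np.array(
            [
                [1.39 * math.cos(math.radians(60 * i + 13)), 1.39 * math.sin(math.radians(60 * i + 13)), 0.02 * (i % 2)]
                for i in range(6)
            ]
        )
        _, n1, _ = ct.fit_plane(coords)
        _, n2, _ = ct.fit_plane(coords[list(perm)])
        assert min(np.linalg.norm(n1 - n2), np.linalg.norm(n1 + n2)) < 1e-9


class TestAmidePerception:
    def test_backbone_amide_from_dipeptide(self, config, gly_gly_pdb):
        result = analyse(gly_gly_pdb, config)
        assert len(result.amides) == 1
        group = result.amides[0]
        assert group.c_atom.res_seq == 1 and group.n_atom.res_seq == 2

    def test_asparagine_side_chain_amide(self, config):
        atoms = [
            atom_record("CG", "ASN", "A", 1, "C", (0, 0, 0)),
            atom_record("OD1", "ASN", "A", 1, "O", (0, 1.23, 0)),
            atom_record("ND2", "ASN", "A", 1, "N", (1.152, -0.665, 0)),
        ]
        result = analyse(assemble_pdb(atoms), config)
        assert len(result.amides) == 1

    def test_ligand_amide_matched_by_connectivity(self, config):
        # acetamide: CH3-C(=O)-NH2 with sp2 geometry
        atoms = [
            atom_record("C1", "ACM", "A", 1, "C", (-1.5, 0, 0), hetatm=True),
            atom_record("C", "ACM", "A", 1, "C", (0, 0, 0), hetatm=True),
            atom_record("O", "ACM", "A", 1, "O", (0, 1.23, 0), hetatm=True),
            atom_record("N", "ACM", "A", 1, "N", (1.152, -0.665, 0), hetatm=True),
        ]
        result = analyse(assemble_pdb(atoms), config)
        assert len(result.amides) == 1
        assert result.amides[0].n_atom.name == "N"
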