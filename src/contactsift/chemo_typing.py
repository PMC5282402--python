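"""Physicochemical atom typing, ring perception and amide-group perception.

Standard polymer residues and waters are typed from a shipped dictionary
(``data/typing_dictionary.yaml``); hetero groups are typed from their inferred
connectivity by a rule layer and, where a chemically sensible molecule can be
built, by SMARTS pattern matching with RDKit (``data/patterns.yaml``).

Two robustness features address typical defects of experimental models:

* the lenient-acceptor rule — any covalently bound oxygen is a hydrogen-bond
  acceptor — so carboxylates and other delocalised oxygens are never stripped
  of acceptor character;
* terminal main-chain atoms are typed from the dictionary even when sibling
  atoms are missing, so a C-terminal carboxylate with a missing OXT can never
  be mistaken for a hydroxyl (and typed as a spurious donor).

Histidine tautomer ambiguity is handled by an explicit leniency switch: when
enabled, both ring nitrogens are typed donor and acceptor; when disabled,
donor/acceptor assignment follows explicit hydrogens.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import yaml

from .config import GeometryConfig
from .structure_io import Atom, Residue, Structure, polymer_links

# Atom flag vocabulary. An atom may hold any subset; METAL is exclusive.
HBOND_DONOR = "hbond_donor"
HBOND_ACCEPTOR = "hbond_acceptor"
WEAK_DONOR = "weak_donor"
WEAK_ACCEPTOR = "weak_acceptor"
POS_IONISABLE = "pos_ionisable"
NEG_IONISABLE = "neg_ionisable"
HYDROPHOBE = "hydrophobe"
AROMATIC = "aromatic"
HALOGEN = "halogen"
XBOND_DONOR = "xbond_donor"
XBOND_ACCEPTOR = "xbond_acceptor"
METAL = "metal"
CARBONYL_OXYGEN = "carbonyl_oxygen"
CARBONYL_CARBON = "carbonyl_carbon"

ATOM_FLAGS = frozenset(
    {
        HBOND_DONOR,
        HBOND_ACCEPTOR,
        WEAK_DONOR,
        WEAK_ACCEPTOR,
        POS_IONISABLE,
        NEG_IONISABLE,
        HYDROPHOBE,
        AROMATIC,
        HALOGEN,
        XBOND_DONOR,
        XBOND_ACCEPTOR,
        METAL,
        CARBONYL_OXYGEN,
        CARBONYL_CARBON,
    }
)

_XBOND_DONOR_HALOGENS = frozenset({"CL", "BR", "I"})  # F is a negligible donor
_DOUBLE_BOND_CO_MAX = 1.30  # C=O distance ceiling, Angstrom


# ---------------------------------------------------------------------------
# Typing dictionary
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TypingDictionary:
    """Dictionary-based typing for standard residues, waters and termini."""

    residues: dict  # res_name -> {atom_name -> frozenset(flags)}
    rings: dict  # res_name -> list of atom-name tuples
    amides: dict  # res_name -> list of (C, O, N) atom-name tuples
    backbone: dict  # peptide backbone atom_name -> frozenset(flags)
    water_atoms: dict
    water_names: frozenset

    @classmethod
    def default(cls) -> "TypingDictionary":
        text = (resources.files("contactsift") / "data" / "typing_dictionary.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "TypingDictionary":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_mapping(cls, raw: dict) -> "TypingDictionary":
        def fs(flags: Iterable[str]) -> frozenset:
            flags = frozenset(flags or [])
            bad = flags - ATOM_FLAGS
            if bad:
                raise ValueError(f"unknown atom flags in dictionary: {sorted(bad)}")
            return flags

        residues: dict = {}
        rings: dict = {}
        amides: dict = {}
        backbone = {k: fs(v) for k, v in (raw.get("peptide_backbone") or {}).items()}
        for name, block in (raw.get("residues") or {}).items():
            residues[name] = {k: fs(v) for k, v in (block.get("atoms") or {}).items()}
            if block.get("rings"):
                rings[name] = [tuple(r) for r in block["rings"]]
            if block.get("amides"):
                amides[name] = [tuple(g) for g in block["amides"]]
        nuc_backbone = {k: fs(v) for k, v in (raw.get("nucleic_backbone") or {}).items()}
        bases = raw.get("bases") or {}
        for res_name, base in (raw.get("nucleotides") or {}).items():
            block = bases[base]
            atoms = {k: fs(v) for k, v in (block.get("atoms") or {}).items()}
            atoms.update(nuc_backbone)
            residues[res_name] = atoms
            if block.get("rings"):
                rings[res_name] = [tuple(r) for r in block["rings"]]
        return cls(
            residues=residues,
            rings=rings,
            amides=amides,
            backbone=backbone,
            water_atoms={k: fs(v) for k, v in (raw.get("water_atoms") or {}).items()},
            water_names=frozenset(raw.get("water_names") or ["HOH", "WAT", "DOD"]),
        )

    def lookup(self, res_name: str, atom_name: str) -> Optional[frozenset]:
        if res_name in self.water_names:
            if atom_name in self.water_atoms:
                return self.water_atoms[atom_name]
            return frozenset() if atom_name.startswith("O") else None
        block = self.residues.get(res_name)
        if block is not None and atom_name in block:
            return block[atom_name]
        if res_name in self.residues and atom_name in self.backbone:
            return self.backbone[atom_name]
        return None

    def is_standard(self, res_name: str) -> bool:
        return res_name in self.residues or res_name in self.water_names


# ---------------------------------------------------------------------------
# Planar groups
# ---------------------------------------------------------------------------


def fit_plane(coords: np.ndarray) -> tuple:
    """Least-squares plane: (centroid, unit normal, RMS out-of-plane deviation).

    The normal is the eigenvector of the smallest principal moment of the
    centred coordinates; its sign is arbitrary.
    """
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return centroid, normal, rms


@dataclasses.dataclass
class RingSystem:
    """An aromatic ring with centroid and least-squares-plane unit normal."""

    ring_id: int
    atoms: list
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float

    @property
    def residue(self) -> Residue:
        return self.atoms[0].residue

    @property
    def member_indices(self) -> frozenset:
        return frozenset(a.index for a in self.atoms)

    def __hash__(self) -> int:
        return id(self)


@dataclasses.dataclass
class AmideGroup:
    """A planar amide group C(=O)N, the subject of amide-pi interactions."""

    group_id: int
    c_atom: Atom
    o_atom: Atom
    n_atom: Atom
    h_atom: Optional[Atom]
    centroid: np.ndarray
    normal: np.ndarray

    @property
    def atoms(self) -> list:
        out = [self.c_atom, self.o_atom, self.n_atom]
        if self.h_atom is not None:
            out.append(self.h_atom)
        return out

    @property
    def residues(self) -> list:
        seen = []
        for a in (self.c_atom, self.n_atom):
            if a.residue not in seen:
                seen.append(a.residue)
        return seen

    @property
    def member_indices(self) -> frozenset:
        return frozenset(a.index for a in self.atoms)

    def __hash__(self) -> int:
        return id(self)


# ---------------------------------------------------------------------------
# Hetero-group rule typing
# ---------------------------------------------------------------------------


def _component_atoms(structure: Structure, bonds: dict) -> list:
    """Connected components (lists of atoms) over hetero residues only."""
    hetero = [a for r in structure.residues if r.polymer_class == "hetero" for a in r.atoms]
    hetero_idx = {a.index: a for a in hetero}
    seen: set = set()
    components = []
    for a in hetero:
        if a.index in seen:
            continue
        comp = []
        stack = [a.index]
        seen.add(a.index)
        while stack:
            i = stack.pop()
            comp.append(hetero_idx[i])
            for j in bonds.get(i, ()):
                if j in hetero_idx and j not in seen:
                    seen.add(j)
                    stack.append(j)
        components.append(sorted(comp, key=lambda x: x.index))
    return components


def _rule_type_component(component: list, atoms_by_index: dict, bonds: dict, config: GeometryConfig) -> None:
    has_explicit_h = any(a.element == "H" for a in component)
    for atom in component:
        el = atom.element.upper()
        flags = atom.type_flags
        neighbours = [atoms_by_index[j] for j in bonds.get(atom.index, ())]
        heavy = [n for n in neighbours if n.element != "H"]
        hydrogens = [n for n in neighbours if n.element == "H"]
        if el == "H":
            continue
        if config.is_metal(el):
            continue  # metal exclusivity applied globally later
        if el == "O":
            flags.add(HBOND_ACCEPTOR)
            carbon_partners = [n for n in heavy if n.element == "C"]
            if hydrogens:
                flags.add(HBOND_DONOR)
            if len(heavy) == 1 and carbon_partners:
                c = carbon_partners[0]
                d = float(np.linalg.norm(atom.coords - c.coords))
                sibling_o = [
                    atoms_by_index[j]
                    for j in bonds.get(c.index, ())
                    if j != atom.index and atoms_by_index[j].element == "O"
                ]
                terminal_sibling_o = [
                    o for o in sibling_o if len([k for k in bonds.get(o.index, ()) if atoms_by_index[k].element != "H"]) == 1
                ]
                if terminal_sibling_o:
                    # carboxylate-like: two terminal O on one carbon
                    flags.add(NEG_IONISABLE)
                elif d <= _DOUBLE_BOND_CO_MAX:
                    flags.add(CARBONYL_OXYGEN)
                elif not hydrogens and not has_explicit_h:
                    # terminal single-bonded O without modelled H: hydroxyl-like
                    flags.add(HBOND_DONOR)
            if len(heavy) == 1 and heavy[0].element in ("P", "S") and len(
                [k for k in bonds.get(atom.index, ()) if atoms_by_index[k].element != "H"]
            ) == 1:
                flags.add(NEG_IONISABLE)
            if not heavy and not hydrogens:
                flags.add(HBOND_DONOR)  # bare water-like oxygen
        elif el == "N":
            if hydrogens:
                flags.add(HBOND_DONOR)
            elif len(heavy) <= 2:
                flags.add(HBOND_DONOR)
                if not has_explicit_h:
                    flags.add(HBOND_ACCEPTOR)
            else:
                flags.add(HBOND_ACCEPTOR)
        elif el == "C":
            if not any(n.element in ("N", "O", "P") for n in heavy):
                flags.add(HYDROPHOBE)
            if hydrogens or (not has_explicit_h and len(heavy) <= 3):
                flags.add(WEAK_DONOR)
            o_partners = [
                n
                for n in heavy
                if n.element == "O"
                and float(np.linalg.norm(atom.coords - n.coords)) <= _DOUBLE_BOND_CO_MAX
            ]
            if o_partners:
                terminal_o = [
                    o
                    for o in o_partners
                    if len([k for k in bonds.get(o.index, ()) if atoms_by_index[k].element != "H"]) == 1
                ]
                sibling_terminal_o = [
                    atoms_by_index[j]
                    for j in bonds.get(atom.index, ())
                    if atoms_by_index[j].element == "O"
                    and len([k for k in bonds.get(j, ()) if atoms_by_index[k].element != "H"]) == 1
                ]
                if terminal_o and len(sibling_terminal_o) == 1:
                    flags.add(CARBONYL_CARBON)
        elif el == "S":
            if not any(n.element in ("N", "O", "P") for n in heavy):
                flags.add(HYDROPHOBE)
            if hydrogens:
                flags.add(HBOND_DONOR)
            if len(heavy) == 2:
                flags.add(WEAK_ACCEPTOR)
        elif el in ("F", "CL", "BR", "I"):
            flags.add(HALOGEN)


def _smarts_type_component(component: list, bonds: dict, patterns: list) -> None:
    """SMARTS pattern typing via RDKit; silently skipped when the group cannot
    be turned into a sanitised molecule (the rule layer has already run)."""
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdDetermineBonds

        RDLogger.DisableLog("rdApp.*")
    except ImportError:  # pragma: no cover - rdkit is a hard dependency
        return
    index_of = {a.index: k for k, a in enumerate(component)}
    mol = Chem.RWMol()
    conf = Chem.Conformer(len(component))
    for k, a in enumerate(component):
        el = a.element.capitalize() if len(a.element) == 2 else a.element.upper()
        try:
            rd_atom = Chem.Atom(el)
        except Exception:
            return
        mol.AddAtom(rd_atom)
        conf.SetAtomPosition(k, tuple(float(x) for x in a.coords))
    added = set()
    for a in component:
        for j in bonds.get(a.index, ()):
            if j in index_of:
                key = frozenset((a.index, j))
                if key not in added:
                    added.add(key)
                    mol.AddBond(index_of[a.index], index_of[j], Chem.BondType.SINGLE)
    mol.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineBondOrders(mol, charge=0)
        Chem.SanitizeMol(mol)
    except Exception:
        return
    for pattern in patterns:
        query = pattern.get("_query")
        if query is None:
            query = Chem.MolFromSmarts(pattern["smarts"])
            pattern["_query"] = query
        if query is None:
            continue
        for match in mol.GetSubstructMatches(query):
            idx = pattern.get("atom_index", 0)
            if idx < len(match):
                component[match[idx]].type_flags.update(pattern["flags"])


def load_patterns(path=None) -> list:
    if path is None:
        text = (resources.files("contactsift") / "data" / "patterns.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    patterns = raw.get("patterns") or []
    for p in patterns:
        bad = set(p.get("flags") or []) - ATOM_FLAGS
        if bad:
            raise ValueError(f"pattern {p.get('name')} uses unknown flags {sorted(bad)}")
    return patterns


# ---------------------------------------------------------------------------
# Main typing operations
# ---------------------------------------------------------------------------


def assign_atom_types(
    structure: Structure,
    bonds: dict,
    config: GeometryConfig | None = None,
    dictionary: TypingDictionary | None = None,
    patterns: list | None = None,
) -> list:
    """Assign type flags to every atom in place; returns warning strings.

    Idempotent: flags are recomputed from scratch on every call.
    """
    config = config or GeometryConfig.default()
    dictionary = dictionary or TypingDictionary.default()
    if patterns is None:
        patterns = load_patterns()
    warnings_out: list = []
    atoms_by_index = {a.index: a for a in structure.atoms}

    for atom in structure.atoms:
        atom.type_flags = set()

    # 1. dictionary typing for standard polymer residues and waters
    for res in structure.residues:
        if res.polymer_class == "hetero":
            continue
        for atom in res.atoms:
            if atom.element == "H":
                continue
            flags = dictionary.lookup(res.res_name, atom.name)
            if flags is None:
                warnings_out.append(
                    f"atom {atom.spec()} of standard residue {res.res_name} has no "
                    "dictionary entry; typed by element rules only"
                )
            else:
                atom.type_flags |= set(flags)

    # 2. rule + SMARTS typing for hetero groups
    for component in _component_atoms(structure, bonds):
        _rule_type_component(component, atoms_by_index, bonds, config)
        _smarts_type_component(component, bonds, patterns)

    # 3. global rules
    for atom in structure.atoms:
        el = atom.element.upper()
        if not config.has_radii(atom.element) and atom.element:
            warnings_out.append(
                f"element {atom.element!r} of {atom.spec()} has no radii entry; "
                "excluded from feature typing"
            )
            atom.type_flags = set()
            continue
        if el in ("F", "CL", "BR", "I"):
            atom.type_flags.add(HALOGEN)
            bonded_c = [
                atoms_by_index[j]
                for j in bonds.get(atom.index, ())
                if atoms_by_index[j].element == "C"
            ]
            if bonded_c:
                atom.type_flags.add(HYDROPHOBE)
                if el in _XBOND_DONOR_HALOGENS:
                    atom.type_flags.add(XBOND_DONOR)
                if config.halogen_weak_acceptor:
                    atom.type_flags.add(WEAK_ACCEPTOR)
        if el == "O" and bonds.get(atom.index):
            # lenient rule: any covalently bound oxygen is an acceptor
            atom.type_flags.add(HBOND_ACCEPTOR)
        if config.is_metal(el) and atom.is_hetatm and len(atom.residue.atoms) == 1:
            atom.type_flags = {METAL, POS_IONISABLE}

    correct_terminal_residues(structure, bonds, dictionary)

    # xbond acceptors mirror hbond acceptors; metal exclusivity last
    for atom in structure.atoms:
        if HBOND_ACCEPTOR in atom.type_flags:
            atom.type_flags.add(XBOND_ACCEPTOR)
        if METAL in atom.type_flags:
            atom.type_flags = {METAL}
    return warnings_out


def correct_terminal_residues(
    structure: Structure,
    bonds: dict,
    dictionary: TypingDictionary | None = None,
) -> Structure:
    """Canonical terminus typing for main-chain atoms of terminal residues.

    A C-terminal carboxyl oxygen is acceptor + negatively ionisable even when
    OXT is absent (never a donor hydroxyl); an N-terminal nitrogen is a
    protonated amine (donor unless proline without explicit H).
    """
    atoms_by_index = {a.index: a for a in structure.atoms}
    for res in structure.residues:
        if res.polymer_class != "peptide":
            continue
        if res.is_terminal == "c_term":
            for name in ("O", "OXT"):
                atom = res.atom(name)
                if atom is not None:
                    atom.type_flags = {HBOND_ACCEPTOR, NEG_IONISABLE}
            c = res.atom("C")
            if c is not None:
                c.type_flags.discard(CARBONYL_CARBON)
        elif res.is_terminal == "n_term":
            n = res.atom("N")
            if n is not None:
                has_h = any(
                    atoms_by_index[j].element == "H" for j in bonds.get(n.index, ())
                )
                if res.res_name == "PRO":
                    n.type_flags = {POS_IONISABLE} | ({HBOND_DONOR} if has_h else set())
                else:
                    n.type_flags = {HBOND_DONOR, POS_IONISABLE}
    return structure


def apply_ambiguity_leniency(structure: Structure, bonds: dict, enabled: bool) -> Structure:
    """Histidine tautomer handling.

    Lenient: both ring nitrogens are donor and acceptor. Strict: a ring
    nitrogen with an explicit hydrogen is a donor, otherwise an acceptor only.
    """
    atoms_by_index = {a.index: a for a in structure.atoms}
    for res in structure.residues:
        if res.res_name != "HIS":
            continue
        for name in ("ND1", "NE2"):
            atom = res.atom(name)
            if atom is None:
                continue
            atom.type_flags.discard(HBOND_DONOR)
            atom.type_flags.discard(HBOND_ACCEPTOR)
            if enabled:
                atom.type_flags |= {HBOND_DONOR, HBOND_ACCEPTOR, POS_IONISABLE}
            else:
                has_h = any(
                    atoms_by_index[j].element == "H" for j in bonds.get(atom.index, ())
                )
                atom.type_flags.add(HBOND_DONOR if has_h else HBOND_ACCEPTOR)
            if HBOND_ACCEPTOR in atom.type_flags:
                atom.type_flags.add(XBOND_ACCEPTOR)
            else:
                atom.type_flags.discard(XBOND_ACCEPTOR)
    return structure


# ---------------------------------------------------------------------------
# Ring and amide perception
# ---------------------------------------------------------------------------


def perceive_rings(
    structure: Structure,
    bonds: dict,
    config: GeometryConfig | None = None,
    dictionary: TypingDictionary | None = None,
) -> tuple:
    """Aromatic ring systems; returns (rings, warnings).

    Standard residues use dictionary ring definitions; hetero groups use
    cycle perception on the bond graph gated by composition (C/N/O/S, heavy
    degree <= 3) and planarity (RMS deviation <= planarity_tol).
    """
    config = config or GeometryConfig.default()
    dictionary = dictionary or TypingDictionary.default()
    rings: list = []
    warnings_out: list = []

    for res in structure.residues:
        for member_names in dictionary.rings.get(res.res_name, []):
            members = [res.atom(n) for n in member_names]
            if any(m is None for m in members):
                warnings_out.append(
                    f"ring {member_names} of {res.spec()} has missing member atoms; skipped"
                )
                continue
            coords = np.vstack([m.coords for m in members])
            centroid, normal, rms = fit_plane(coords)
            rings.append(
                RingSystem(
                    ring_id=-1,
                    atoms=members,
                    centroid=centroid,
                    normal=normal,
                    planarity_rms=rms,
                )
            )

    # hetero-group cycles
    import networkx as nx

    hetero = [a for r in structure.residues if r.polymer_class == "hetero" for a in r.atoms]
    if hetero:
        hetero_idx = {a.index: a for a in hetero}
        graph = nx.Graph()
        graph.add_nodes_from(hetero_idx)
        for i in hetero_idx:
            for j in bonds.get(i, ()):
                if j in hetero_idx:
                    graph.add_edge(i, j)
        for cycle in nx.minimum_cycle_basis(graph):
            if len(cycle) < 5:
                continue
            members = [hetero_idx[i] for i in sorted(cycle)]
            if any(m.element.upper() not in ("C", "N", "O", "S") for m in members):
                continue
            heavy_degree = {
                m.index: sum(
                    1
                    for j in bonds.get(m.index, ())
                    if j in hetero_idx and hetero_idx[j].element != "H"
                )
                for m in members
            }
            if any(heavy_degree[m.index] > 3 for m in members):
                continue
            coords = np.vstack([m.coords for m in members])
            centroid, normal, rms = fit_plane(coords)
            if rms > config.planarity_tol:
                continue
            rings.append(
                RingSystem(
                    ring_id=-1,
                    atoms=members,
                    centroid=centroid,
                    normal=normal,
                    planarity_rms=rms,
                )
            )
            for m in members:
                m.type_flags.add(AROMATIC)

    rings.sort(key=lambda r: min(a.serial for a in r.atoms))
    for k, ring in enumerate(rings):
        ring.ring_id = k
    return rings, warnings_out


def perceive_amides(
    structure: Structure,
    bonds: dict,
    dictionary: TypingDictionary | None = None,
) -> list:
    """Amide groups: backbone peptide bonds, Asn/Gln side chains, ligand amides."""
    dictionary = dictionary or TypingDictionary.default()
    atoms_by_index = {a.index: a for a in structure.atoms}
    groups: list = []

    def add_group(c: Atom, o: Atom, n: Atom) -> None:
        h = None
        for j in bonds.get(n.index, ()):
            if atoms_by_index[j].element == "H":
                h = atoms_by_index[j]
                break
        coords = np.vstack([c.coords, o.coords, n.coords])
        centroid, normal, _ = fit_plane(coords)
        groups.append(
            AmideGroup(
                group_id=-1,
                c_atom=c,
                o_atom=o,
                n_atom=n,
                h_atom=h,
                centroid=centroid,
                normal=normal,
            )
        )

    for prev, nxt in polymer_links(structure):
        if prev.polymer_class != "peptide":
            continue
        c, o, n = prev.atom("C"), prev.atom("O"), nxt.atom("N")
        if c is not None and o is not None and n is not None:
            add_group(c, o, n)

    for res in structure.residues:
        for c_name, o_name, n_name in dictionary.amides.get(res.res_name, []):
            c, o, n = res.atom(c_name), res.atom(o_name), res.atom(n_name)
            if c is not None and o is not None and n is not None:
                add_group(c, o, n)

    # ligand amides: C bonded to a short C=O oxygen and to a nitrogen
    hetero = [a for r in structure.residues if r.polymer_class == "hetero" for a in r.atoms]
    for c in hetero:
        if c.element != "C":
            continue
        neighbours = [atoms_by_index[j] for j in bonds.get(c.index, ())]
        o_partner = next(
            (
                n
                for n in neighbours
                if n.element == "O"
                and float(np.linalg.norm(c.coords - n.coords)) <= _DOUBLE_BOND_CO_MAX
                and len([k for k in bonds.get(n.index, ()) if atoms_by_index[k].element != "H"]) == 1
            ),
            None,
        )
        n_partner = next((n for n in neighbours if n.element == "N"), None)
        if o_partner is not None and n_partner is not None:
            add_group(c, o_partner, n_partner)

    groups.sort(key=lambda g: g.c_atom.serial)
    for k, g in enumerate(groups):
        g.group_id = k
    return groups
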