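"""Contact enumeration, distance classification and feature-bit detection.

Every atom pair within the radial cutoff (5 A by default) receives a
structural interaction fingerprint (SIFt). The first five bits are a mutually
exclusive distance class derived from summed covalent and van der Waals
radii::

    clash      d <  Rcov - cov_tol
    covalent   Rcov - cov_tol <= d <= Rcov + cov_tol
    vdw_clash  Rcov + cov_tol <  d <  Rvdw
    vdw        Rvdw <= d <= Rvdw + vdw_comp
    proximal   otherwise (still within the cutoff)

The remaining bits are feature interactions gated by atom typing plus
distance (and, where defined, angle) criteria: hydrogen bonds, weak hydrogen
bonds, halogen bonds, ionic, metal-complex, aromatic, hydrophobic and
carbonyl interactions, plus angle-free "polar" and "weak polar" analogues of
the two hydrogen-bond types that are robust to missing hydrogens.

Feature bits are suppressed on clash/covalent contacts and on 1-2/1-3 bonded
pairs across residues; intra-residue pairs are never reported.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import chemo_typing as ct
from .config import GeometryConfig, UnknownElementError
from .structure_io import Atom, Structure

DISTANCE_CLASSES = ("clash", "covalent", "vdw_clash", "vdw", "proximal")
FEATURE_BITS = (
    "hbond",
    "weak_hbond",
    "xbond",
    "ionic",
    "metal",
    "aromatic",
    "hydrophobic",
    "carbonyl",
    "polar",
    "weak_polar",
)
SIFT_BITS = DISTANCE_CLASSES + FEATURE_BITS

# Entity labels relative to a resolved selection.
INTRA_SELECTION = "intra_selection"
INTER = "inter"
INTRA_NONSELECTION = "intra_nonselection"
WATER_BRIDGE = "water_bridge_candidate"


@dataclasses.dataclass
class Contact:
    """An unordered atom pair within the cutoff carrying its SIFt."""

    atom_a: Atom  # canonical order: serial ascending
    atom_b: Atom
    distance: float
    distance_class: str
    feature_bits: set
    entity_label: str = INTRA_NONSELECTION

    def bits(self) -> dict:
        row = {b: 0 for b in SIFT_BITS}
        row[self.distance_class] = 1
        for b in self.feature_bits:
            row[b] = 1
        return row


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosine = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosine))))


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.coords - b.coords))


# ---------------------------------------------------------------------------
# Pair enumeration and distance classification
# ---------------------------------------------------------------------------


def neighbor_pairs(structure: Structure, cutoff: float = 5.0) -> list:
    """All unordered atom pairs with d <= cutoff, each exactly once.

    Intra-residue pairs are included (bond inference needs them); contact
    assembly filters them out.
    """
    atoms = structure.atoms
    if len(atoms) < 2:
        return []
    tree = cKDTree(structure.coords())
    out = []
    for i, j in sorted(tree.query_pairs(r=cutoff)):
        a, b = atoms[i], atoms[j]
        if a.serial > b.serial:
            a, b = b, a
        out.append((a, b, _dist(a, b)))
    return out


def classify_distance(atom_a: Atom, atom_b: Atom, distance: float, config: GeometryConfig) -> str:
    """Exactly one of the five mutually exclusive distance classes."""
    for atom in (atom_a, atom_b):
        if not config.has_radii(atom.element):
            raise UnknownElementError(atom.element, "covalent/van der Waals")
    rcov = config.rcov(atom_a.element) + config.rcov(atom_b.element)
    rvdw = config.rvdw(atom_a.element) + config.rvdw(atom_b.element)
    if distance < rcov - config.cov_tol:
        return "clash"
    if distance <= rcov + config.cov_tol:
        return "covalent"
    if distance < rvdw:
        return "vdw_clash"
    if distance <= rvdw + config.vdw_comp:
        return "vdw"
    return "proximal"


# ---------------------------------------------------------------------------
# Feature detectors
# ---------------------------------------------------------------------------


def _attached_hydrogens(atom: Atom, bonds: dict, atoms_by_index: dict) -> list:
    return [
        atoms_by_index[j]
        for j in bonds.get(atom.index, ())
        if atoms_by_index[j].element == "H"
    ]


def detect_hbond(
    donor: Atom,
    donor_hydrogens: Iterable[Atom],
    acceptor: Atom,
    config: GeometryConfig,
) -> bool:
    """D-H...A hydrogen bond with explicit hydrogen geometry."""
    if ct.HBOND_DONOR not in donor.type_flags:
        return False
    if ct.HBOND_ACCEPTOR not in acceptor.type_flags:
        return False
    if _dist(donor, acceptor) > config.hbond_dist_max:
        return False
    for h in donor_hydrogens:
        if _dist(h, acceptor) <= config.hbond_h_dist_max and (
            _angle_deg(donor.coords, h.coords, acceptor.coords) >= config.hbond_angle_min
        ):
            return True
    return False


def detect_weak_hbond(
    donor: Atom,
    donor_hydrogens: Iterable[Atom],
    acceptor: Atom,
    config: GeometryConfig,
) -> bool:
    """C-H...A (weak donor) or D-H...halogen (weak acceptor) hydrogen bond."""
    forward = ct.WEAK_DONOR in donor.type_flags and ct.HBOND_ACCEPTOR in acceptor.type_flags
    halogen_route = (
        ct.HBOND_DONOR in donor.type_flags and ct.WEAK_ACCEPTOR in acceptor.type_flags
        and ct.HALOGEN in acceptor.type_flags
    )
    if not (forward or halogen_route):
        return False
    if _dist(donor, acceptor) > config.weak_hbond_dist_max:
        return False
    for h in donor_hydrogens:
        if _dist(h, acceptor) <= config.weak_hbond_h_dist_max and (
            _angle_deg(donor.coords, h.coords, acceptor.coords)
            >= config.weak_hbond_angle_min
        ):
            return True
    return False


def detect_polar(donor: Atom, acceptor: Atom, config: GeometryConfig) -> bool:
    """Angle-free hydrogen-bond analogue (no hydrogens used)."""
    return (
        ct.HBOND_DONOR in donor.type_flags
        and ct.HBOND_ACCEPTOR in acceptor.type_flags
        and _dist(donor, acceptor) <= config.polar_dist_max
    )


def detect_weak_polar(donor: Atom, acceptor: Atom, config: GeometryConfig) -> bool:
    forward = ct.WEAK_DONOR in donor.type_flags and ct.HBOND_ACCEPTOR in acceptor.type_flags
    halogen_route = (
        ct.HBOND_DONOR in donor.type_flags
        and ct.WEAK_ACCEPTOR in acceptor.type_flags
        and ct.HALOGEN in acceptor.type_flags
    )
    return (forward or halogen_route) and _dist(donor, acceptor) <= config.weak_polar_dist_max


def detect_xbond(
    halogen: Atom,
    acceptor: Atom,
    bonds: dict,
    atoms_by_index: dict,
    config: GeometryConfig,
) -> bool:
    """C-X...A halogen bond (sigma-hole directionality)."""
    if ct.XBOND_DONOR not in halogen.type_flags:
        return False
    if ct.XBOND_ACCEPTOR not in acceptor.type_flags:
        return False
    carbons = [
        atoms_by_index[j]
        for j in bonds.get(halogen.index, ())
        if atoms_by_index[j].element == "C"
    ]
    if not carbons:
        return False
    d_max = config.rvdw(halogen.element) + config.rvdw(acceptor.element) + config.vdw_comp
    if _dist(halogen, acceptor) > d_max:
        return False
    return any(
        _angle_deg(c.coords, halogen.coords, acceptor.coords) >= config.xbond_angle_min
        for c in carbons
    )


def detect_ionic(a: Atom, b: Atom, config: GeometryConfig) -> bool:
    opposite = (
        ct.POS_IONISABLE in a.type_flags and ct.NEG_IONISABLE in b.type_flags
    ) or (ct.NEG_IONISABLE in a.type_flags and ct.POS_IONISABLE in b.type_flags)
    return opposite and _dist(a, b) <= config.ionic_dist_max


def detect_metal(a: Atom, b: Atom, config: GeometryConfig) -> bool:
    if ct.METAL in a.type_flags:
        metal, other = a, b
    elif ct.METAL in b.type_flags:
        metal, other = b, a
    else:
        return False
    coordinating = ct.HBOND_ACCEPTOR in other.type_flags or ct.NEG_IONISABLE in other.type_flags
    return coordinating and _dist(metal, other) <= config.metal_dist_max


def detect_carbonyl(a: Atom, b: Atom, config: GeometryConfig) -> bool:
    """Carbonyl C...O dipole pairing (n->pi*) between different groups."""
    paired = (
        ct.CARBONYL_CARBON in a.type_flags and ct.CARBONYL_OXYGEN in b.type_flags
    ) or (ct.CARBONYL_OXYGEN in a.type_flags and ct.CARBONYL_CARBON in b.type_flags)
    return paired and _dist(a, b) <= config.carbonyl_dist_max


def detect_hydrophobic(a: Atom, b: Atom, config: GeometryConfig) -> bool:
    return (
        ct.HYDROPHOBE in a.type_flags
        and ct.HYDROPHOBE in b.type_flags
        and _dist(a, b) <= config.hydrophobic_dist_max
    )


def detect_aromatic_atoms(a: Atom, b: Atom, config: GeometryConfig) -> bool:
    return (
        ct.AROMATIC in a.type_flags
        and ct.AROMATIC in b.type_flags
        and _dist(a, b) <= config.aromatic_dist_max
    )


# ---------------------------------------------------------------------------
# Contact assembly
# ---------------------------------------------------------------------------


def _entity_label(a: Atom, b: Atom, selection: Optional[set]) -> str:
    if selection is None:
        return INTRA_NONSELECTION
    in_a, in_b = a.index in selection, b.index in selection
    if in_a and in_b:
        return INTRA_SELECTION
    if in_a or in_b:
        outside = b if in_a else a
        if outside.residue is not None and outside.residue.polymer_class == "water":
            return WATER_BRIDGE
        return INTER
    return INTRA_NONSELECTION


def build_contact(
    atom_a: Atom,
    atom_b: Atom,
    distance: float,
    bonds: dict,
    atoms_by_index: dict,
    config: GeometryConfig,
    selection: Optional[set] = None,
) -> Contact:
    """Assemble the full SIFt for one pair (symmetric in its arguments)."""
    if atom_a.serial > atom_b.serial:
        atom_a, atom_b = atom_b, atom_a
    distance_class = classify_distance(atom_a, atom_b, distance, config)
    features: set = set()

    bonded = atom_b.index in bonds.get(atom_a.index, set())
    one_three = bool(bonds.get(atom_a.index, set()) & bonds.get(atom_b.index, set()))
    if distance_class not in ("clash", "covalent") and not bonded and not one_three:
        ha = _attached_hydrogens(atom_a, bonds, atoms_by_index)
        hb = _attached_hydrogens(atom_b, bonds, atoms_by_index)
        if detect_hbond(atom_a, ha, atom_b, config) or detect_hbond(atom_b, hb, atom_a, config):
            features.add("hbond")
        if detect_weak_hbond(atom_a, ha, atom_b, config) or detect_weak_hbond(
            atom_b, hb, atom_a, config
        ):
            features.add("weak_hbond")
        if detect_xbond(atom_a, atom_b, bonds, atoms_by_index, config) or detect_xbond(
            atom_b, atom_a, bonds, atoms_by_index, config
        ):
            features.add("xbond")
        if detect_polar(atom_a, atom_b, config) or detect_polar(atom_b, atom_a, config):
            features.add("polar")
        if detect_weak_polar(atom_a, atom_b, config) or detect_weak_polar(
            atom_b, atom_a, config
        ):
            features.add("weak_polar")
        if detect_ionic(atom_a, atom_b, config):
            features.add("ionic")
        if detect_metal(atom_a, atom_b, config):
            features.add("metal")
        if detect_carbonyl(atom_a, atom_b, config):
            features.add("carbonyl")
        if detect_hydrophobic(atom_a, atom_b, config):
            features.add("hydrophobic")
        if detect_aromatic_atoms(atom_a, atom_b, config):
            features.add("aromatic")

    return Contact(
        atom_a=atom_a,
        atom_b=atom_b,
        distance=distance,
        distance_class=distance_class,
        feature_bits=features,
        entity_label=_entity_label(atom_a, atom_b, selection),
    )


def compute_contacts(
    structure: Structure,
    bonds: dict,
    config: GeometryConfig,
    selection: Optional[set] = None,
) -> list:
    """All inter-residue contacts within the cutoff, sorted by serial pair."""
    atoms_by_index = {a.index: a for a in structure.atoms}
    contacts = []
    for a, b, d in neighbor_pairs(structure, config.cutoff):
        if a.residue_key == b.residue_key:
            continue
        contacts.append(
            build_contact(a, b, d, bonds, atoms_by_index, config, selection)
        )
    contacts.sort(key=lambda c: (c.atom_a.serial, c.atom_b.serial))
    return contacts
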