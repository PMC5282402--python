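"""Group-level interactions of planar systems.

Ring-ring (pi-pi) interactions are gated by centroid separation and labelled
by the interplanar angle theta (folded to [0, 90] degrees): ``stacked``
(theta <= 30), ``tilted`` (30 < theta < 60), ``t_shaped`` (theta >= 60).

Atom-ring interactions (cation-pi, donor-pi, halogen-pi, carbon-pi) require
the atom over the ring face: centroid distance within the maximum and the
angle between the ring normal and the centroid->atom vector within the face
cone. Subtypes follow the atom's type flags and are not mutually exclusive.
Atoms that are themselves members of a perceived ring or amide group are
excluded: their interactions are reported at group level instead.

Amide groups interact with other amides and with aromatic rings (centroid
gates); methionine thioether sulphur interacts with aromatic rings within a
S...centroid maximum, reported with its elevation above the ring plane.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from . import chemo_typing as ct
from .chemo_typing import AmideGroup, RingSystem
from .config import GeometryConfig
from .structure_io import Atom, Structure

ATOM_RING_SUBTYPES = ("cation_pi", "donor_pi", "halogen_pi", "carbon_pi")


def fold_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two directions folded to [0, 90] (sign-insensitive)."""
    cosine = abs(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, cosine)))


@dataclasses.dataclass
class PiPiInteraction:
    ring_a: RingSystem
    ring_b: RingSystem
    distance: float  # centroid-centroid, Angstrom
    interplanar_angle: float  # degrees, [0, 90]
    geometry: str  # stacked | tilted | t_shaped


@dataclasses.dataclass
class AtomRingInteraction:
    atom: Atom
    ring: RingSystem
    distance: float  # atom-centroid
    theta: float  # off-normal angle, degrees
    subtypes: tuple


@dataclasses.dataclass
class AmideInteraction:
    kind: str  # amide_amide | amide_ring
    group: AmideGroup
    other: object  # AmideGroup or RingSystem
    distance: float
    interplanar_angle: float


@dataclasses.dataclass
class MetAromaticInteraction:
    s_atom: Atom
    ring: RingSystem
    distance: float
    elevation: float  # degrees above the ring plane


# ---------------------------------------------------------------------------
# Ring-ring
# ---------------------------------------------------------------------------


def ring_ring(
    r1: RingSystem, r2: RingSystem, config: GeometryConfig
) -> Optional[PiPiInteraction]:
    if r1.member_indices & r2.member_indices:
        return None
    d = float(np.linalg.norm(r2.centroid - r1.centroid))
    if d > config.ring_ring_dist_max:
        return None
    theta = fold_angle_deg(r1.normal, r2.normal)
    if theta <= config.stacked_angle_max:
        geometry = "stacked"
    elif theta < config.t_shaped_angle_min:
        geometry = "tilted"
    else:
        geometry = "t_shaped"
    return PiPiInteraction(
        ring_a=r1, ring_b=r2, distance=d, interplanar_angle=theta, geometry=geometry
    )


def all_ring_ring(rings: list, config: GeometryConfig) -> list:
    out = []
    for i, r1 in enumerate(rings):
        for r2 in rings[i + 1 :]:
            inter = ring_ring(r1, r2, config)
            if inter is not None:
                out.append(inter)
    return out


# ---------------------------------------------------------------------------
# Atom-ring
# ---------------------------------------------------------------------------


def atom_ring(
    atom: Atom, ring: RingSystem, config: GeometryConfig
) -> Optional[AtomRingInteraction]:
    if atom.index in ring.member_indices:
        return None
    if atom.residue is ring.residue:
        return None
    vec = atom.coords - ring.centroid
    d = float(np.linalg.norm(vec))
    if d > config.atom_ring_dist_max or d == 0.0:
        return None
    theta = fold_angle_deg(ring.normal, vec)
    if theta > config.atom_ring_angle_max:
        return None
    subtypes = []
    if ct.POS_IONISABLE in atom.type_flags:
        subtypes.append("cation_pi")
    if ct.HBOND_DONOR in atom.type_flags:
        subtypes.append("donor_pi")
    if ct.XBOND_DONOR in atom.type_flags:
        subtypes.append("halogen_pi")
    if ct.WEAK_DONOR in atom.type_flags and atom.element == "C":
        subtypes.append("carbon_pi")
    if not subtypes:
        return None
    return AtomRingInteraction(
        atom=atom, ring=ring, distance=d, theta=theta, subtypes=tuple(subtypes)
    )


def all_atom_ring(
    structure: Structure,
    rings: list,
    amides: list,
    config: GeometryConfig,
) -> list:
    in_group: set = set()
    for ring in rings:
        in_group |= ring.member_indices
    for g in amides:
        in_group |= g.member_indices
    candidates = [
        a
        for a in structure.atoms
        if a.index not in in_group
        and a.type_flags
        & {ct.POS_IONISABLE, ct.HBOND_DONOR, ct.XBOND_DONOR, ct.WEAK_DONOR}
    ]
    out = []
    for ring in rings:
        for atom in candidates:
            inter = atom_ring(atom, ring, config)
            if inter is not None:
                out.append(inter)
    out.sort(key=lambda i: (i.atom.serial, i.ring.ring_id))
    return out


# ---------------------------------------------------------------------------
# Amide groups
# ---------------------------------------------------------------------------


def amide_group_interactions(
    amides: list, rings: list, config: GeometryConfig
) -> list:
    out = []
    for i, g in enumerate(amides):
        for other in amides[i + 1 :]:
            if g.member_indices & other.member_indices:
                continue
            d = float(np.linalg.norm(other.centroid - g.centroid))
            if d <= config.amide_amide_dist_max:
                out.append(
                    AmideInteraction(
                        kind="amide_amide",
                        group=g,
                        other=other,
                        distance=d,
                        interplanar_angle=fold_angle_deg(g.normal, other.normal),
                    )
                )
        for ring in rings:
            if g.member_indices & ring.member_indices:
                continue
            if ring.residue in g.residues:
                continue  # a residue's own backbone amide vs its side-chain ring
            d = float(np.linalg.norm(ring.centroid - g.centroid))
            if d <= config.amide_ring_dist_max:
                out.append(
                    AmideInteraction(
                        kind="amide_ring",
                        group=g,
                        other=ring,
                        distance=d,
                        interplanar_angle=fold_angle_deg(g.normal, ring.normal),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Methionine sulphur - aromatic
# ---------------------------------------------------------------------------


def _thioether_sulphurs(structure: Structure, bonds: dict, config: GeometryConfig) -> list:
    atoms_by_index = {a.index: a for a in structure.atoms}
    out = []
    for a in structure.atoms:
        if a.element != "S":
            continue
        if a.res_name == "MET" and a.name == "SD":
            out.append(a)
        elif config.include_all_thioethers:
            carbon_neighbours = [
                atoms_by_index[j]
                for j in bonds.get(a.index, ())
                if atoms_by_index[j].element == "C"
            ]
            if len(carbon_neighbours) >= 1:
                out.append(a)
    return out


def met_sulphur_aromatic(
    s_atom: Atom, ring: RingSystem, config: GeometryConfig
) -> Optional[MetAromaticInteraction]:
    if s_atom.residue is ring.residue:
        return None
    vec = s_atom.coords - ring.centroid
    d = float(np.linalg.norm(vec))
    if d > config.met_arom_dist_max or d == 0.0:
        return None
    elevation = 90.0 - fold_angle_deg(ring.normal, vec)
    return MetAromaticInteraction(s_atom=s_atom, ring=ring, distance=d, elevation=elevation)


def all_met_aromatic(
    structure: Structure, rings: list, bonds: dict, config: GeometryConfig
) -> list:
    out = []
    for s_atom in _thioether_sulphurs(structure, bonds, config):
        for ring in rings:
            inter = met_sulphur_aromatic(s_atom, ring, config)
            if inter is not None:
                out.append(inter)
    out.sort(key=lambda i: (i.s_atom.serial, i.ring.ring_id))
    return out
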