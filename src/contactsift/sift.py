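"""Per-residue aggregation of contacts and group interactions.

Each residue with at least one in-scope interaction receives a binary
presence vector and an integer count vector over the full interaction-type
vocabulary. The integer counts follow atom semantics for atom-atom contacts:
the number of the residue's atoms making at least one contact of that type
(one atom with two hydrogen bonds counts once). Ring and group interactions
count once per interaction, attributed to the parent residue(s) of each side.

A contact between two residues contributes to both residues' fingerprints:
the fingerprint describes each residue's interaction environment.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

from .contacts import Contact, DISTANCE_CLASSES, FEATURE_BITS, INTER, WATER_BRIDGE

GROUP_TYPES = (
    "pi_pi",
    "cation_pi",
    "donor_pi",
    "halogen_pi",
    "carbon_pi",
    "amide_amide",
    "amide_ring",
    "met_aromatic",
)
SIFT_TYPES = DISTANCE_CLASSES + FEATURE_BITS + GROUP_TYPES


@dataclasses.dataclass
class ResidueSIFt:
    """Binary and integer interaction fingerprint of one residue."""

    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    counts: dict  # type -> int

    @property
    def binary(self) -> dict:
        return {t: int(self.counts.get(t, 0) > 0) for t in SIFT_TYPES}

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.i_code)


def _contact_in_scope(contact: Contact, selection_active: bool) -> bool:
    if not selection_active:
        return True
    return contact.entity_label in (INTER, WATER_BRIDGE)


def _sides_in_scope(atoms_a, atoms_b, selection: Optional[set]) -> bool:
    if selection is None:
        return True
    hit_a = any(a.index in selection for a in atoms_a)
    hit_b = any(b.index in selection for b in atoms_b)
    return hit_a != hit_b


def aggregate_residue_sifts(
    contacts: Iterable[Contact],
    pi_pi_interactions: Iterable = (),
    atom_ring_interactions: Iterable = (),
    amide_interactions: Iterable = (),
    met_interactions: Iterable = (),
    selection: Optional[set] = None,
) -> list:
    """One ResidueSIFt per residue with at least one in-scope interaction.

    With an active selection, scope is restricted to inter-entity contacts
    (labels ``inter`` and ``water_bridge_candidate``) and to group
    interactions spanning the selection boundary.
    """
    selection_active = selection is not None
    atom_sets: dict = {}  # residue -> type -> set of atom serials
    group_counts: dict = {}  # residue -> type -> int
    residues: dict = {}

    def atom_hit(residue, type_name: str, serial: int) -> None:
        residues[residue.key] = residue
        atom_sets.setdefault(residue.key, {}).setdefault(type_name, set()).add(serial)

    def group_hit(residue, type_name: str) -> None:
        residues[residue.key] = residue
        by_type = group_counts.setdefault(residue.key, {})
        by_type[type_name] = by_type.get(type_name, 0) + 1

    for contact in contacts:
        if not _contact_in_scope(contact, selection_active):
            continue
        types = [contact.distance_class, *contact.feature_bits]
        for atom in (contact.atom_a, contact.atom_b):
            if atom.residue is None:
                continue
            for t in types:
                atom_hit(atom.residue, t, atom.serial)

    for inter in pi_pi_interactions:
        if not _sides_in_scope(inter.ring_a.atoms, inter.ring_b.atoms, selection):
            continue
        group_hit(inter.ring_a.residue, "pi_pi")
        group_hit(inter.ring_b.residue, "pi_pi")

    for inter in atom_ring_interactions:
        if not _sides_in_scope([inter.atom], inter.ring.atoms, selection):
            continue
        for subtype in inter.subtypes:
            if inter.atom.residue is not None:
                group_hit(inter.atom.residue, subtype)
            group_hit(inter.ring.residue, subtype)

    for inter in amide_interactions:
        other_atoms = inter.other.atoms
        if not _sides_in_scope(inter.group.atoms, other_atoms, selection):
            continue
        for res in inter.group.residues:
            group_hit(res, inter.kind)
        if inter.kind == "amide_amide":
            for res in inter.other.residues:
                group_hit(res, inter.kind)
        else:
            group_hit(inter.other.residue, inter.kind)

    for inter in met_interactions:
        if not _sides_in_scope([inter.s_atom], inter.ring.atoms, selection):
            continue
        if inter.s_atom.residue is not None:
            group_hit(inter.s_atom.residue, "met_aromatic")
        group_hit(inter.ring.residue, "met_aromatic")

    out = []
    for key in sorted(residues):
        residue = residues[key]
        counts = {t: 0 for t in SIFT_TYPES}
        for t, serials in atom_sets.get(key, {}).items():
            counts[t] = len(serials)
        for t, n in group_counts.get(key, {}).items():
            counts[t] += n
        out.append(
            ResidueSIFt(
                chain_id=residue.chain_id,
                res_seq=residue.res_seq,
                i_code=residue.i_code,
                res_name=residue.res_name,
                counts=counts,
            )
        )
    return out


def summarise_selection(
    contacts: Iterable[Contact],
    pi_pi_interactions: Iterable = (),
    atom_ring_interactions: Iterable = (),
    amide_interactions: Iterable = (),
    met_interactions: Iterable = (),
    selection: Optional[set] = None,
) -> dict:
    """Total in-scope interaction counts per type (the CLI summary table)."""
    selection_active = selection is not None
    totals = {t: 0 for t in SIFT_TYPES}
    for contact in contacts:
        if not _contact_in_scope(contact, selection_active):
            continue
        totals[contact.distance_class] += 1
        for t in contact.feature_bits:
            totals[t] += 1
    for inter in pi_pi_interactions:
        if _sides_in_scope(inter.ring_a.atoms, inter.ring_b.atoms, selection):
            totals["pi_pi"] += 1
    for inter in atom_ring_interactions:
        if _sides_in_scope([inter.atom], inter.ring.atoms, selection):
            for subtype in inter.subtypes:
                totals[subtype] += 1
    for inter in amide_interactions:
        if _sides_in_scope(inter.group.atoms, inter.other.atoms, selection):
            totals[inter.kind] += 1
    for inter in met_interactions:
        if _sides_in_scope([inter.s_atom], inter.ring.atoms, selection):
            totals["met_aromatic"] += 1
    return totals
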