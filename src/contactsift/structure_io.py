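"""PDB parsing, selection expressions, molecular entities and bond inference.

The reader is built on Biopython's ``Bio.PDB`` parser and flattens the chosen
model into a light-weight structure of :class:`Atom`/:class:`Residue` records:

* alternate locations are resolved to the highest-occupancy conformer (ties
  broken by alphabetical altLoc identifier) and dropped conformers are logged;
* elements are taken from columns 77-78 and inferred from the atom name when
  blank; deuterium is treated as hydrogen;
* polymer connectivity (peptide C-N <= 1.7 A, nucleotide O3'-P <= 1.8 A)
  identifies chain breaks and terminal residues;
* residue numbering is reported exactly as authored in the input file.

Selections use a simple ``/chain/resseq[icode]/atomname`` syntax where an
empty component is a wildcard; whitespace-separated items are unioned.
"""

from __future__ import annotations

import dataclasses
import io
import re
import warnings
from typing import Iterable, Optional

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial import cKDTree

from .config import GeometryConfig

PEPTIDE_LINK_MAX = 1.7  # C(i)-N(i+1), Angstrom
NUCLEOTIDE_LINK_MAX = 1.8  # O3'(i)-P(i+1), Angstrom

STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE""".split()
)
STANDARD_NUCLEOTIDES = frozenset("A C G U I DA DC DG DT DI".split())
DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_TWO_LETTER_ELEMENTS = frozenset(
    """BR CL NA MG ZN FE MN CU NI CO CA CD HG SE AS LI RB CS SR BA AL SI""".split()
)


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be turned into a structure."""


class SelectionSyntaxError(ValueError):
    """Raised for a malformed selection item."""


@dataclasses.dataclass
class Atom:
    """One PDB atom record after alternate-location resolution."""

    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    element: str
    coords: np.ndarray
    is_hetatm: bool
    occupancy: float = 1.0
    index: int = -1  # position in Structure.atoms
    type_flags: set = dataclasses.field(default_factory=set)
    residue: Optional["Residue"] = dataclasses.field(default=None, repr=False)

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.i_code)

    def spec(self) -> str:
        """Identifier matching the selection syntax, e.g. ``A/123/CA``."""
        return f"{self.chain_id}/{self.res_seq}{self.i_code.strip()}/{self.name}"

    def __hash__(self) -> int:
        return id(self)


@dataclasses.dataclass
class Residue:
    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    atoms: list = dataclasses.field(default_factory=list)
    polymer_class: str = "hetero"  # peptide | nucleotide | hetero | water
    is_terminal: str = "none"  # none | n_term | c_term | five_prime | three_prime

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.i_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def spec(self) -> str:
        return f"{self.chain_id}/{self.res_seq}{self.i_code.strip()}/{self.res_name}"

    def __hash__(self) -> int:
        return id(self)


@dataclasses.dataclass
class Entity:
    """A polymer chain or a connected hetero (ligand) group."""

    entity_id: str
    kind: str  # polymer_chain | hetero_group
    atoms: list

    def __len__(self) -> int:
        return len(self.atoms)


@dataclasses.dataclass
class Structure:
    residues: list
    conect: set = dataclasses.field(default_factory=set)  # frozenset serial pairs
    dropped: list = dataclasses.field(default_factory=list)
    model_index: int = 0

    @property
    def atoms(self) -> list:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        atoms = self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.vstack([a.coords for a in atoms])

    def atom_by_serial(self, serial: int) -> Optional[Atom]:
        for a in self.atoms:
            if a.serial == serial:
                return a
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Deep-copied structure with coordinates ``R @ x + t`` (rigid motion)."""
        import copy

        new = copy.deepcopy(self)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for a in new.atoms:
            a.coords = R @ a.coords + t
        return new


# ---------------------------------------------------------------------------
# Element inference
# ---------------------------------------------------------------------------


def infer_element(atom_name: str, res_name: str = "") -> str:
    """Element from a PDB atom name when the element column is blank.

    Digits are stripped; a name starting in column 13 (no leading space in the
    4-char field) with a recognised two-letter symbol is taken as such,
    otherwise the first alphabetic character wins.
    """
    raw = atom_name
    stripped = re.sub(r"[0-9']", "", raw).strip()
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if len(raw) >= 2 and raw[0] != " " and two in _TWO_LETTER_ELEMENTS:
        return two
    first = stripped[0].upper()
    if first == "D":
        return "H"
    return first


def _normalise_element(element: str, atom_name: str) -> str:
    e = (element or "").strip().upper()
    if not e or e == "X":  # Biopython uses 'X' when its own guess fails
        e = infer_element(atom_name)
    if e == "D":
        e = "H"
    return e


# ---------------------------------------------------------------------------
# read_structure
# ---------------------------------------------------------------------------


def _pick_altloc(bio_atom):
    """Highest occupancy wins; ties broken by alphabetical altLoc id."""
    if not bio_atom.is_disordered():
        return bio_atom, []
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0], children[1:]


def read_structure(
    pdb_text: str,
    model_index: int = 0,
    water_names: Iterable[str] = DEFAULT_WATER_NAMES,
) -> Structure:
    """Parse PDB text into the internal model (one model only)."""
    water_names = frozenset(water_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        bio = parser.get_structure("input", io.StringIO(pdb_text))
    models = list(bio.get_models())
    if not models or not any(True for _ in bio.get_atoms()):
        raise StructureParseError("no ATOM or HETATM records found")
    if not 0 <= model_index < len(models):
        raise StructureParseError(
            f"model_index {model_index} out of range; available models: "
            f"{list(range(len(models)))}"
        )
    model = models[model_index]

    structure = Structure(residues=[], model_index=model_index)
    for chain in model:
        for bio_res in chain:
            hetfield, res_seq, i_code = bio_res.id
            res_name = bio_res.get_resname().strip()
            residue = Residue(
                chain_id=chain.id,
                res_seq=res_seq,
                i_code=i_code.strip(),
                res_name=res_name,
            )
            if res_name in water_names:
                residue.polymer_class = "water"
            elif res_name in STANDARD_AMINO_ACIDS:
                residue.polymer_class = "peptide"
            elif res_name in STANDARD_NUCLEOTIDES:
                residue.polymer_class = "nucleotide"
            else:
                residue.polymer_class = "hetero"
            for bio_atom in bio_res:
                chosen, dropped = _pick_altloc(bio_atom)
                for d in dropped:
                    structure.dropped.append(
                        f"altloc {d.get_altloc()!r} of {chain.id}/{res_seq}/"
                        f"{d.get_name()} dropped (occupancy "
                        f"{d.get_occupancy()}): lower than kept conformer"
                    )
                coords = np.asarray(chosen.get_coord(), dtype=float)
                if not np.all(np.isfinite(coords)):
                    raise StructureParseError(
                        f"non-finite coordinates for atom {chosen.get_name()}"
                    )
                atom = Atom(
                    serial=chosen.get_serial_number(),
                    name=chosen.get_name().strip(),
                    alt_loc=chosen.get_altloc().strip(),
                    res_name=res_name,
                    chain_id=chain.id,
                    res_seq=res_seq,
                    i_code=i_code.strip(),
                    element=_normalise_element(chosen.element, chosen.get_fullname()),
                    coords=coords,
                    is_hetatm=bool(hetfield.strip()),
                    occupancy=chosen.get_occupancy() or 1.0,
                    residue=residue,
                )
                residue.atoms.append(atom)
            if residue.atoms:
                structure.residues.append(residue)

    for i, atom in enumerate(structure.atoms):
        atom.index = i

    structure.conect = _parse_conect(pdb_text)
    _mark_termini(structure)
    return structure


def _parse_conect(pdb_text: str) -> set:
    pairs = set()
    for line in pdb_text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[i : i + 5].strip() for i in range(6, min(len(line), 31), 5)]
        serials = [int(f) for f in fields if f]
        if len(serials) >= 2:
            centre = serials[0]
            for other in serials[1:]:
                pairs.add(frozenset((centre, other)))
    return pairs


def polymer_links(structure: Structure) -> list:
    """(residue_i, residue_j) pairs joined by a polymer backbone bond."""
    links = []
    by_chain: dict = {}
    for res in structure.residues:
        if res.polymer_class in ("peptide", "nucleotide"):
            by_chain.setdefault(res.chain_id, []).append(res)
    for residues in by_chain.values():
        for prev, nxt in zip(residues, residues[1:]):
            if prev.polymer_class == "peptide" == nxt.polymer_class:
                c, n = prev.atom("C"), nxt.atom("N")
                if c is not None and n is not None:
                    if np.linalg.norm(c.coords - n.coords) <= PEPTIDE_LINK_MAX:
                        links.append((prev, nxt))
            elif prev.polymer_class == "nucleotide" == nxt.polymer_class:
                o3, p = prev.atom("O3'"), nxt.atom("P")
                if o3 is not None and p is not None:
                    if np.linalg.norm(o3.coords - p.coords) <= NUCLEOTIDE_LINK_MAX:
                        links.append((prev, nxt))
    return links


def _mark_termini(structure: Structure) -> None:
    links = polymer_links(structure)
    has_pred = {nxt.key for _, nxt in links}
    has_succ = {prev.key for prev, _ in links}
    for res in structure.residues:
        if res.polymer_class == "peptide":
            if res.key not in has_pred and res.key in has_succ:
                res.is_terminal = "n_term"
            elif res.key not in has_succ and res.key in has_pred:
                res.is_terminal = "c_term"
        elif res.polymer_class == "nucleotide":
            if res.key not in has_pred and res.key in has_succ:
                res.is_terminal = "five_prime"
            elif res.key not in has_succ and res.key in has_pred:
                res.is_terminal = "three_prime"


# ---------------------------------------------------------------------------
# Bond inference
# ---------------------------------------------------------------------------


def infer_bonds(structure: Structure, config: GeometryConfig) -> dict:
    """Adjacency (atom index -> set of atom indices) of inferred covalent bonds.

    Bonded iff 0.4 A < d <= rcov(a) + rcov(b) + bond_tol, plus any CONECT
    pairs. Metals form no inferred bonds (coordination is handled by the
    metal-complex detector, not as covalent structure); CONECT can still
    connect them explicitly.
    """
    atoms = structure.atoms
    adjacency: dict = {a.index: set() for a in atoms}
    if len(atoms) >= 2:
        coords = structure.coords()
        max_rcov = max(
            (config.cov_radii.get(a.element.upper(), 0.0) for a in atoms),
            default=0.0,
        )
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(r=2 * max_rcov + config.bond_tol):
            a, b = atoms[i], atoms[j]
            if config.is_metal(a.element) or config.is_metal(b.element):
                continue
            if not (config.has_radii(a.element) and config.has_radii(b.element)):
                continue
            d = np.linalg.norm(a.coords - b.coords)
            if 0.4 < d <= config.rcov(a.element) + config.rcov(b.element) + config.bond_tol:
                adjacency[i].add(j)
                adjacency[j].add(i)
    if structure.conect:
        by_serial = {a.serial: a for a in atoms}
        for pair in structure.conect:
            serials = list(pair)
            if len(serials) == 2:
                a = by_serial.get(serials[0])
                b = by_serial.get(serials[1])
                if a is not None and b is not None:
                    adjacency[a.index].add(b.index)
                    adjacency[b.index].add(a.index)
    return adjacency


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SelectionItem:
    chain: str  # '' = wildcard
    residue: str  # resseq + optional icode, '' = wildcard
    atom: str  # atom name, '' = wildcard

    def matches(self, atom: Atom) -> bool:
        if self.chain and atom.chain_id != self.chain:
            return False
        if self.residue and f"{atom.res_seq}{atom.i_code.strip()}" != self.residue:
            return False
        if self.atom and atom.name.upper() != self.atom.upper():
            return False
        return True


@dataclasses.dataclass
class Selection:
    items: list

    def resolve(self, structure: Structure) -> set:
        """Atoms (by index) matching the union of all items."""
        return {
            a.index
            for a in structure.atoms
            if any(item.matches(a) for item in self.items)
        }


def parse_selection(expr: str) -> Selection:
    """Parse ``/chain/resseq[icode]/atomname`` items (whitespace-separated)."""
    items = []
    for raw in expr.split():
        parts = raw.split("/")
        if len(parts) != 4 or parts[0] != "":
            raise SelectionSyntaxError(
                f"malformed selection item {raw!r}: expected /chain/resseq[icode]/atomname"
            )
        items.append(
            SelectionItem(chain=parts[1], residue=parts[2].strip(), atom=parts[3].strip())
        )
    if not items:
        raise SelectionSyntaxError("empty selection expression")
    return Selection(items=items)


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------


def detect_entities(structure: Structure, config: GeometryConfig | None = None) -> list:
    """One entity per polymer chain plus one per connected hetero group.

    Waters are excluded. Hetero connectivity is the covalent-distance graph
    (plus CONECT) restricted to hetero-residue atoms, so covalently linked
    HETATM residues form a single entity.
    """
    config = config or GeometryConfig.default()
    entities = []

    by_chain: dict = {}
    for res in structure.residues:
        if res.polymer_class in ("peptide", "nucleotide"):
            by_chain.setdefault(res.chain_id, []).extend(res.atoms)
    for chain_id in sorted(by_chain):
        entities.append(
            Entity(entity_id=f"chain:{chain_id}", kind="polymer_chain", atoms=by_chain[chain_id])
        )

    hetero_atoms = [
        a
        for r in structure.residues
        if r.polymer_class == "hetero"
        for a in r.atoms
    ]
    if hetero_atoms:
        adjacency = infer_bonds(structure, config)
        hetero_idx = {a.index for a in hetero_atoms}
        seen: set = set()
        by_index = {a.index: a for a in hetero_atoms}
        for start in sorted(hetero_idx):
            if start in seen:
                continue
            component = []
            stack = [start]
            seen.add(start)
            while stack:
                i = stack.pop()
                component.append(by_index[i])
                for j in adjacency[i]:
                    if j in hetero_idx and j not in seen:
                        seen.add(j)
                        stack.append(j)
            component.sort(key=lambda a: a.serial)
            first = component[0]
            entities.append(
                Entity(
                    entity_id=f"group:{first.chain_id}/{first.res_seq}{first.i_code}/{first.res_name}",
                    kind="hetero_group",
                    atoms=component,
                )
            )
    return entities
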