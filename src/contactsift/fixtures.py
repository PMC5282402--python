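"""Analytic PDB fixtures: minimal structures with ideal geometry per subtype.

Each fixture places the defining geometric parameter of one interaction
subtype at an exact value derived from the loaded :class:`GeometryConfig`:

* ``ideal`` — well inside every threshold;
* ``boundary_pass`` — defining threshold minus 0.05 A;
* ``boundary_fail`` — defining threshold plus 0.05 A (not detected).

Because boundary values are derived from the configuration at generation
time, editing a threshold keeps the fixture suite self-consistent. All
coordinates are computed analytically (no random placement) and atom naming
is chosen so typing is dictionary-driven wherever possible. Fragments are
kept minimal so that, apart from documented companions (``polar`` alongside a
hydrogen bond, ``weak_polar`` alongside a weak hydrogen bond, ``pi_pi``
alongside aromatic atom-atom contacts), no unintended feature subtype fires.

The module also generates seeded random structures used by the
spatial-index/brute-force and one-hot distance-class checks.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from .config import GeometryConfig

FEATURE_SUBTYPES = (
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
    "pi_pi",
    "cation_pi",
    "donor_pi",
    "halogen_pi",
    "carbon_pi",
)
GROUP_SUBTYPES = ("amide_amide", "amide_ring", "met_aromatic")
DISTANCE_CLASS_SUBTYPES = ("clash", "covalent", "vdw_clash", "vdw", "proximal")
VOCABULARY = FEATURE_SUBTYPES + GROUP_SUBTYPES + DISTANCE_CLASS_SUBTYPES
VARIANTS = ("ideal", "boundary_pass", "boundary_fail")

# Feature subtypes that legitimately co-occur with a fixture's intended
# subtype: the polar types are angle-free supersets of the hydrogen-bond
# types, and aromatic atom-atom contacts between two close rings are the
# atomwise shadow of a ring-ring interaction.
ALLOWED_EXTRA = {
    "hbond": frozenset({"polar"}),
    "weak_hbond": frozenset({"weak_polar"}),
    "aromatic": frozenset({"pi_pi"}),
}

_HIS_RING_NAMES = ("CG", "ND1", "CE1", "NE2", "CD2")
_HIS_RING_RADIUS = 1.166  # circumradius of the imidazole pentagon, Angstrom
_CO_BOND = 1.23
_CN_PEPTIDE = 1.33
_OH_BOND = 0.96
_CH_BOND = 1.09
_CCL_BOND = 1.74


@dataclasses.dataclass
class FixtureEntry:
    subtype: str
    variant: str
    pdb_text: str
    expect_detected: bool
    allowed_extra: frozenset
    defining_value: float


# ---------------------------------------------------------------------------
# PDB text assembly
# ---------------------------------------------------------------------------


def _pdb_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    xyz,
    element: str,
    hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    if len(element) == 1 and len(name) < 4:
        name_field = f" {name:<3}"
    else:
        name_field = f"{name:<4}"
    x, y, z = (float(v) for v in xyz)
    return (
        f"{record}{serial:5d} {name_field} {res_name:<3} {chain}{res_seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


def _to_pdb(atoms: list) -> str:
    """atoms: (name, res_name, chain, res_seq, element, xyz, hetatm) tuples."""
    lines = [
        _pdb_line(i + 1, name, res_name, chain, res_seq, xyz, element, hetatm)
        for i, (name, res_name, chain, res_seq, element, xyz, hetatm) in enumerate(atoms)
    ]
    return "\n".join(lines) + "\nEND\n"


def _his_ring(chain: str, res_seq: int, centre, phase_deg: float = 0.0, plane: str = "xy") -> list:
    """Imidazole ring fragment (5 dictionary-typed atoms) as atom tuples."""
    centre = np.asarray(centre, dtype=float)
    atoms = []
    for k, name in enumerate(_HIS_RING_NAMES):
        angle = math.radians(phase_deg + 72.0 * k)
        u = _HIS_RING_RADIUS * math.cos(angle)
        v = _HIS_RING_RADIUS * math.sin(angle)
        if plane == "xy":
            offset = np.array([u, v, 0.0])
        else:  # xz
            offset = np.array([u, 0.0, v])
        element = "N" if name.startswith("N") else "C"
        atoms.append((name, "HIS", chain, res_seq, element, centre + offset, False))
    return atoms


def _single(name, res_name, chain, res_seq, element, xyz, hetatm=False) -> tuple:
    return (name, res_name, chain, res_seq, element, np.asarray(xyz, dtype=float), hetatm)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _variant_value(variant: str, ideal: float, threshold: float) -> float:
    if variant == "ideal":
        return ideal
    if variant == "boundary_pass":
        return threshold - 0.05
    return threshold + 0.05


def _pair_fixture(subtype: str, variant: str, config: GeometryConfig) -> tuple:
    """Two-fragment fixtures defined by one interatomic distance."""
    if subtype == "hbond":
        h_dist = _variant_value(variant, 1.84, config.hbond_h_dist_max)
        d = h_dist + _OH_BOND
        atoms = [
            _single("OG", "SER", "A", 1, "O", (0, 0, 0)),
            _single("HG", "SER", "A", 1, "H", (_OH_BOND, 0, 0)),
            _single("O", "HOH", "B", 1, "O", (d, 0, 0), hetatm=True),
        ]
        return atoms, h_dist
    if subtype == "weak_hbond":
        d = _variant_value(variant, 3.30, config.weak_hbond_dist_max)
        atoms = [
            _single("CA", "GLY", "A", 1, "C", (0, 0, 0)),
            _single("HA", "GLY", "A", 1, "H", (_CH_BOND, 0, 0)),
            _single("O", "HOH", "B", 1, "O", (d, 0, 0), hetatm=True),
        ]
        return atoms, d
    if subtype == "xbond":
        d_max = config.rvdw("CL") + config.rvdw("O") + config.vdw_comp
        d = _variant_value(variant, 3.20, d_max)
        theta = math.radians(180.0 - 175.0)  # C-Cl...O angle of 175 degrees
        o_pos = np.array([d * math.cos(theta), d * math.sin(theta), 0.0])
        c_pos = o_pos * (1.0 + _CO_BOND / d)
        atoms = [
            _single("C1", "CLM", "A", 1, "C", (-_CCL_BOND, 0, 0), hetatm=True),
            _single("CL1", "CLM", "A", 1, "CL", (0, 0, 0), hetatm=True),
            _single("O", "GLY", "B", 1, "O", o_pos),
            _single("C", "GLY", "B", 1, "C", c_pos),
        ]
        return atoms, d
    if subtype == "ionic":
        d = _variant_value(variant, 3.00, config.ionic_dist_max)
        atoms = [
            _single("CZ", "ARG", "A", 1, "C", (0, 0, 0)),
            _single("OD1", "ASP", "B", 1, "O", (d, 0, 0)),
        ]
        return atoms, d
    if subtype == "metal":
        d = _variant_value(variant, 2.10, config.metal_dist_max)
        atoms = [
            _single("ZN", "ZN", "A", 1, "ZN", (0, 0, 0), hetatm=True),
            _single("OD1", "ASP", "B", 1, "O", (d, 0, 0)),
        ]
        return atoms, d
    if subtype == "hydrophobic":
        d = _variant_value(variant, 4.20, config.hydrophobic_dist_max)
        atoms = [
            _single("CD1", "LEU", "A", 1, "C", (0, 0, 0)),
            _single("CG1", "VAL", "B", 1, "C", (d, 0, 0)),
        ]
        return atoms, d
    if subtype == "carbonyl":
        d = _variant_value(variant, 3.20, config.carbonyl_dist_max)
        atoms = [
            _single("C", "GLY", "A", 1, "C", (0, -_CO_BOND, 0)),
            _single("O", "GLY", "A", 1, "O", (0, 0, 0)),
            _single("C", "GLY", "B", 1, "C", (d, 0, 0)),
            _single("O", "GLY", "B", 1, "O", (d, _CO_BOND, 0)),
        ]
        return atoms, d
    if subtype == "polar":
        d = _variant_value(variant, 3.00, config.polar_dist_max)
        atoms = [
            _single("OG", "SER", "A", 1, "O", (0, 0, 0)),
            _single("O", "HOH", "B", 1, "O", (d, 0, 0), hetatm=True),
        ]
        return atoms, d
    if subtype == "weak_polar":
        d = _variant_value(variant, 3.50, config.weak_polar_dist_max)
        atoms = [
            _single("CA", "GLY", "A", 1, "C", (0, 0, 0)),
            _single("O", "HOH", "B", 1, "O", (d, 0, 0), hetatm=True),
        ]
        return atoms, d
    if subtype == "aromatic":
        d = _variant_value(variant, 3.50, config.aromatic_dist_max)
        # two coplanar imidazole rings with their CG atoms facing: the CG-CG
        # distance is the defining parameter; every other cross-ring pair is
        # farther away than any feature maximum.
        centre_b = d + 2.0 * _HIS_RING_RADIUS
        atoms = _his_ring("A", 1, (0, 0, 0), phase_deg=0.0)
        atoms += _his_ring("B", 1, (centre_b, 0, 0), phase_deg=180.0)
        return atoms, d
    raise AssertionError(subtype)


def _ring_fixture(subtype: str, variant: str, config: GeometryConfig) -> tuple:
    ring = _his_ring("A", 1, (0, 0, 0), phase_deg=0.0)
    if subtype == "pi_pi":
        d = _variant_value(variant, 4.20, config.ring_ring_dist_max)
        atoms = ring + _his_ring("B", 1, (0, 0, d), phase_deg=0.0)
        return atoms, d
    if subtype == "met_aromatic":
        d = _variant_value(variant, 5.00, config.met_arom_dist_max)
        atoms = ring + [_single("SD", "MET", "B", 1, "S", (0, 0, d))]
        return atoms, d
    # atom-over-face fixtures share the atom-centroid distance gate
    h = _variant_value(
        variant,
        {"cation_pi": 3.50, "donor_pi": 4.10, "halogen_pi": 4.10, "carbon_pi": 4.10}[subtype],
        config.atom_ring_dist_max,
    )
    if subtype == "cation_pi":
        atoms = ring + [_single("CZ", "ARG", "B", 1, "C", (0, 0, h))]
    elif subtype == "donor_pi":
        atoms = ring + [_single("OG", "SER", "B", 1, "O", (0, 0, h))]
    elif subtype == "halogen_pi":
        atoms = ring + [
            _single("CL1", "CLM", "B", 1, "CL", (0, 0, h), hetatm=True),
            _single("C1", "CLM", "B", 1, "C", (0, 0, h + _CCL_BOND), hetatm=True),
        ]
    elif subtype == "carbon_pi":
        atoms = ring + [_single("CA", "GLY", "B", 1, "C", (0, 0, h))]
    else:
        raise AssertionError(subtype)
    return atoms, h


def _amide_atoms(chain: str, origin) -> list:
    """Peptide-bond amide fragment: C,O of residue 1 + N of residue 2."""
    origin = np.asarray(origin, dtype=float)
    return [
        _single("C", "GLY", chain, 1, "C", origin + (0, 0, 0)),
        _single("O", "GLY", chain, 1, "O", origin + (0, _CO_BOND, 0)),
        _single("N", "GLY", chain, 2, "N", origin + (_CN_PEPTIDE, 0, 0)),
    ]


_AMIDE_CENTROID = np.array([_CN_PEPTIDE / 3.0, _CO_BOND / 3.0, 0.0])


def _amide_fixture(subtype: str, variant: str, config: GeometryConfig) -> tuple:
    if subtype == "amide_amide":
        d = _variant_value(variant, 3.70, config.amide_amide_dist_max)
        atoms = _amide_atoms("A", (0, 0, 0)) + _amide_atoms("B", (0, 0, d))
        return atoms, d
    if subtype == "amide_ring":
        h = _variant_value(variant, 4.20, config.amide_ring_dist_max)
        shift = np.array([-_AMIDE_CENTROID[0], -_AMIDE_CENTROID[1], h])
        atoms = _his_ring("A", 1, (0, 0, 0), phase_deg=0.0) + _amide_atoms("B", shift)
        return atoms, h
    raise AssertionError(subtype)


def _distance_class_fixture(subtype: str, variant: str, config: GeometryConfig) -> tuple:
    rcov = 2.0 * config.rcov("C")
    rvdw = 2.0 * config.rvdw("C")
    bands = {
        "clash": (1.00, rcov - config.cov_tol),
        "covalent": (rcov, rcov + config.cov_tol),
        "vdw_clash": ((rcov + config.cov_tol + rvdw) / 2.0, rvdw),
        "vdw": (rvdw + config.vdw_comp / 2.0, rvdw + config.vdw_comp),
        "proximal": ((rvdw + config.vdw_comp + config.cutoff) / 2.0, config.cutoff),
    }
    ideal, upper = bands[subtype]
    d = _variant_value(variant, ideal, upper)
    atoms = [
        _single("C", "GLY", "A", 1, "C", (0, 0, 0)),
        _single("C", "GLY", "B", 1, "C", (d, 0, 0)),
    ]
    return atoms, d


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def make_fixture(
    subtype: str, variant: str, config: GeometryConfig | None = None
) -> FixtureEntry:
    """Minimal PDB fixture for one interaction subtype and boundary variant."""
    config = config or GeometryConfig.default()
    if subtype not in VOCABULARY:
        raise ValueError(
            f"unknown subtype {subtype!r}; supported: {', '.join(VOCABULARY)}"
        )
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; supported: {', '.join(VARIANTS)}")

    if subtype in DISTANCE_CLASS_SUBTYPES:
        atoms, value = _distance_class_fixture(subtype, variant, config)
    elif subtype in ("amide_amide", "amide_ring"):
        atoms, value = _amide_fixture(subtype, variant, config)
    elif subtype in ("pi_pi", "cation_pi", "donor_pi", "halogen_pi", "carbon_pi", "met_aromatic"):
        atoms, value = _ring_fixture(subtype, variant, config)
    else:
        atoms, value = _pair_fixture(subtype, variant, config)

    return FixtureEntry(
        subtype=subtype,
        variant=variant,
        pdb_text=_to_pdb(atoms),
        expect_detected=variant != "boundary_fail",
        allowed_extra=ALLOWED_EXTRA.get(subtype, frozenset()),
        defining_value=value,
    )


def fixture_catalogue(config: GeometryConfig | None = None) -> list:
    """Full cross product of the subtype vocabulary and the three variants."""
    config = config or GeometryConfig.default()
    return [
        make_fixture(subtype, variant, config)
        for subtype in VOCABULARY
        for variant in VARIANTS
    ]


def observed_subtypes(result) -> tuple:
    """(feature/group subtype names, distance-class names) found in a result."""
    features: set = set()
    for contact in result.contacts:
        features |= contact.feature_bits
    if result.pi_pi:
        features.add("pi_pi")
    for inter in result.atom_rings:
        features |= set(inter.subtypes)
    for inter in result.amide_interactions:
        features.add(inter.kind)
    if result.met_interactions:
        features.add("met_aromatic")
    classes = {c.distance_class for c in result.contacts}
    return features, classes


def evaluate_fixture(entry: FixtureEntry, config: GeometryConfig | None = None) -> dict:
    """Run the full pipeline on a fixture and compare with its annotation."""
    from .cli import run_analysis

    config = config or GeometryConfig.default()
    result = run_analysis(entry.pdb_text, config=config)
    features, classes = observed_subtypes(result)
    if entry.subtype in DISTANCE_CLASS_SUBTYPES:
        detected = entry.subtype in classes
        unexpected = set(features)
    else:
        detected = entry.subtype in features
        unexpected = features - {entry.subtype} - set(entry.allowed_extra)
    return {
        "entry": entry,
        "result": result,
        "detected": detected,
        "features": features,
        "classes": classes,
        "unexpected": unexpected,
        "as_expected": detected == entry.expect_detected,
    }


def random_structure(seed: int, n_atoms: int = 50, box: float = 18.0) -> str:
    """Seeded random hetero structure (one atom per residue) as PDB text."""
    rng = np.random.default_rng(seed)
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms)
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    atoms = [
        _single(f"{elements[i]}1", "UNX", "A", i + 1, str(elements[i]), coords[i], hetatm=True)
        for i in range(n_atoms)
    ]
    return _to_pdb(atoms)


def atom_record(
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    element: str,
    xyz,
    hetatm: bool = False,
) -> tuple:
    """Public helper: one atom tuple for :func:`assemble_pdb`."""
    return _single(name, res_name, chain, res_seq, element, xyz, hetatm)


def assemble_pdb(atom_records: list) -> str:
    """Public helper: PDB text from :func:`atom_record` tuples."""
    return _to_pdb(atom_records)


def imidazole_ring(chain: str, res_seq: int, centre, phase_deg: float = 0.0) -> list:
    """Public helper: His imidazole ring fragment as atom records."""
    return _his_ring(chain, res_seq, centre, phase_deg)


def dump_catalogue(out_dir: Path, config: GeometryConfig | None = None) -> Path:
    """Write every fixture as a .pdb file plus a manifest TSV; returns the manifest path."""
    import pandas as pd

    config = config or GeometryConfig.default()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in fixture_catalogue(config):
        name = f"{entry.subtype}__{entry.variant}.pdb"
        (out_dir / name).write_text(entry.pdb_text)
        rows.append(
            {
                "subtype": entry.subtype,
                "variant": entry.variant,
                "file": name,
                "expect_detected": int(entry.expect_detected),
                "defining_value": f"{entry.defining_value:.3f}",
                "allowed_extra": ",".join(sorted(entry.allowed_extra)),
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False, lineterminator="\n")
    return manifest
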