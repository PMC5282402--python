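import numpy as np
import pytest

import contactsift as cs
from contactsift.fixtures import assemble_pdb, atom_record, imidazole_ring


@pytest.fixture(scope="session")
def config():
    return cs.GeometryConfig.default()


@pytest.fixture(scope="session")
def dictionary():
    return cs.TypingDictionary.default()


def gly_gly_atoms(oxt: bool = True, chain: str = "A") -> list:
    """Gly-Gly dipeptide fragment with a valid peptide bond (C-N 1.33 A)."""
    atoms = [
        atom_record("N", "GLY", chain, 1, "N", (0.0, 0.0, 0.0)),
        atom_record("CA", "GLY", chain, 1, "C", (1.45, 0.0, 0.0)),
        atom_record("C", "GLY", chain, 1, "C", (2.0, 1.3, 0.0)),
        atom_record("O", "GLY", chain, 1, "O", (2.0, 2.53, 0.0)),
        atom_record("N", "GLY", chain, 2, "N", (3.33, 1.3, 0.0)),
        atom_record("CA", "GLY", chain, 2, "C", (4.3, 2.3, 0.0)),
        atom_record("C", "GLY", chain, 2, "C", (5.7, 2.3, 0.0)),
        atom_record("O", "GLY", chain, 2, "O", (5.7, 3.53, 0.0)),
    ]
    if oxt:
        atoms.append(atom_record("OXT", "GLY", chain, 2, "O", (6.315, 1.235, 0.0)))
    return atoms


@pytest.fixture(scope="session")
def gly_gly_pdb():
    return assemble_pdb(gly_gly_atoms())


def benzene_atoms(
    centre=(0.0, 0.0, 0.0), normal_axis: str = "z", res_name: str = "BNZ", chain: str = "A", res_seq: int = 1
) -> list:
    """Regular benzene hexagon, C-C 1.39 A (circumradius 1.39 A)."""
    centre = np.asarray(centre, dtype=float)
    atoms = []
    for i in range(6):
        a = np.radians(60.0 * i)
        u, v = 1.39 * np.cos(a), 1.39 * np.sin(a)
        offset = {
            "z": np.array([u, v, 0.0]),
            "x": np.array([0.0, u, v]),
            "y": np.array([u, 0.0, v]),
        }[normal_axis]
        atoms.append(
            atom_record(f"C{i+1}", res_name, chain, res_seq, "C", centre + offset, hetatm=True)
        )
    return atoms


def analyse(pdb_text: str, config=None, **kwargs) -> cs.AnalysisResult:
    return cs.run_analysis(pdb_text, config=config or cs.GeometryConfig.default(), **kwargs)


__all__ = [
    "analyse",
    "assemble_pdb",
    "atom_record",
    "benzene_atoms",
    "gly_gly_atoms",
    "imidazole_ring",
]
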