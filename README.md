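# contactsift

Interatomic contact detection and structural interaction fingerprints
(SIFts) for macromolecular structures.

Given a structure in PDB format — any mix of protein, nucleic acid,
small-molecule HETATM groups, waters and metals, with or without hydrogens —
`contactsift` assigns physicochemical types to every atom, enumerates all
atom pairs within a 5 Å radial cutoff, and classifies each pair with a
structural interaction fingerprint. It is aimed at structural biologists and
computational chemists who need defined, reproducible interaction criteria
rather than visual intuition: binding-site analysis, interface
characterisation, mutation impact assessment, fingerprint generation for
downstream statistics.

## The fingerprint

For a pair of atoms *a*, *b* at distance *d*, with summed covalent radii
*R*<sub>cov</sub> and summed van der Waals radii *R*<sub>vdW</sub>, the first
five bits are a **mutually exclusive distance class**:

| class | condition |
|---|---|
| clash | *d* < *R*<sub>cov</sub> − t<sub>cov</sub> |
| covalent | *R*<sub>cov</sub> − t<sub>cov</sub> ≤ *d* ≤ *R*<sub>cov</sub> + t<sub>cov</sub> |
| vdw_clash | *R*<sub>cov</sub> + t<sub>cov</sub> < *d* < *R*<sub>vdW</sub> |
| vdw | *R*<sub>vdW</sub> ≤ *d* ≤ *R*<sub>vdW</sub> + c |
| proximal | otherwise, up to the 5 Å cutoff |

The remaining bits are **feature interactions** gated by atom typing plus
distance (and angle) criteria: hydrogen bond (D–H⋯A with ∠D–H⋯A and H⋯A
terms), weak hydrogen bond (C–H donor), halogen bond (C–X⋯A σ-hole
directionality, X = Cl/Br/I), ionic, metal complex, aromatic,
hydrophobe–hydrophobe and carbonyl (n→π\*) interactions, plus angle-free
**polar** and **weak polar** analogues of the two hydrogen-bond types that
remain meaningful when hydrogens are not modelled.

Planar groups are first-class objects: aromatic rings (dictionary-defined
for standard residues, perceived from connectivity and planarity for
ligands) and amide groups (peptide bonds, Asn/Gln side chains, ligand
amides) carry centroids and least-squares-plane normals, supporting
ring–ring (π–π, labelled stacked/tilted/T-shaped by interplanar angle),
atom–ring (cation-π, donor-π, halogen-π, carbon-π over the ring face),
amide–amide, amide–ring and methionine sulphur–aromatic interactions.
Everything is aggregated per residue into binary and integer fingerprints
(counts of atoms making each contact type; group interactions count once per
interaction).

Typing is robust to common model defects: any covalently bound oxygen is an
acceptor (so carboxylates are never stripped of acceptor character), terminal
main-chain atoms are typed from a dictionary even when sibling atoms are
missing (a C-terminus without OXT is still a carboxylate, never a spurious
hydroxyl donor), and a `--lenient` switch types both histidine ring
nitrogens as donor *and* acceptor to absorb tautomer/flip ambiguity.

## Worked example

A minimal hydrogen-bond fixture (serine hydroxyl donating to a water oxygen
at 2.8 Å, linear geometry) — the package generates this itself:

```sh
python -c "
import contactsift as cs
cfg = cs.GeometryConfig.default()
open('hbond.pdb','w').write(cs.make_fixture('hbond','ideal',cfg).pdb_text)"
contactsift hbond.pdb -o out
```

`out/hbond.contacts.tsv`:

```text
atom_a	atom_b	distance	entity_label	clash	covalent	vdw_clash	vdw	proximal	hbond	weak_hbond	xbond	ionic	metal	aromatic	hydrophobic	carbonyl	polar	weak_polar
A/1/OG	B/1/O	2.800	intra_nonselection	0	0	1	0	0	1	0	0	0	0	0	0	0	1	0
A/1/HG	B/1/O	1.840	intra_nonselection	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
```

The OG⋯O pair overlaps van der Waals radii (`vdw_clash` = 1, exactly one
distance-class bit per row) and satisfies both the full hydrogen-bond
geometry (`hbond`) and its angle-free superset (`polar`); the H⋯O row is a
distance-class-only record. Five more files are written alongside:
`rings.tsv` (π–π), `atom_rings.tsv`, `groups.tsv` (amide/Met–aromatic),
`residue_sifts.tsv` (per-residue binary + count vectors) and `summary.tsv`
(in-scope totals per type — here `hbond 1`, `polar 1`, `vdw_clash 2`).

Typical options:

```sh
contactsift 1abc.pdb -s /A/200/ -o results      # ligand A:200 vs its binding site
contactsift 1abc.pdb -s /A// -s /B//            # chain-chain interface
contactsift 1abc.pdb --lenient --model 0 -c my_geometry.yaml -v
contactsift fixtures --out fixture_dir          # dump the analytic catalogue
```

With a selection, contacts are labelled `intra_selection` / `inter` /
`intra_nonselection` (`water_bridge_candidate` for selection–water
contacts), and residue fingerprints and the summary are restricted to
inter-entity interactions.

Every geometric threshold lives in `src/contactsift/data/geometry.yaml`
(override with `-c`); radii tables and the typing dictionary are equally
editable YAML.

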