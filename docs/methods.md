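# Methods

## Scope and model

`contactsift` computes pairwise interatomic interactions in macromolecular
structures from geometry and physicochemical atom typing alone: no energies,
no electrostatics, no protonation-state prediction. An interaction exists
when its typing preconditions hold and its distance/angle gates pass. All
coordinates and distances are in Å, angles in degrees, and residue numbering
is reported exactly as authored in the input file.

## Structure model

Parsing is built on Biopython's PDB parser. One model is analysed at a time
(`--model`, default 0; NMR ensembles are never averaged). Alternate
locations are resolved to the highest-occupancy conformer, ties broken by
alphabetical altLoc identifier — a deterministic convention chosen because
the PDB format itself does not prescribe one; every dropped conformer is
logged with a reason, so each ATOM/HETATM record of the chosen model maps to
exactly one atom or one log line. Residue identity is the triple (chain,
resSeq, iCode) with file order preserved. Elements come from columns 77–78,
falling back to name-based inference (digits stripped, two-letter symbols
recognised when the name starts in column 13); deuterium is treated as
hydrogen. Hydrogens are parsed and used (hydrogen-bond geometry, donor
protonation checks) but carry no feature flags themselves.

Covalent bonds are inferred where d ≤ r_cov(a) + r_cov(b) + 0.45 Å
(plus any CONECT records), with a 0.4 Å lower bound against duplicate
coordinates. Metals are excluded from bond inference: coordination is
handled by the metal-complex detector, and treating Zn–O at 2.1 Å as a
covalent bond would wrongly suppress the interaction. Polymer connectivity
uses peptide C–N ≤ 1.7 Å and nucleotide O3′–P ≤ 1.8 Å; residues
with a successor but no predecessor are N-terminal (5′), the converse
C-terminal (3′). An isolated polymer residue is marked neither — a
fragment's "terminus" is not meaningful and terminus retyping would be
speculative.

Entities are polymer chains plus connected components of the bond graph
restricted to hetero residues (waters excluded), matching the
ligand-vs-binding-site and chain-vs-chain calculation modes. Selections use
`/chain/resseq[icode]/atomname`, empty component = wildcard, items unioned.

## Atom typing

Standard residues, nucleotides and waters are typed from a shipped
dictionary (`data/typing_dictionary.yaml`), covering every heavy atom of the
20 amino acids, the eight standard (deoxy)ribonucleotides and peptide
backbone/termini entries. The dictionary applies two uniform conventions:
hydrophobes are carbon or sulphur atoms with no N/O/P neighbour in the
canonical topology (halogens on carbon also count), and weak donors are
carbons bearing at least one hydrogen in the canonical residue.

Hetero groups are typed from their inferred connectivity by a rule layer
(terminal short C–O ⇒ carbonyl pair; two terminal oxygens on one carbon ⇒
carboxylate; terminal O on P/S ⇒ negatively ionisable; N with hydrogens or
low coordination ⇒ donor; halogen on carbon ⇒ halogen-bond donor, Cl/Br/I
only — fluorine's σ-hole is negligible). Where a chemically sensible
molecule can be built from the group (RDKit bond-order determination
succeeds), SMARTS patterns from `data/patterns.yaml` add refinements; when
it cannot — fragmentary ligands without hydrogens are common — the rule
layer alone is the contract. Correctness is defined against the analytic
fixture suite, not against any particular pattern file.

Three robustness passes run after base typing:

* **Lenient acceptors.** Any covalently bound oxygen is a hydrogen-bond
  acceptor, so delocalised carboxylate/phosphate oxygens keep acceptor
  character regardless of how a pattern would classify them.
* **Terminus correction.** A C-terminal residue's O and OXT are typed
  {acceptor, negatively ionisable} even when OXT is absent — by
  construction, a lone terminal oxygen can never be mistyped as a hydroxyl
  donor. An N-terminal nitrogen is a protonated amine (proline: donor only
  with an explicit hydrogen, it is a secondary amine).
* **Histidine leniency.** With `--lenient`, both ring nitrogens become donor
  and acceptor (and positively ionisable), absorbing tautomer and flip
  ambiguity; without it, donor/acceptor assignment follows explicit
  hydrogens, and an unprotonated ring nitrogen is acceptor-only.

Metal cations (single-atom HETATM residues of metallic elements) carry the
metal flag exclusively. Halogen-bond acceptors mirror hydrogen-bond
acceptors. Typing is idempotent: flags are recomputed from scratch each run.

## Rings and amide groups

Dictionary rings (Phe/Tyr six-ring, Trp 5+6, His imidazole, purine 5+6,
pyrimidine six-ring) are instantiated whenever all member atoms are present;
incomplete rings are skipped with a warning. Hetero-group rings come from a
minimum cycle basis of the bond graph, gated by size ≥ 5, composition
(C/N/O/S), heavy degree ≤ 3 and planarity: RMS out-of-plane deviation
≤ 0.1 Å of the least-squares plane. The plane normal is the singular
vector of the smallest singular value of the centred member coordinates; its
sign is arbitrary and all downstream angles are folded to [0°, 90°].
A perfectly flat saturated ring would pass this geometric gate; puckered
saturated rings (the realistic case) are rejected.

Amide groups are one per peptide bond (C, O of residue i, N of i+1, plus the
amide hydrogen when present), one per Asn/Gln side chain, and one per ligand
C(=O)N match; the centroid and normal are computed from the C/O/N triangle.

## Detectors and thresholds

Tools of this class keep their thresholds in configuration files rather
than prose; the defaults here are standard hydrogen-bond-survey values of
the HBPLUS lineage, all externalised in `data/geometry.yaml`:

| parameter | default | meaning |
|---|---|---|
| cutoff | 5.0 Å | radial neighbour cutoff (SciPy cKDTree) |
| cov_tol | 0.1 Å | covalent-band half-width |
| vdw_comp | 0.1 Å | vdW-band width / halogen-bond compensation |
| hbond | 3.9 Å, H⋯A 2.7 Å, ∠ ≥ 90° | D–H⋯A |
| weak hbond | 3.6 Å, H⋯A 3.0 Å, ∠ ≥ 130° | C–H⋯A, D–H⋯X |
| polar / weak polar | 3.5 / 4.0 Å | angle-free analogues |
| xbond | r_vdW sum + 0.1 Å, ∠C–X⋯A ≥ 120° | σ-hole directionality |
| ionic / metal | 4.0 / 2.8 Å | opposite ionisable flags / metal–acceptor |
| carbonyl / hydrophobic / aromatic | 3.6 / 4.5 / 4.0 Å | atom–atom |
| ring–ring | 6.0 Å; stacked ≤ 30° < tilted < 60° ≤ t_shaped | centroid gate + label |
| atom–ring | 4.5 Å, ≤ 30° off-normal | face cone |
| amide–amide / amide–ring | 5.0 / 4.5 Å | centroid gates |
| Met S–aromatic | 6.0 Å | S⋯centroid |

Radii ship as data: Pyykkö single-bond covalent radii and Bondi van der
Waals radii (common extensions for metals), overridable in the config.

Design choices where the design was genuinely open:

* The stacked/tilted/T-shaped discretisation of π–π geometry is this
  package's own (the interaction itself is recorded without a sub-taxonomy
  upstream); no lateral-offset criterion is applied beyond the centroid and
  face-angle gates — offsets are recoverable from the reported geometry.
* Atom–ring subtypes are non-exclusive (flags are independent properties: a
  lysine NZ over a ring is both cation-π and donor-π). Atoms that are
  themselves members of a perceived ring or amide group are excluded from
  atom–ring detection: their stacking is reported once, at group level, not
  double-counted as dozens of member-atom events.
* A residue's own backbone amide is not paired with its own side-chain ring.
* Feature bits are suppressed on clash/covalent contacts and on 1–2/1–3
  bonded pairs across residues (a bonded pair is not "interacting");
  intra-residue pairs are never reported. Note that a peptide C–N bond
  (1.33 Å, partial double bond) falls below the single-bond covalent sum
  and therefore classifies as `clash` — the class bits describe distance
  geometry relative to single-bond radii, not bond orders.
* Proximal contacts may carry feature bits when the feature's own distance
  test passes (e.g. an ionic pair at 3.95 Å); this is deliberate, not an
  inconsistency.
* Waters participate in hydrogen-bond/polar/metal detection and receive
  residue fingerprints like any residue; water-mediated bridge analysis is
  out of scope, but selection–water contacts are labelled
  `water_bridge_candidate` so downstream tools can find them.
* His rings participate in π interactions regardless of protonation.
* Cys SG is excluded from sulphur–aromatic detection by default
  (`include_all_thioethers` widens it to any thioether).

Residue fingerprints follow atom-counting semantics: the integer for an
atom–atom type is the number of the residue's atoms making ≥ 1 such
contact (an atom with two hydrogen bonds counts once); ring/group
interactions count once per interaction per parent residue. A contact
contributes to both partners' fingerprints — each fingerprint describes that
residue's environment. With an active selection, scope is restricted to
inter-entity contacts.

## The fixture generator

The primary test surface is a catalogue of analytic PDB fixtures: for each
of the 15 feature subtypes, 3 group families and 5 distance classes, three
variants place the defining geometric parameter at an ideal value, at the
threshold − 0.05 Å, and at the threshold + 0.05 Å. Boundary values are
derived from the loaded configuration at generation time, so threshold edits
keep the suite self-consistent. Fragments are minimal and chosen so typing
is dictionary-driven wherever possible (e.g. Arg CZ as a pure cation that is
neither donor nor weak donor; imidazole rings rather than benzene where a
hydrocarbon ring's hydrophobic atoms would fire a second detector). Each
fixture is annotated with its expected outcome and with the subtypes that
legitimately co-occur: `polar` alongside a hydrogen bond and `weak_polar`
alongside a weak hydrogen bond (angle-free supersets by construction), and
`pi_pi` alongside aromatic atom–atom contacts (two rings close enough for
atom-level aromatic contacts are necessarily within the ring–ring centroid
gate). Any other co-firing subtype fails the suite.

What the fixtures emulate — and what they do not: they are geometry-exact,
hydrogen-sparse fragments probing one decision boundary each. They do not
exercise crystallographic noise, alternate conformers in contact regions,
exotic ligand chemistry (where SMARTS semantics on real molecules matter),
or crowded environments where many detectors fire at once. Passing the
suite shows the decision logic and thresholds are implemented exactly; it
does not calibrate the thresholds themselves against experimental structure
statistics.

Seeded random structures (50 atoms of C/N/O/S uniform in an 18 Å box, one
atom per residue) supplement the catalogue for the properties that need
volume: spatial-index completeness against an O(n²) brute-force oracle and
one-hot distance classes over thousands of contacts. Problem sizes
(100 random structures of 50 atoms; a 69-entry catalogue) keep the whole
verification run in seconds while exceeding a thousand classified contacts.

## Numerical notes

Distances are float64 throughout; the 5 Å cutoff and all thresholds are
compared inclusively (d ≤ max passes). Angle computations clamp cosines to
[−1, 1]. Normals are reproducible under member permutation up to sign; all
reported angles are sign-folded. Output files are deterministic: rows sorted
by (serial_a, serial_b) or by group identifiers, floats fixed to 3 decimals
(angles 1 decimal), LF endings. Rigid motions change contact distances by
< 1e-12 Å in practice (verified to 1e-6 in the suite); PDB coordinate
quantisation (0.001 Å) applies only when a transformed structure is
re-written as text, which the invariance checks therefore avoid.

## Known limitations

* No protonation-state or pKa reasoning beyond explicit hydrogens and the
  His leniency switch; no formal charges from quantum methods.
* SMARTS refinement of hetero groups requires a sanitisable molecule;
  fragmentary ligands fall back to connectivity rules silently.
* mmCIF input, structure repair, hydrogen addition, PDB fetching by
  accession, energy scoring and water-network analysis are out of scope.
* Numerical agreement with any particular external tool on real PDB entries
  is not a goal: thresholds are configurable and correctness is defined by
  the fixture suite.
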