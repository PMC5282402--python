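# Geometric thresholds for contact detection and interaction classification.
# All distances in Angstrom, all angles in degrees. Edit and point the CLI at
# this file with -c/--config to override any value.

# Radial neighbour cutoff: atom pairs beyond this distance are never reported.
cutoff: 5.0

# Half-width of the covalent-bond distance band around the summed covalent radii.
cov_tol: 0.1
# Compensation added to summed van der Waals radii for the vdW band and for
# halogen-bond distance maxima.
vdw_comp: 0.1

# Hydrogen bonds (D-H...A): donor-acceptor max, hydrogen-acceptor max, D-H...A minimum angle.
hbond_dist_max: 3.9
hbond_h_dist_max: 2.7
hbond_angle_min: 90.0

# Weak hydrogen bonds (carbon donor C-H...A, or D-H...halogen).
weak_hbond_dist_max: 3.6
weak_hbond_h_dist_max: 3.0
weak_hbond_angle_min: 130.0

# Angle-free polar analogues of (weak) hydrogen bonds; robust to missing hydrogens.
polar_dist_max: 3.5
weak_polar_dist_max: 4.0

# Halogen bonds: distance max is rvdw(X)+rvdw(A)+vdw_comp; sigma-hole directionality.
xbond_angle_min: 120.0

ionic_dist_max: 4.0
metal_dist_max: 2.8
carbonyl_dist_max: 3.6
hydrophobic_dist_max: 4.5
aromatic_dist_max: 4.0

# Ring-ring (pi-pi) interactions: centroid-centroid maximum and the interplanar
# angle boundaries of the stacked / tilted / t_shaped geometry labels.
ring_ring_dist_max: 6.0
stacked_angle_max: 30.0
t_shaped_angle_min: 60.0

# Atom-ring (cation-pi, donor-pi, halogen-pi, carbon-pi): atom-centroid maximum
# and maximum angle between the ring normal and the centroid->atom vector.
atom_ring_dist_max: 4.5
atom_ring_angle_max: 30.0

# Amide group interactions (centroid-centroid).
amide_amide_dist_max: 5.0
amide_ring_dist_max: 4.5

# Methionine sulphur - aromatic ring (S...centroid).
met_arom_dist_max: 6.0
# When true, any thioether sulphur (e.g. Cys SG) participates, not just Met SD.
include_all_thioethers: false

# Halogens bonded to carbon act as weak hydrogen-bond acceptors.
halogen_weak_acceptor: true

# Bond inference: bonded iff distance <= rcov(a)+rcov(b)+bond_tol (metals excluded).
bond_tol: 0.45
# Maximum RMS out-of-plane deviation for accepting a perceived hetero-group ring.
planarity_tol: 0.1
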