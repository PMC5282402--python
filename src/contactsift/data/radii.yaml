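# Element radii in Angstrom. Covalent radii follow the Pyykko single-bond
# scale; van der Waals radii follow the Bondi scale (with common extensions
# for metals). Keys are upper-case element symbols; deuterium maps to H.
covalent:
  H: 0.32
  D: 0.32
  B: 0.85
  C: 0.75
  N: 0.71
  O: 0.63
  F: 0.64
  NA: 1.55
  MG: 1.39
  P: 1.11
  S: 1.03
  CL: 0.99
  K: 1.96
  CA: 1.71
  MN: 1.19
  FE: 1.16
  CO: 1.11
  NI: 1.10
  CU: 1.12
  ZN: 1.18
  AS: 1.21
  SE: 1.16
  BR: 1.14
  CD: 1.36
  I: 1.33
  HG: 1.33
vdw:
  H: 1.20
  D: 1.20
  B: 1.92
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  NA: 2.27
  MG: 1.73
  P: 1.80
  S: 1.80
  CL: 1.75
  K: 2.75
  CA: 2.31
  MN: 2.05
  FE: 2.05
  CO: 2.00
  NI: 1.97
  CU: 1.96
  ZN: 1.39
  AS: 1.85
  SE: 1.90
  BR: 1.85
  CD: 1.58
  I: 1.98
  HG: 1.55
metals: [LI, NA, MG, K, CA, MN, FE, CO, NI, CU, ZN, CD, HG, AL, RB, CS, SR, BA]
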