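# Default hemefold parameter set.
#
# Units: lengths nm, energies kJ/mol, angles rad, charges e, temperature K.
# Every key is required by the loader; there are no silent fallbacks.
schema_version: 1

# Fe coordinate-covalent restraint (Cbeta_i -- Fe distance + angular gate).
# lambda is per residue type (one-letter code); negative values are attractive
# wells.  Only His and Met coordinate the iron in this model.
fe_cc:
  lambda:
    A: 0.0
    C: 0.0
    D: 0.0
    E: 0.0
    F: 0.0
    G: 0.0
    H: -1500.0
    I: 0.0
    K: 0.0
    L: 0.0
    M: -750.0
    N: 0.0
    P: 0.0
    Q: 0.0
    R: 0.0
    S: 0.0
    T: 0.0
    V: 0.0
    W: 0.0
    Y: 0.0
  r0: 0.45          # equilibrium Cbeta--Fe distance
  theta0: 1.0       # angular gate threshold on angle(Cbeta, Fe, N_pyrrole)
  exponent_sign: -1 # -1: bounded Gaussian well; +1: literal growing exponential

# Screened (Debye-Hueckel-like) electrostatics between residue charges on
# Cbeta and the heme partial charges.  lambda = Coulomb constant / dielectric.
elec:
  lambda: 1.7367    # 138.935458 kJ mol^-1 nm e^-2 / 80
  k_screening: 1.0
  l_screening: 1.0  # Debye length, nm

# Backbone N-H ... carboxylate-O hydrogen bond
hb_backbone:
  lambda: -4.0
  r0: 0.20          # H...O distance
  theta0: 1.5708    # gate opens ~1.5 rad above this (near-linear N-H...O)

# Sidechain Cbeta ... carboxylate-O hydrogen bond, per residue type.
# Basic residues are parameterized at salt-bridge strength (Lys/Arg --
# propionate ion pairs), polar donors at ordinary hydrogen-bond
# strength.
hb_sidechain:
  lambda:
    A: 0.0
    C: 0.0
    D: 0.0
    E: 0.0
    F: 0.0
    G: 0.0
    H: -4.0
    I: 0.0
    K: -6.0
    L: 0.0
    M: 0.0
    N: -3.0
    P: 0.0
    Q: -3.0
    R: -6.0
    S: -2.0
    T: -2.0
    V: 0.0
    W: -1.0
    Y: -3.0
  r0:
    A: 0.45
    C: 0.45
    D: 0.45
    E: 0.45
    F: 0.45
    G: 0.45
    H: 0.45
    I: 0.45
    K: 0.45
    L: 0.45
    M: 0.45
    N: 0.45
    P: 0.45
    Q: 0.45
    R: 0.45
    S: 0.45
    T: 0.45
    V: 0.45
    W: 0.45
    Y: 0.45

# Desolvation penalty for burying the hydrophilic carboxylates
burial:
  lambda: 100.0
  r0: 0.70

# Excluded volume between every protein bead and every heme atom
excl:
  lambda: 2000.0
  r0: 0.35

# Thioester tether (heme c only): CXXC cysteine Cbeta -- vinyl carbon
thioester:
  lambda_cs: -250.0
  r0: 0.40

# Heme-protein contact cutoff used by the pocket-accuracy metric Q_c
qc_cutoff: 0.65

# Ideal-geometry virtual backbone sites as fixed linear combinations of
# neighbouring bead coordinates (coefficients sum to 1: affine, hence
# rigid-motion equivariant).
backbone_virtual_sites:
  N: {ca_prev: 0.48318, ca: 0.70328, o_prev: -0.18643}
  H: {ca_prev: 0.84100, ca: 0.89296, o_prev: -0.73389}
  C: {ca: 0.44365, ca_next: 0.23520, o: 0.32115}

# Internal heme forcefield: harmonic bonds/angles E = k (x - x0)^2,
# periodic dihedrals E = k (1 + cos(n*phi - gamma)), LJ + screened Coulomb
# nonbonded with 1-2/1-3 exclusions and scaled 1-4 pairs.
heme:
  formal_charge: -2.0
  charges:
    FE: 0.60
    NA: -0.25
    NB: -0.25
    NC: -0.25
    ND: -0.25
    C1A: 0.05
    C4A: 0.05
    C1B: 0.05
    C4B: 0.05
    C1C: 0.05
    C4C: 0.05
    C1D: 0.05
    C4D: 0.05
    CHA: -0.10
    CHB: -0.10
    CHC: -0.10
    CHD: -0.10
    CAB: 0.00
    CAC: 0.00
    CAA: 0.00
    CGA: 0.70
    O1A: -0.80
    O2A: -0.70
    CAD: 0.00
    CGD: 0.70
    O1D: -0.80
    O2D: -0.70
  lj:
    C:  {sigma: 0.340, epsilon: 0.36}
    N:  {sigma: 0.325, epsilon: 0.71}
    O:  {sigma: 0.296, epsilon: 0.88}
    FE: {sigma: 0.230, epsilon: 0.05}
  bond_k: 34000.0       # kJ/mol/nm^2
  angle_k: 250.0        # kJ/mol/rad^2
  dihedral_k: 5.0       # kJ/mol, n = 2, gamma = pi (planarity-preserving)
  coulomb_constant: 138.935458
  dielectric: 80.0
  scale14_lj: 0.2
  scale14_coulomb: 0.8333333333

# Structure-based single-memory protein potential (stand-in for the
# transferable coarse-grained protein forcefield): Gaussian wells on native
# Calpha-Calpha and Cbeta-Cbeta pair distances (sequence separation >= 3),
# harmonic chain connectivity, and a chirality restraint on the signed
# Calpha/Cbeta triple product.
standin:
  epsilon: 1.1          # kJ/mol well depth per native pair
  width: 0.10           # nm well width
  bond_k: 10000.0       # kJ/mol/nm^2 on native bond lengths
  chirality_k: 5000.0   # kJ/mol/nm^6 on the triple product
  pair_cutoff: 1.2      # native pairs farther than this get no well, nm

# Pair-distance truncation for the Gaussian coupling terms
truncation_cutoff: 2.0
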