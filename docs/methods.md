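# Methods

This note documents the model implemented in `hemefold`, the choices
made where the design was genuinely open, and what the test systems do
and do not show about real heme proteins.

## Representation

The protein is coarse-grained to three interaction sites per residue:
Cα, Cβ (absent for glycine) and the carbonyl O.  The remaining backbone
sites — amide N, amide H and carbonyl C — are *virtual*: they are
reconstructed on the fly as fixed affine combinations of neighbouring
bead coordinates under an ideal peptide-geometry assumption
(N and H of residue *i* from Cα(i−1), Cα(i), O(i−1); C of residue *i*
from Cα(i), Cα(i+1), O(i)).  The coefficients live in the parameter
file; the loader renormalizes them to sum exactly to one, because only
an exactly affine combination is equivariant under rigid motion, and
forces on virtual sites are chain-ruled onto their parent beads with
those same coefficients.  Residue charges are the minimal coarse-grained
convention: Asp/Glu −1, Lys/Arg +1, everything else (including His) 0,
carried on Cβ.

The heme keeps all heavy atoms.  Atoms are role-tagged by PDB v3 name
(FE; NA/NB/NC/ND pyrrole nitrogens; O1A/O2A/O1D/O2D carboxylate oxygens;
CAB/CAC ring-bonded vinyl carbons), with a config-overridable role map
for nonstandard dialects.  Internal topology (bonds, angles, dihedrals,
1–2/1–3 exclusions, scaled 1–4 pairs) is generated from a name-based
bond template, with distance-based attachment for unknown atom names.
Bond and angle equilibria are taken from the geometry the heme was built
or read with — a knowledge-based native reference — and each dihedral's
phase is chosen so that the reference geometry is a torsional minimum.
Internal units are nm / kJ/mol / radians / amu; PDB I/O converts Å↔nm.

## Coupling Hamiltonian

The heme b–protein coupling is the six-term sum described in the README.
Notable conventions, all of which are open switches or documented
choices:

- **Fe coordination radial factor.**  The distance factor is implemented
  as the bounded Gaussian `exp(−(r − r0)²)` paired with a negative
  coupling constant λ (an attractive well).  A growing exponential
  (`fe_cc.exponent_sign: +1`) is also available for comparison, but it
  is unbounded with separation and cannot restrain a distance.
- **Angular gate units.**  All angles are radians, including the "−6"
  offset inside the backbone hydrogen-bond gate
  `(tanh(4(θ − θ0) − 6) + 1)/2`, which therefore opens ~1.5 rad above
  θ0; with θ0 = π/2 the gate selects near-linear N–H…O geometries.
- **Eligibility.**  The Fe term and both hydrogen-bond terms run over
  interior residues only (2…N−1) and skip glycine wherever Cβ is
  required.  The excluded-volume term runs over *all* protein beads
  (Cα, Cβ, O), not just Cβ.
- **Truncation.**  The narrow `exp(−4(r−r0)²)` terms (both hydrogen
  bonds, thioester) are truncated at 2.0 nm pair distance, where their
  magnitude is below e^{−4·1.3²} ≈ 10⁻³ of the well depth.  The Fe
  coordination term has an ~1 nm-wide radial factor and is evaluated in
  full, as are electrostatics, burial and excluded volume.  At the
  system sizes this package targets (tens of residues plus one heme),
  full pair evaluation is cheaper than neighbour-list bookkeeping.
- **Heme c attachment.**  The thioester term requires exactly one CXXC
  motif (cysteines separated by two residues); it is auto-detected and
  overridable.  Asking for the term on heme b is a hard error.
- **Distal ligand.**  An occupied axial face is modelled as an angular
  mask: residues approaching the blocked face (sign of (Cβ−Fe)·n̂ equal
  to the blocked face) are removed from the Fe coordination sum.

### Parameter values

The coupling constants ship in `data/default_params.yaml` and were
curated on physical grounds: the screened electrostatics uses the
aqueous Coulomb prefactor (138.935/80 kJ·nm/mol/e²) with a 1 nm Debye
length; sidechain–carboxylate wells are a few kJ/mol on polar donors
and −6 kJ/mol on Lys/Arg (propionate salt bridges); and the two
covalent-anchor terms are parameterized at covalent-bond energy scale —
the Fe–His well reaches ≈ −270 kJ/mol at the coordination optimum and
each thioester tether ≈ −100 to −400 kJ/mol near contact — because
these terms stand in for genuine chemical bonds, not van der Waals
contacts.  The angular-gate threshold θ0 = 0.7 rad keeps a clear axial
preference while accepting approaches within ~40° of the ring normal.
The burial (desolvation) coupling is 100 kJ/mol: its printed 1/(4N)
normalization dilutes it by the protein size, so a three-digit λ is
what yields a physically sensible ~kT-scale penalty per buried
carboxylate contact at N ≈ 30.  Every value is overridable and the
loader refuses to run with missing keys.

The heme partial charges are a curated set summing exactly to the
declared formal charge (−2, deprotonated propionates); per-element LJ
parameters are conventional.  The intra-heme 1–4 LJ scale is set to 0.2
(softer than the common 0.5) because the idealized porphyrin skeleton
has short 1–4 distances across the meso bridges and carries none of the
aromatic-system exclusions a full all-atom topology would; the 1–4
Coulomb scale is the usual 5/6.  The LJ potential is linearized below
0.8σ so that transient overlaps at 800 K produce a bounded force — this
clamp is part of the term's definition and is mirrored by the test
oracles.

## Protein stand-in potential

The transferable coarse-grained protein forcefield this model would
normally ride on is out of scope here; in its place the protein is held
by a structure-based single-memory potential: Gaussian wells (depth
ε = 1.1 kJ/mol, width 0.1 nm) on every native Cα–Cα and Cβ–Cβ distance
with sequence separation ≥ 3 and native distance ≤ 1.2 nm, harmonic
chain-connectivity bonds (Cα–Cα, Cα–Cβ, Cα–O, O–Cα′) at native lengths,
and a chirality restraint on the signed triple product
[(Cα_i−Cα_{i−1})×(Cα_{i+1}−Cα_i)]·(Cβ_i−Cα_i).  The native structure is
the exact global minimum by construction.  The well width 0.1 nm trades
funnel sharpness for folding kinetics at desk-scale run lengths; the
depth was chosen so that the 30-residue toy is marginally stable near
300 K, the regime in which cofactor binding can visibly shift the
folding equilibrium.

## Dynamics

BAOAB-discretized Langevin dynamics, timestep 5 fs, in MD units
(kB = 0.008314 kJ/mol/K).  Bead masses lump the residue mass onto the
three beads (56 amu on Cα, 16 on O, sidechain mass on Cβ); heme atoms
use atomic masses.  Annealing ramps the thermostat linearly (default
800 K → 200 K); umbrella sampling holds a fixed temperature and adds
`0.5 k (Q_w − q0)²`, whose force is the analytic chain rule of Q_w over
all Cα pairs.  Trajectories are bitwise reproducible under a fixed seed.

One protocol-level device makes *binding* observable in short runs: a
**flat-bottom COM tether** (radius 2.5 nm in the binding experiments,
50 kJ/mol/nm²) between the heme and protein centres of mass, which
bounds the search volume — equivalently, fixes a high effective
concentration.  It is a restraint on the sampling protocol, not a term
of the model Hamiltonian; it exerts no force on bound or nearby
configurations, and it is applied identically to every condition being
compared.  Production-scale protocols (4×10⁶ steps) reach binding by
brute sampling time; the tether emulates that reachability at desk
scale.

The friction coefficient matters more than it may appear: the thioester
tether switches on over ~0.03 nm, and at weak coupling (γ ≲ 0.1 ps⁻¹)
the integrator pumps energy into that stiff mode faster than the
thermostat removes it, spuriously ejecting even deeply bound pairs.  At
the default γ = 1 ps⁻¹ the bound state is stable indefinitely; do not
lower the friction below ~0.5 ps⁻¹ in systems with engaged covalent
anchors.

## Metrics

Q_w uses the separation-dependent width σ_ij = |j−i|^0.15 measured in
Å (0.1 nm).  In nm the metric saturates — a random coil would score
≈ 0.8 against the native fold — whereas the Å convention reproduces the
standard reading of Q_w ≈ 0.2 for unfolded and ≳ 0.6 for native-like
structures.  Q_c counts residue-level contacts by default (a residue
contacts the heme if *any* heme atom is within 0.65 nm of its Cβ);
atom-pair counting is available (`mode="atom"`).  Residue-level counting
is robust to heme atom-naming differences; glycine can never form a
contact.  Q_c is normalized by the reference structure's contacts and is
therefore deliberately asymmetric in its arguments.  RMSD uses Kabsch
superposition (proper rotations only) with per-residue deviations
available for structure colouring.

## Free-energy surfaces

2D surfaces are −kT ln P histograms (40×40 bins over the observed range
padded 5%), reported in kT relative to the minimum with empty bins
flagged NaN, over any pair of {Q_w, Q_c, energy components}.  Umbrella
windows are recombined with the standard binned self-consistent WHAM
iteration (convergence when window shifts move < 10⁻⁸ kT); neighbouring
windows sharing < 10% histogram mass trigger a warning.  The first 20%
of each window is discarded as equilibration by default.  WHAM is
validated against a Metropolis sampler on the analytic double well
U(q) = a(q² − b)² (a = 64, b = 0.25: wells at ±0.5, 4 kT barrier), where
the reconstruction error over the interior of the sampled range is
≈ 0.05 kT, well inside the 0.2 kT target.

## Toy systems and what they show

The self-contained fixture is a 30-residue helical hairpin (13-residue
helix, glycine-rich loop, 13-residue helix) with the heme docked in the
groove between the helices, so the pocket spans both: the axial His Cβ
sits at the Fe coordination optimum on the ring normal, at least four
residues (in practice 8–9, from both helices) form Q_c contacts, the
pocket is clash-free, and for heme c the ring is spun/tilted so the
vinyl carbons reach the CXXC cysteines at the thioester distance
(sidechain directions of the binding residues are pointed at their
partners — rotamers are free in this representation).  Pocket
chemistry follows the natural families: the heme b toy's pocket is
predominantly hydrophobic around the proximal His (globin-like), while
the heme c toy's second helix is lined with basic/polar residues, as
natural cytochrome pockets coordinate the heme propionates with
lysines.  Pockets are constructed *at the
equilibrium distances of the loaded parameter set*, so energy-minimum
checks remain valid if parameters change.  The extended state is a
self-avoiding random coil reusing the native bond geometry, with the
heme placed ≥ 3 nm from the protein centroid.

The two landscape experiments operationalize the model's central
qualitative claims on this fixture:

- **Binding funnel** (`experiments.binding_funnel`): over matched
  annealing seeds (default 10 per condition, 30,000 steps), the median
  final Q_c with the covalent anchors (V_Fe-cc and, for heme c,
  V_thioester) enabled exceeds the median with them zeroed.  Binding at
  this run length is nucleation-limited, so individual seeds may fail to
  bind; the claim is about the medians.
- **Holo stabilization** (`experiments.holo_stabilization`): Q_w
  umbrella profiles at 300 K (windows q0 = 0.12…0.96 spaced 0.06,
  k = 400 kJ/mol so neighbouring histograms overlap well,
  WHAM-recombined) with the full coupling (holo) and with it switched
  off (apo).  The folded-side basin (Q_w ≥ 0.45) is measured by the
  free-energy rise toward lower Q_w needed to leave it.  Binding
  reproducibly deepens and upshifts the folded-side basin on this toy,
  but the contrast is modest (on the order of 1–2 kT) — see Known
  limitations.

Passing these experiments shows the implemented Hamiltonian funnels
binding and couples binding to folding stability *on a designed toy with
an ideal pocket*.  It does not demonstrate prediction accuracy on real
heme proteins: the toy has a single memory of its own native structure,
an unfrustrated pocket, no competing binding sites, no solvent, and
run lengths orders of magnitude below production protocols.

## Numerical notes

- Analytic forces exist for every term (angle and dihedral gradients by
  the standard vector formulas) and match central finite differences to
  < 10⁻⁴ relative; the virtual-site chain rule and the Q_w bias gradient
  are included in that check.
- The two heaviest terms (protein stand-in, heme internal) are compiled
  with numba; the compiled kernels are transcriptions of the same
  formulas and are tested both against the vectorized reference
  implementations (10⁻⁹) and against the independent naive oracles
  (10⁻¹⁰).
- Angle gradients are floored at sin θ = 10⁻⁶ against collinear
  degeneracy; such configurations carry vanishing weight in every term
  that uses angles.
- Q_c is undefined when the reference has no contacts (raises);
  all-glycine chains yield empty Cβ sums, not errors.
- Empty histogram bins are reported as NaN, never as a finite free
  energy; surfaces are min-shifted over populated bins only.

## Known limitations

- **Binding is only weakly fold-specific on this toy.**  The coupling
  energy of the bound heme is similar in the folded pocket and in a
  compact unfolded chain: the covalent anchors travel with the CXXCH
  segment, and a flexible coil can arrange many of the same polar
  contacts around the heme that the folded groove provides.  The
  holo/apo free-energy contrast along Q_w is therefore modest here
  (roughly 1.5–2 kT of extra folded-basin depth, reproducible across
  seeds) rather than the decisive folded-state stabilization seen for
  real cytochromes, whose buried pockets form contacts a disordered
  chain cannot.  A fixture that *encloses* the cofactor would be needed
  to recover the full effect; a 30-residue two-helix toy cannot wrap a
  1.4 nm disc.
- Heme partial charges are curated, not derived from quantum chemistry;
  redox states, electron transfer and O₂ chemistry are out of scope.
- One protein chain, one heme; no periodic boundary conditions.
- The distal-ligand mask is a binary face selector, discontinuous for a
  residue crossing the ring plane at close range (negligible in
  practice: the term is near zero there).
- The stand-in protein potential is structure-based; results involving
  it probe the coupling terms, not transferable folding prediction.
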