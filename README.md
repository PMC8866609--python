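# hemefold

A hybrid energy model for heme proteins: a coarse-grained protein (three
beads per residue — Cα, Cβ, carbonyl O) coupled to an atomistically
represented heme b or heme c cofactor through knowledge-based interaction
potentials.  The package evaluates the coupled Hamiltonian and its
analytic forces, measures structure quality with the Q_w / Q_c metrics,
predicts structures by Langevin simulated annealing, runs Q_w-biased
umbrella sampling, and builds 1D/2D free-energy surfaces (−kT ln P and
WHAM).

## The model

For heme b, the heme–protein coupling has six terms,

    H_coupling = V_Fe-cc + V_elec + V_hb-backbone + V_hb-sidechain + V_burial + V_excl

and heme c adds a seventh, `V_thioester`, tethering the two vinyl carbons
to the CXXC cysteine pair.  The key terms:

- **V_Fe-cc** — the coordinate-covalent bond between the heme iron and an
  axial His/Met: a Gaussian well on the Cβ–Fe distance gated by
  `∏_j (1 + tanh(2(sin θ_ij − sin θ0)))/2` over the four pyrrole
  nitrogens, which selects residues approaching along the ring normal.
  Terminal residues and glycine are excluded.
- **V_elec** — Debye–Hückel-screened Coulomb coupling between residue
  unit charges (on Cβ) and the heme partial charges.
- **V_hb-backbone / V_hb-sidechain** — hydrogen bonds between the heme
  propionate carboxylates and, respectively, the reconstructed backbone
  N–H groups and polar sidechains.
- **V_burial** — a desolvation penalty for burying the hydrophilic
  carboxylates, `(1 − tanh 8(r − r0)) / 4N`.
- **V_excl** — harmonic excluded volume below 0.35 nm for every protein
  bead / heme atom pair.
- **V_thioester** — `λ_CS e^{−4d²}(1 − tanh 3d)(1 + tanh 32d)`,
  d = r − r0, a short-ranged covalent tether (heme c only).

The heme's internal energy is a conventional bonded + nonbonded
forcefield (harmonic bonds/angles, periodic dihedrals, LJ + Coulomb with
1–2/1–3 exclusions).  The protein itself is held by a structure-based
single-memory potential (Gaussian wells on native pair distances).

Structure quality is scored by

    Q_w = 2/((N−2)(N−3)) Σ_{j−i>2} exp(−(r_ij − r_ij^N)² / 2σ_ij²),  σ_ij = |j−i|^0.15 Å

and the pocket accuracy Q_c = (native heme contacts reproduced) /
(native heme contacts), a contact being any heme atom within 0.65 nm of
a residue's Cβ.

All lengths are nm, energies kJ/mol, angles radians.  Every coupling
constant lives in a YAML parameter file
(`src/hemefold/data/default_params.yaml`); the loader is strict — a
missing key is an error, never a silent default.

## Worked example

Build the self-contained heme c toy system (a 30-residue helical hairpin
with a real pocket: axial His on the ring normal, CXXC clamp on the
vinyl carbons), score it, and run a short annealing prediction:

```bash
hemefold make-toy --type c --seed 1 --out-native native.pdb --out-extended extended.pdb
hemefold energy --pdb native.pdb --native native.pdb
hemefold anneal --pdb extended.pdb --native native.pdb \
    --steps 30000 --tether-radius 2.5 --seed 3 --out traj.npz
hemefold fes --traj traj.npz --x q_w --y q_c --out fes.csv
```

The `energy` call prints the per-term breakdown of the native state
(kJ/mol):

```json
{
  "fe_cc": -273.44,
  "elec": -3.73,
  "hb_backbone": -0.1,
  "hb_sidechain": -31.47,
  "burial": 9.35,
  "excl": 0.0,
  "thioester": -367.0,
  "heme_internal": -6.49,
  "protein_standin": -257.4,
  "total": -930.3
}
```

The two large negative coupling terms are the covalent anchors: the
Fe–His coordinate bond (`fe_cc`) and the two thioester tethers
(`thioester`).  `excl = 0` confirms the constructed pocket is clash-free,
and `protein_standin` is the depth of the structure-based well at the
native fold.  The `anneal` run reports the final and best Q_w/Q_c of the
prediction; with the anchors enabled the heme typically finds the native
pocket (Q_c > 0) as the protein folds, and the `fes` surface over
(Q_w, Q_c) is funneled toward the bound, folded corner.

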