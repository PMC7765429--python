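# Methods

## Scope and model

`dockrf` estimates the binding affinity (pKd) of a rigid protein–ligand
pose with a random-forest regressor over three feature classes:
pharmacophore contact-shell counts (phCo), unweighted AutoDock Vina energy
terms, and solvent-accessible-surface-area (SASA) desolvation features.
The package covers featurization, model training/validation/persistence,
metric evaluation, pose-set rescoring and a synthetic fixture generator;
it does not perform docking, structure preparation or protonation
assignment, and no licensed affinity corpus is shipped — users holding
such data can train and evaluate on it through the same interfaces.

## Structure model and typing

Structures are typed atom lists with bonds. mol2 SYBYL types are trusted
as given. PDBQT atoms are mapped from their AutoDock types (A → C.ar,
OA → O.3, …); PDB atoms are typed from element plus connectivity after
distance-based bond perception (covalent-radius sum × 1.25). The PDB
fallback is heuristic by design: aromaticity is approximated by
membership in a 5/6-ring whose members have ≤ 3 heavy neighbours,
carbonyl/carboxylate oxygens by terminal-oxygen patterns. Receptors are
stripped of waters and non-"A" alternate locations by default; metal
ions are kept as isolated single-atom entries (they carry the MI label
and Vina's metal radius). Coordinates are Å; indices are 0-based in
memory and 1-based in files.

Pharmacophore labels (P, N, DA, D, A, AR, H, PL, HA + MI) come from an
ordered rule table shipped as a plain-text resource
(`data/pharmacophore_rules.txt`) so it can be audited or extended. Rules
are scanned top to bottom, first match wins; the table is ordered from
specific to generic (carboxylate-like oxygen rules precede the generic
oxygen-acceptor rule). Required-neighbour clauses use at-least-count
semantics and count the bond back to the parent when nested (the only
reading under which carboxylate, phosphate and sulfonate oxygens match
their patterns); forbidden clauses ignore the parent bond. The printed
polar-carbon pattern is implemented as "carbon bonded to at least one of
N/O/F/P/S", the complement of the hydrophobic-carbon rule. Hydrogens are
not independently labelled. When a molecule carries no explicit
hydrogens, hydrogen-dependent patterns fall back to an implied-hydrogen
count (expected SYBYL connectivity minus observed degree); consequence:
a pyrrole-type N.ar without explicit H types as acceptor rather than
donor. Unmatched heavy atoms (B, Se, …) fall back to PL with a logged
warning. The MI label is assigned to isolated ions of the common
biometals; a 9-type mode without MI is a configuration switch
(feature vector 729 + 6 + 3).

## Contact shells

Shell i (1-based) spans `[i·d − d + d0, i·d + d0)`, half-open so the
shells partition the sampled range exactly; defaults d = 2 Å, d0 = 1 Å,
9 shells (outer bound 19 Å). Pairs closer than d0 are unphysical clashes
and fall in no shell (logged, not clamped). Pair search uses a KD-tree
(scipy cKDTree); the test suite asserts bin-for-bin equality with the
exhaustive O(N·M) loop, rigid-transform invariance and the partition
property. Bin order is protein label major, ligand label middle, shell
minor, with self-describing names `P<label>_L<label>_S<shell>`; models
persist the schema hash and refuse mismatched inputs.

## SASA

Accessible areas use Lee–Richards slicing of the probe-expanded spheres
(probe 1.4 Å, van der Waals radii from a Bondi-style table shipped as a
resource; unknown elements raise rather than default). Each atom's
sphere is cut into slabs of at most 0.25 Å; within a slab the accessible
fraction of the circle of intersection is obtained by merging the
angular intervals covered by neighbouring circles, and the slab area is
the Archimedes zone area 2πR·Δz. The arc profile is integrated with
3-point Gauss–Legendre quadrature per slab, which keeps the default slab
width accurate (generic two-sphere geometries agree with the spherical-
cap closed form to ≲ 0.2%; exactly axis-aligned sphere pairs are the
worst case because the coverage profile is discontinuous there, and the
tests use fine slicing for that configuration). Hydrogens are excluded
by default, as is conventional; N, O and S surface counts as polar.

Desolvation features: ΔSASA_protein = SASA(apo) − SASA(protein in
complex) with the same coordinates (rigid receptor — conformational
relaxation is out of scope), ΔSASA_ligand likewise for the free versus
bound ligand, and CSA = (buried_protein + buried_ligand)/2 where buried
surface is each partner's total (polar + apolar) SASA loss.

## Vina terms

The five unweighted terms are functions of the surface distance
d = r − (r_a + r_b) with Vina atom-type radii (resource table, metals at
the metal-donor radius 1.2 Å): gauss1 = exp(−(d/0.5)²),
gauss2 = exp(−((d−3)/2)²), repulsion = d² for d < 0,
hydrophobic = linear ramp 1→0 over d ∈ [0.5, 1.5] for hydrophobic–
hydrophobic pairs, hbond = ramp 1→0 over d ∈ [−0.7, 0] for donor–
acceptor pairs; all summed over intermolecular heavy-atom pairs within
8 Å. All parameters live in an auditable config block. Pair eligibility
derives from the pharmacophore labels (H, and AR on carbon, are
hydrophobic; D/DA donate; A/DA accept); metal–acceptor coordination is
therefore not counted in the H-bond term, a deliberate simplification.
Intra-ligand contributions and Vina's weighted total (including its
rotatable-bond normalisation) are out of scope — only unweighted terms
are features. The sixth feature is the rotatable-bond count: the PDBQT
TORSDOF record when present, else acyclic non-terminal heavy-atom single
bonds excluding amide-like C–N bonds.

## Features, model, metrics

The raw vector is `[phCo | Vina | SASA]` = 900 + 6 + 3 = 909 entries by
default; class subsets support ablation studies. Zero-variance columns
(in practice contact bins never observed in the training data) are
dropped by a mask fit on the training partition only and persisted with
the model, together with the schema hash and seed; SVM and LR presets
additionally standardise features with statistics fit on the training
partition. The default regressor is a random forest with 500 trees,
`max_features = 0.33`, and out-of-bag scoring; presets RF100
(100 trees), SVM (RBF kernel), LR and KNN (k = 10) reproduce the usual
comparison baselines. k-fold cross-validation (default ten-fold) refits
the mask and scaler per fold. A small randomised hyperparameter search
over an artifact-chosen grid is provided for convenience.

Affinity labels are pKd; Kd/Ki (molar) convert as −log₁₀, IC50 is
accepted as a surrogate, and values with inequality qualifiers are
excluded. Metrics follow the CASF conventions: Pearson R; MAE; RMSE
(the standard root-mean-square form — the MAE ≤ RMSE inequality and the
CASF definition fix this reading); and SD = √(Σc²/(N−1)) with
c_i = (a·pred_i + b) − exp_i, where (a, b) regress the experimental
values on the predictions (SD is therefore invariant to affine changes
of the predictions). Both statistics are cross-checked against
independent implementations in the tests.

## Synthetic study set

The generator emulates what the featurizers actually consume — typed
atoms, bonds, coordinates — not protein topology. Receptor and ligand
are atom clouds packed at protein-like heavy-atom density
(0.04 atoms/Å³) with ≥ 1.5 Å separation between non-bonded sites;
bonded motifs (hydroxyl/amide/thiol hydrogens, quaternary amines,
planar carboxylate triads) are added only where typing patterns need
neighbours, with extra clearance for motifs whose pendant atoms extend
beyond their site. The ligand cloud centre sits ~1 ± 1 Å outside the
receptor surface, like a surface-bound pose, which populates the short
contact shells. Defaults: 500 complexes, receptors of 40–80 heavy
atoms, ligands of 8–16.

Labels are pKd = 2.5 + Σ w·x + ε, clipped to [0, 16], with a sparse
signal on short/medium-range hydrophobic, aromatic and donor–acceptor
contact bins plus CSA, and ε ~ N(0, 0.35 pKd). The weights were sized
once from the generator's feature scales so labels span roughly pKd
3–10 with a standard deviation near 2, mimicking the range that
dominates experimental affinity data. Because the signal is a sparse
linear function with known noise, recovery has an analytic ceiling
(R ≈ 0.98 at the default signal-to-noise), which grounds the
parameter-recovery checks (default RF reaches held-out R ≥ 0.9 at
n = 500; label shuffling drives R to ~0).

What passing these tests does **not** show: performance on real
complexes. The clouds have no secondary structure, no realistic ligand
chemistry or conformational strain, labels are exactly (sparse-)linear
in the features, and poses are never wrong — so the tests validate the
machinery (featurization correctness, leakage-free training,
reproducibility), not the published benchmark accuracy, which requires
the licensed PDBBind/CASF corpora.

## Numerical and interface choices

- Shell intervals half-open; boundary pairs belong to the outer of the
  two adjacent shells' shared edge (lower edge inclusive).
- SASA slab width ≤ 0.25 Å, 3-point Gauss per slab; per-atom slab grids
  are anchored to the atom centre, so areas are exactly
  translation-invariant.
- mol2 output carries 4-decimal coordinates (the format's convention);
  integer contact features survive a write/read round trip exactly,
  continuous features to ~1e-3 Å² — the round-trip tests assert exactly
  that. The ligand TORSDOF is recorded in the fixture label table since
  mol2 has no such record.
- Determinism: a single integer seed fixes generation, training
  (forest bootstrap) and fold assignment; identical seeds give
  byte-identical feature matrices and identical predictions.
- Degenerate inputs error early: empty (water-only) structures,
  all-constant feature matrices, constant label vectors, constant
  vectors in correlation, mismatched pose atom counts, unknown element
  radii.

## Known limitations

- The PDB typing fallback is heuristic; supplying mol2 (or PDBQT with
  AutoDock types) gives better-defined labels.
- Implied-hydrogen typing cannot distinguish pyridine- from
  pyrrole-type aromatic nitrogen without explicit hydrogens.
- The SASA integrator's worst case (exactly collinear sphere pairs
  aligned with the slicing axis) converges only linearly in slab width.
- The H-bond term ignores geometry (angles) and metal coordination,
  matching the unweighted-term definition, not a full physical model.
- Explicit hydrogens in the synthetic clouds are placed at 1.0 Å from
  their parent without steric checks against other sites; they are
  invisible to all heavy-atom featurizers.
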