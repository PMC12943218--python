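# Methods

This note documents the models and procedures implemented in flavoscreen,
the parameters that matter, the design decisions taken where the underlying
protocol left choices open, and what the synthetic-data generators do and do
not emulate.

## Structures and file formats

PDB parsing is fixed-column per the wwPDB format. Alternate locations keep
only altLoc ' ' or 'A'; waters (HOH/WAT and variants) are dropped. HETATM
records whose residue name is not one of the 20 standard amino acids become
ligand atoms — this matches a preparation protocol in which waters and
heteroatoms are stripped before docking, so any remaining HETATM is the
docked ligand. Multi-MODEL files become trajectories whose topology is the
first model; frames store protein atoms first, ligand atoms last, so frame
indices are stable across modules.

PDBQT parsing understands the Vina output dialect: one MODEL per pose, a
`REMARK VINA RESULT:` record whose first numeric field is the affinity
(kcal/mol). Partial charges and AutoDock atom types are parsed and retained
for losslessness but are not used by the profiler (docked poses cannot be
assumed to carry hydrogens or reliable charges). Pose selection takes the
minimum affinity; ties break toward the lower rank, i.e. Vina's own
ordering.

All coordinates are Ångström end to end; metric series offer an explicit
nm conversion for GROMACS-style plots rather than converting silently.

## Interaction classifier

The classifier is purely geometric. Defaults: H-bond 3.5 Å between ligand
N/O and protein N/O; hydrophobic 4.0 Å between ligand carbons and side-chain
carbons of PHE, TRP, TYR, LEU, ILE, VAL, ALA, MET, PRO; π-stacking 5.5 Å
between any heavy ligand atom and the ring atoms of PHE/TRP/TYR (fixed name
lists; the TYR hydroxyl oxygen is not a ring atom). Choices made where the
protocol was ambiguous:

- **Cutoffs are inclusive (≤).** "Within X Å" reads naturally as ≤; boundary
  tests pin the behavior.
- **Two H-bond modes.** The default is distance-only. Angle mode adds the
  common visualization-software criterion (donor–H⋯acceptor ≥ 120°) but only
  when an explicit hydrogen is covalently attached (≤ 1.3 Å) to one partner;
  pairs without hydrogens fall back to distance so that hydrogen-free docked
  poses remain analyzable. The two criteria are deliberately kept as
  separate documented modes instead of being merged.
- **Hydrophobic contacts pair carbons with side-chain carbons** (backbone
  N/CA/C/O/OXT excluded). Counting polar atoms as "hydrophobic contacts"
  would be a category error, and CA belongs to the backbone.
- **π-stacking has a literal mode (any ligand atom) and a strict mode
  (ligand atom flagged aromatic).** Neither applies a ring-plane angle test;
  a proximity criterion at 5.5 Å is already generous and an angle test would
  be a different method, not a parameter.

Residues are reported once per interaction type as NAME+number (ASN458),
sorted by (chain, number). `check_reference_interactions` validates a pose
against a known binding mode, e.g. the crystallographic apigenin anchors
ASN458/TRP459 on GLUT9.

The profiler is tested against an independent brute-force all-pairs scan,
for cutoff monotonicity, for invariance under global rigid motions, and for
exact recovery of generator-planted profiles.

## ADMET rules

Descriptors come from RDKit on canonical SMILES: MolWt, Crippen MolLogP,
Lipinski NHOH/NO counts (the original rule-of-five donor/acceptor
definitions: HBD = O–H plus N–H groups, HBA = N plus O atoms), Ertl TPSA,
and the standard rotatable-bond count (non-ring single bonds between
non-terminal heavy atoms, amides excluded). Formula masses use IUPAC 2021
standard atomic weights, rounded only at presentation (2 decimals).

The rule engine counts strict-inequality violations of MW ≤ 500, LogP ≤ 5,
HBD ≤ 5, HBA ≤ 10. The pass flag is `violations == 0`: the screening table
being reproduced labels a one-violation compound "No (1)", although the
classic formulation tolerates one violation. Both the count and the flag are
reported so either convention is recoverable. GI absorption is High iff
TPSA ≤ 140 Å²; BBB is Yes iff TPSA ≤ 90 Å² and MW ≤ 450 — all boundaries
inclusive on the passing side. Rotatable-bond counts are a soft check only:
definitions vary between toolkits, so no verdict depends on them.

## Reactivity descriptors

Koopmans' theorem maps frontier-orbital energies to global reactivity
indices: I = −E(HOMO), A = −E(LUMO), χ = (I+A)/2, η = (I−A)/2, S = 1/(2η),
ω = χ²/(2η), ΔE = E(LUMO) − E(HOMO). These identities hold to machine
precision by construction and are property-tested as such. A degenerate gap
(η = 0) makes S and ω undefined and raises an explicit error. Inputs are eV;
Hartree values pass through `hartree_to_ev` with the CODATA factor
27.211386 (the underlying protocol does not state its constant; CODATA is
adopted). Quantum-chemistry ingestion is a documented key–value CSV
(compound, e_homo_ev, e_lumo_ev, dipole_debye, total_energy_hartree); full
DFT-log parsing is out of scope because log formats drift across program
versions. Table output rounds to 4 decimals at presentation only.

The package embeds the published B3LYP/6-31G(d) orbital energies of EGCG,
chrysin, and apigenin as reference inputs; `scripts/acceptance.py`
recomputes the derived rows from them at run time.

## MD metrics

- **Superposition** is closed-form Kabsch (SVD with reflection correction);
  rank-deficient (collinear) configurations are rejected rather than
  silently fitted.
- **RMSD** uses frame 0 as the reference (the analyzed trajectories start
  near equilibrium, and a first-frame reference keeps the series
  interpretable as drift from the docked pose). Selection defaults to
  backbone N/CA/C/O, falling back to all protein atoms for toy topologies
  without backbone names.
- **RMSF** measures fluctuation about the mean structure. The initial
  alignment reference is the raw coordinate mean — not frame 0 — which makes
  the profile exactly invariant under frame reordering; one refinement pass
  re-aligns to the aligned mean. Selection defaults to one Cα per residue.
  Note that the rigid fit absorbs a small share of per-atom motion, so the
  measured RMSF of iid isotropic jitter sits slightly below the closed form
  √3·σ (about 2 % low at 50 atoms); tests use a 5 % band.
- **H-bond counts** re-use the profiler's distance criterion frame-wise, so
  the trajectory metric and the static profile cannot disagree by
  construction.
- **SASA** is Shrake–Rupley: each atom's sphere is expanded by the probe
  radius (1.4 Å water probe) and sampled with a golden-angle spiral
  (960 points by default; well under 1 % from the 10000-point value on toy
  clusters); a point is accessible if outside every other expanded sphere.
  Radii are the Bondi set; unknown elements raise by name rather than
  defaulting.

No simulation engine is wrapped: the module analyzes trajectories, it does
not produce them. XTC/TRR ingestion is not core; multi-model PDB is.

## Assay analysis

Activity is 100·(A_control − A_sample)/A_control. The 4PL model is
y = d + (a−d)/(1 + (x/c)^b) with a the zero-dose response and d the plateau.
Fits are bounded least squares (scipy `curve_fit`) from five deterministic
starts (slope/center variations on the data range); the best SSE wins.
Bounds: b ∈ [0.1, 20], c ∈ [0.01·x_min, 100·x_max], asymptotes within the
data range ± 50 %. Flat data (activity range < 1 %) is rejected as
degenerate rather than fitted.

The IC50 is the 50 %-crossing of the fitted curve, solved analytically as
x = c·((a−d)/(50−d) − 1)^(1/b) — identical to c under 0/100 asymptotes and
verified against numerical root-finding to 1e−9. Replicates are fitted
pooled; the reported IC50 SD is the standard deviation of per-replicate
refits, matching a mean ± SD (n = 3) reporting convention. (Whether such SDs
come from refits or from the fit covariance is generally unstated in assay
write-ups; refits are the choice here and are what the generator's noise
model calibrates against.)

FRAP calibration is OLS through (Trolox concentration, absorbance)
standards; the sample TE concentration inverts the line and divides by an
explicit `mass_factor` (grams of sample per reaction) because per-gram
conversion factors are protocol-specific and should never be implicit.

Group comparison is one-way ANOVA (scipy `f_oneway`) with Tukey HSD
(`tukey_hsd`, studentized-range adjusted p), flagged at 0.05 and 0.001. The
type-I error of the full path is calibration-tested at 0.05 ± 0.02 over
2000 null simulations.

## Synthetic data: what it emulates, what it does not

The generators reproduce the study *design*, with exact ground truth:

- **Planted complexes**: each requested contact is built in its own region
  25 Å from the next (far beyond every cutoff), using correct residue atom
  names (ASN CB/OD1/ND2; PHE ring hexagon at 1.39 Å radius; LEU CD1) at
  exact target distances — H-bond plants default to 3.0 Å, π plants to
  5.0 Å (outside the hydrophobic cutoff so types stay clean; a π plant
  placed ≤ 4.0 Å is honestly added to the expected hydrophobic list),
  hydrophobic plants to 3.5 Å. Decoy residues sit ~1000 Å away.
- **Jitter trajectories**: iid isotropic Gaussian noise around a reference,
  5000 frames by default at 20 ps spacing (a 100 ns production run sampled
  at regular intervals). An optional planted H-bond pins one polar
  ligand/protein pair at 3.0 Å in exactly round(f·n) seeded-chosen frames
  and 30 Å otherwise, making the mean H-bond count exact by construction.
- **Dose–response**: the six assay concentrations (3.125–100 μM) in
  triplicate, 4PL truth plus Gaussian noise (default calibration scenario:
  σ = 2 % activity). Trolox standards are points on a stated line plus
  noise.

Every generator is a pure function of (arguments, seed). What the synthetic
data does **not** emulate: correlated protein motions (jitter is iid, so
RMSF is flat by design where real profiles show loop/core structure),
docking-score physics, non-Gaussian plate-reader error, or assay-specific
systematic effects (path-length, solvent quenching). Passing the synthetic
round-trips therefore demonstrates the *analysis* code is correct under the
stated noise model, not that the upstream science is reproduced.

## Problem sizes and numerics

Default test and calibration sizes are chosen to be statistically
meaningful at desk scale: oracle equivalence on complexes of ≤ 200 atoms;
planted-profile recovery over 50+ seeded specs; RMSF closed-form checks at
5000 frames × 50 atoms; IC50 recovery over 200 seeded datasets; ANOVA
calibration over 2000 null datasets. Quartiles use linear interpolation
(numpy default). Ties in pose selection break by rank; ties in residue
ordering cannot occur because (chain, number) is unique.

## Known limitations

- The profiler has no salt-bridge, halogen-bond, or cation-π classes and
  does not score interaction strength.
- Whether the original contact script measured hydrophobic distances to all
  residue atoms or carbons only, and π distances to ring atoms or any
  residue atom, cannot be determined from the published residue lists alone;
  both behaviors are switchable (mode flags) and neither is asserted as
  ground truth.
- Published absolute RMSD/SASA magnitudes and assay IC50s depend on
  un-deposited trajectories and raw absorbances; they are validated here
  through synthetic recovery, not value reproduction.
- ADMET is the stated rule set only — no metabolism, clearance, hERG, or
  ML-based prediction, and no attempt to replicate external ADMET servers
  beyond those rules.
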