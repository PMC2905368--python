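# Methods

This note documents the models, conventions and numerical choices behind
`zfdock`, in the spirit of a software methods section: what is computed, what
is assumed, and where the design was genuinely open.

## Scope and division of labour

The package covers everything *around* a data-driven docking engine for
three-finger Cys₂His₂ zinc-finger–DNA complexes: restraint construction and
vetting, canonical B-DNA construction, and evaluation of docked models.  It
deliberately does not dock: no force field, no electrostatics/van der
Waals/desolvation energies (those are parsed from engine output, never
recomputed), no flexible refinement.  The flowchart is
select AIRs → prescreen geometry → (external docking) → evaluate ensemble,
with back-loops from prescreen failure and from a poor ensemble back to
restraint selection.

## Structure model

Coordinates live in a chain → residue → atom hierarchy with 1-based PDB
numbering (closed intervals for ranges).  Each chain has a single role,
protein or DNA.  PDB I/O is delegated to gemmi; on reading, alternate
locations collapse to the highest-occupancy conformer (tie → first
encountered), only model 1 of multi-model files is taken, and HETATM records
(zinc ions) are retained as annotations but excluded from every metric, as
are hydrogens — all metrics are heavy-atom metrics.

Zinc fingers are detected on sequence with the C-x(2,4)-C-x(12)-H-x(3,5)-H
motif.  The recognition helix is anchored at the second zinc-ligating Cys:
helix position +1 = Cys₂ + 7, so canonical position −1 (the RSD-motif
arginine in classical fingers) is Cys₂ + 6.  This offset reproduces the
canonical positions of all three Zif268 fingers (−1 at residues 18/46/74)
and is configurable for unusual architectures.  Positions −1, +1, +2, +3,
+5, +6 are mapped; the helix is taken to run to the second His.

## Canonical B-DNA

Duplexes are built by propagating a base-pair frame along the global z axis
with fixed twist (36.0°/step) and rise (3.38 Å/step) — the classical fiber
values for B-DNA; both are configurable, with no sequence dependence, since
the construction is deliberately canonical.

Nucleotide geometry comes from the ideal chemical-component coordinates
bundled with biotite (heavy atoms only, terminal OP3 dropped).  Each base is
placed rigidly into the pair frame under three constraints applied in order:

1. **C1′ exactly on its frame target** (0, 5.346, 0).  The strand-2 partner
   is generated by the dyad (x, −y, −z), so the paired-C1′ midpoint is the
   frame origin and the z axis is the *exact* helical axis of every built
   duplex.  This departs from the fiber-model x-displacement of real B-DNA;
   it is a deliberate convention that gives the axis-fitting and projection
   code a bit-exact ground truth.
2. **Pairing calibration.**  The base face (ring-normal sign) and a small
   in-plane rotation about the fixed C1′ are selected by a deterministic grid
   search so the central Watson–Crick hydrogen-bond atoms (purine N1,
   pyrimidine N3) meet at 2.9 Å without steric overlap of the paired bases.
3. **Backbone calibration.**  The glycosidic torsion (sugar–phosphate
   rotation about the C1′–N bond) is set, again by deterministic grid search,
   to bring O3′ of one step close to P of the next (bonded continuity target
   1.6 Å) without stacking clashes, using the default twist/rise as the
   calibration geometry.

The result is a chemically sensible, clash-free, all-heavy-atom duplex whose
measured step parameters reproduce the requested twist to < 0.5° and rise to
< 0.05 Å for arbitrary sequences.  It is a geometric scaffold for restraint
design and metric evaluation, not a refined force-field model; minor
backbone strain at purine/pyrimidine junctions (closest non-bonded approach
≈ 2 Å) is accepted.

Step parameters are measured from the duplex itself: rise as the axial
separation of successive paired-C1′ midpoints along the least-squares axis,
twist as the signed rotation of the C1′–C1′ vector about it.  A step whose
rise exceeds 1.5× the median is flagged as a gap (e.g. a deleted base pair).

## Restraints

The effective distance uses the plain r⁻⁶ sum over heavy-atom cross pairs
with no 1/(N_atoms·N_res) normalisation: the pure sum preserves
d_eff ≤ min pairwise distance, which the violation analysis relies on (a
satisfied restraint means at least one genuine atomic contact).  The
exponent is configurable for sensitivity checks.  Restraint energy is a
flat-bottom harmonic, E_AIR = k·Σ max(0, d_eff − bound)², additive over
restraints; k defaults to 50 kcal·mol⁻¹·Å⁻², the usual engine convention.
Because engines may normalise d_eff differently and weight E_AIR inside
their scores, E_AIR values here support internal comparisons (satisfied
vs violated, population splits), not cross-engine numeric parity.

Pairwise mode restrains one residue against one base (whole-residue
heavy-atom selections — restraints act on residues and bases, not named
atoms).  Non-pairwise mode adds passive selections: surface neighbours
within 6.5 Å (heavy-atom minimum distance) of an active residue with
relative solvent accessibility ≥ 15 %.  Relative accessibility is the
residue's SASA in context divided by its SASA computed in isolation with the
identical algorithm — self-consistent, with no external reference table.

The two-per-finger selector splits each finger's candidate interactions at
the recognition-helix midpoint and takes the candidate closest to position
−1 from the N-terminal half and the candidate closest to position +6 from
the C-terminal half (ties toward the smaller residue number).  A finger
whose candidates all fall on one half cannot anchor both helix ends and
raises the workflow back-loop error.

Restraint tables are CNS-style `assign` blocks with the distance triple
`d d⁻ d⁺ = 2.0 2.0 0.0` (only separations beyond the bound are penalised)
and structured comments carrying the finger index and active/passive split,
making write→read a lossless round trip.  Output is byte-stable.  Random
deletion of restraint subsets is not implemented anywhere: all restraints
are always in force.

## Axis geometry and balance

The DNA helix axis is the least-squares 3-D line through paired-C1′
midpoints, oriented 5′→3′ along strand 1; the azimuth reference vector is
the perpendicular component of (first midpoint → first-strand C1′), an
arbitrary but fixed convention.  Only the restraint *residues* are projected
(their Cα), one dot per AIR.

A set is balanced when (a) every finger carries the same number of AIRs,
(b) no dot deviates from its finger's circular-mean azimuth by more than the
cluster halfwidth (default 60°), and (c) the set's total azimuthal span
(360° minus the largest gap) reaches the minimum span (default 120°) —
a set confined to one side of the DNA cannot pull the protein around it.
The two thresholds are not physical constants; they were chosen once so that
well-spread two-per-finger sets pass while sets with a finger rotated far
out of its cluster, or confined to one DNA side, fail, and both are exposed
in configuration.

## Model evaluation

* **Contacts**: residue–nucleotide pairs with any heavy-atom distance
  ≤ 5.0 Å.  F_nat = |model ∩ reference contacts| / |reference contacts|;
  hydrogen-bonded and non-bonded contacts are counted identically under the
  single distance criterion.
* **Superposition**: closed-form least-squares rotation (Kabsch SVD with
  determinant guard; the McLachlan solution coincides).  Collinear point
  sets are rejected.
* **iRMSD**: interface = reference residues/nucleotides with any heavy atom
  within 10 Å of the partner (the community convention for interface
  definition); the shared heavy atoms are superposed and the RMSD reported.
* **SASA**: Shrake–Rupley with a deterministic golden-spiral sphere of 960
  points per atom, probe 1.4 Å, radii C 1.70, N 1.55, O 1.52, P 1.80,
  S 1.80 Å.  BSA = SASA(protein) + SASA(DNA) − SASA(complex).  Comparisons
  with areas from other programs carry ±2 % algorithm tolerance.
* **Wrap-around**: traditionally judged by visual inspection; here it is
  operationalised.  Interface protein residues (in
  contact at 5 Å) are projected about the DNA axis; coverage is the extent
  of the occupied azimuthal arc after bridging gaps narrower than 120°, and
  a model wraps when coverage ≥ 180° *and* all three fingers touch the DNA.
  Both thresholds are configuration, and the classifier always reports the
  coverage so borderline models can be audited.
* **Scores**: engine scores are parsed (a `file.list` of
  `"model.pdb" { score }` entries, or `key=value` REMARK lines); missing
  components stay absent.  Re-ranking uses a weighted component sum
  (defaults 0.2·E_vdw + 1.0·E_elec + 1.0·E_desolv + 0.1·E_AIR, BSA
  unweighted), ascending, stable under ties; the 10 best models are analysed
  by default.  When no engine scores exist the ensemble is ranked by E_AIR,
  flagged as `recomputed(e_air)`.
* **Populations**: E_AIR values are clustered in 1-D by splitting the sorted
  values at gaps > 25 kcal·mol⁻¹ — crude but deterministic, and sufficient
  to separate "restraints satisfied" from "restraints violated" modes, which
  sit orders of magnitude apart.
* **Back-loop**: the evaluation warns (exit code 1) when the wrap-around
  fraction and the low-E_AIR population fraction are both below 50 %.  The
  50 % default is a judgment call exposed in configuration, not a derived
  constant.

## Synthetic fixtures

The generators emulate exactly the geometric features the metrics measure,
and nothing else.  A "finger" is a mini-helix of eight pseudo-residues
(CA/CB/CG stub plus a tip oxygen) placed at a prescribed azimuth around a
built B-DNA duplex, tracking the axis with a 5°/residue azimuthal slope; the
tip atom sits 1.9 Å from its nearest DNA heavy atom, which guarantees both a
5 Å contact and a satisfied 2 Å restraint on the generating geometry (d_eff
≤ minimum distance ≤ 1.9 Å).  Rotating one finger about the DNA axis by
≥ 120° produces the canonical mismatched decoy: coverage drops below 180°,
the finger's restraints are violated, and native contacts are lost.  All
generators are seed-deterministic (byte-identical PDB output for a fixed
seed).

What the fixtures do *not* emulate: real side-chain chemistry, hydrogen
bonding, protein fold stability, DNA deformation, or engine sampling noise.
Tests passing on fixtures therefore validate the geometry and bookkeeping of
the metrics — not the accuracy of any docking engine, and not biological
recognition specificity.

## Problem sizes and determinism

Default study conditions: 12-bp duplexes (the Sp1 consensus site
5′-AGGGGCGGGGCC-3′), three fingers, ensembles of tens of models in tests and
the 1000 → 20 % → 200 convention as the bookkeeping default for real runs.
Property tests use 20 seeded replicates (classifier, B-DNA round trip) and
brute-force oracles on ≤ 50-atom random sets.  Every stochastic element
(coordinate noise, decoy choice, random sequences) is driven by an explicit
seed; the template calibrations are grid searches with no randomness.

## Known limitations

* The B-DNA backbone is rigid-template based; it is not suitable as a
  starting point for force-field refinement without minimisation.
* Balance and wrap-around thresholds are conventions; borderline geometries
  (coverage near 180°, clusters near 60° halfwidth) deserve visual review.
* E_AIR is comparable only within one restraint definition; no attempt is
  made to match engine-internal energies numerically.
* Interface residue lists for published complexes depend on the original
  model coordinates; without those models, only protocol constants and
  set sizes are reproduced exactly, while metric behaviour is validated on
  synthetic ground truth.
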