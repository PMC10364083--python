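# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the limitations a user should keep in mind.

## Coordinate model

Structures are orthogonal-Å coordinate sets grouped into residues and chains,
backed by biotite `AtomArray`s; ensembles are ordered lists of
topology-identical frames (multi-model PDB). No periodic imaging is applied:
ensembles are assumed whole-molecule and pre-imaged, so `CRYST1` is ignored.
Alternate locations are resolved at read time (highest occupancy by default,
ties to first occurrence); residue insertion codes are rejected outright
rather than silently merged, because downstream stages key residues by
(chain, sequence number). Hydrogens are preserved on read — disulfide
formation and hydrogen-bond detection need them — and can be stripped by
flag.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral (Fibonacci) lattice instead
of random sphere sampling: results are exactly reproducible without seeds and
converge as ~1/n in the point count. Defaults: Bondi van der Waals radii
keyed by element, probe 1.4 Å, 960 points (≲1% error against the
isolated-sphere and two-sphere spherical-cap closed forms; ≲0.2% at 10 000
points), hydrogens excluded from both area and occlusion, matching common
heavy-atom SASA tools. Fewer than 32 points is refused as below any useful
accuracy. Because the lattice orientation is fixed in space, SASA is
invariant under rigid motion of the molecule only to within the lattice
discretisation (< 0.5% observed), not to machine precision.

## Exposure normalisation

Per-residue exposure is SASA divided by the maximum SASA (MSA) of the residue
type as the central X of a Gly–X–Gly tripeptide, in percent. Choices:

* **Scope** defaults to side-chain-only area in both numerator and
  denominator — the side chain decides whether a thiol can reach a partner —
  with whole-residue available by flag. Glycine's side-chain reference falls
  back to its whole-residue value.
* **MSA mode** defaults to the maximum over the supplied conformer ensemble
  ("maximum SASA" read literally); a mean mode is provided for sensitivity
  analysis.
* Exposure above 100% (a conformation more extended than the tripeptide
  reference) is reported and flagged, never clamped.
* Time averaging computes exposure per frame and then averages; averaging
  SASA first and dividing once is available by flag and identical for a
  fixed MSA table.
* Cysteine classification uses strict inequalities: exposed > 20%,
  buried < 7%, intermediate otherwise.
* Hetero residues (cofactors, shielding dummies) contribute occlusion but
  get no exposure row — there is no tripeptide reference for them.

## Dimer screening

The screen measures all inter-chain cysteine Sγ–Sγ distances (Cβ–Cβ
optionally, for models without side-chain detail) and applies a three-band
policy: closest pair ≤ 6 Å → candidate, > 10 Å → rejected, otherwise
marginal. The two thresholds play different roles in practice — 6 Å is a
direct-bond feasibility bound, 10 Å an exclusion bound beyond which even
restrained refinement is hopeless — so the band between them is made
explicit rather than collapsed. Verdicts are monotone in distance by
construction.

In-silico disulfide formation removes the HG atoms of both cysteines and
records the bond; coordinates are deliberately untouched (closing the S–S
distance to ~2.05 Å is a refinement engine's job, out of scope here).
Already-deprotonated cysteines pass through unchanged.

C2 symmetry is checked by chain-swap superposition: for an exact two-fold
dimer, swapping the chain labels produces a rigid copy, so the Kabsch RMSD
between original and swapped coordinate stacks is zero. A 1e-6 Å floor on
the tolerance absorbs float32 coordinate noise.

## Interface panel

* **Kabsch superposition** uses the SVD formulation with reflection
  correction (determinant-negative solutions flipped along the smallest
  singular direction), so the returned rotation is always proper. It is
  cross-checked against an independent Horn quaternion eigenvalue oracle to
  1e-6 Å in the tests.
* **RMSD** is computed per frame against a caller-chosen reference frame on
  a backbone selection after superposition.
* **RMSF** superposes all frames onto an iteratively refined mean structure
  (two passes; converged to well below measurement noise for the jitter
  levels of interest) and reports per-atom RMS deviation from the mean. The
  fit uses all atoms by default: fitting on a small selection removes six
  rigid degrees of freedom from few coordinates and biases RMSF visibly low.
  For isotropic per-coordinate jitter σ the expected value is σ√3; the
  tests recover it within 5% at 2000 frames. Both all-carbon and Cα-only
  report selections are supported.
* **Interaction energy** sums Lennard-Jones 12-6 (ε/r_min convention,
  geometric-mean ε, additive r_min/2) and Coulomb
  (332.0636 kcal·Å/(mol·e²), dielectric 1) over *inter-chain* atom pairs
  only; bonded terms are never computed, so a formed disulfide's covalent
  energy is excluded by construction. Both terms are multiplied by the
  CHARMM-style switching polynomial between 10 and 12 Å — C1-continuous at
  both ends — and truncated at the cutoff. Parameters are caller-supplied
  per atom; a minimal bundled assigner (element-based LJ, formal charges on
  Asp/Glu carboxylate oxygens, Lys NZ and Arg guanidinium nitrogens, zeros
  and inert LJ for hetero atoms) supports toy systems and trend analysis.
  Absolute agreement with any specific force field is explicitly not
  claimed.
* **Interface area** A_IS = SASA(A) + SASA(B) − SASA(AB), clipped at zero to
  absorb lattice quantisation for barely touching chains.
* **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ 3.5 Å and
  donor–H–acceptor angle ≥ 140°, evaluated over every hydrogen on the
  donor (best angle reported). These criteria are a documented choice, are
  configurable, and are recorded in the panel metadata. A heavy-atom-only
  fallback (distance criterion alone, each unordered pair counted once)
  exists for hydrogen-free models.
* **Salt bridges**: a candidate is an (Asp/Glu carboxylate, Lys/Arg — and
  optionally His — cationic group) pair across the interface; present in a
  frame when the minimum charged-group heavy-atom distance is ≤ 4.0 Å, and
  counted only when present in strictly more than 10% of frames. The strict
  inequality is deliberate: exactly 10 of 100 frames does not count.
* Panel scalars are mean ± population SD over frames; hydrogen bonds are
  reported as the frame-mean count, salt bridges as the post-filter count.

## Cross-link constraints

DSSO and DSBU react with lysine amines and imply a Cα–Cα ceiling of ≈ 27 Å
(spacer plus two side chains); one shared default is used for both linkers,
with per-linker overrides since their spacers differ slightly. Disulfide
records measure Sγ–Sγ with a 6 Å ceiling for *formable* bonds (the screening
bound) and 2.5 Å for *formed* ones. On a homodimer all four chain
assignments (A–A, B–B, A–B, B–A) are evaluated; a record is satisfied if any
assignment fits, ambiguous if both an intra and an inter assignment fit.
Self-pairs (X–X) have no intra realisation — a residue cannot link to
itself — so they are inter-only testable, and a self-pair found in the dimer
fraction is classified intermolecular regardless of other evidence.
Provenance logic: dimer-fraction-only → inter; also found in the monomer
fraction → leaning intra; unknown → ambiguous. Residue numbering is taken
from the model as-is; any construct offset (e.g. an N-terminal purification
remnant) is the caller's responsibility.

## Synthetic data

Every generator is a pure function of its seed and spec. The monomer is an
ideal α-helix (rise 1.5 Å, 100°/residue) whose backbone triads carry ideal
residue templates from the bundled chemical component dictionary; side
chains point outward, so placed cysteines are exposed by construction, and
"buried" cysteines are shielded by a shell of carbon dummy atoms (HETATM
residue `SHL`) that drives their SASA to ≈ 0. Dimer poses are built by a
180° rotation about an axis placed outside the chosen surface cysteine —
exactly C2-symmetric — with the axis offset solved (Brent's method, 1e-6 Å)
so the closest inter-chain Sγ–Sγ distance equals the target; the asymmetric
variant adds a seeded random twist and re-solves the approach shift.
Trajectories are i.i.d. isotropic Gaussian jitter per atom per frame;
contact-occupancy schedules pin charged-group tip atoms at 3.5 Å (contact)
or 6.5 Å (apart) in a deterministic stride-chosen set of exactly
round(occupancy × n_frames) frames, so realised occupancies are exact and
tests cannot flake. Acid protons of Asp/Glu are stripped (side chains are
modelled as charged).

What the generator does **not** emulate: real secondary-structure
heterogeneity, correlated (collective) motions, side-chain rotamer dynamics,
force-field-consistent energetics, or sequence realism. Passing tests
therefore certify the *computations* — geometry, counting, filtering,
normalisation, aggregation — on inputs with known ground truth, not the
biological accuracy of any particular cryptochrome model. A user with a real
homology model can feed it in directly as PDB; nothing in the package
depends on the fixtures.

## Problem sizes and defaults

The bundled analyses use a 24-residue monomer (~320 atoms), 960-point SASA
lattices, 5-frame exposure averaging, 25-frame interface ensembles with
0.15 Å jitter, and 2000 frames for fluctuation-recovery checks — sizes
chosen so each analysis completes in seconds while keeping Monte-Carlo error
comfortably inside the stated tolerances. The Ellman simulation uses the
standard 0–30 μM calibration design in 5 μM steps, slope 0.012 per μM and
absorbance noise σ = 0.005, typical of a plate-reader thiol assay.

## Known limitations

* No docking and no pose generation: poses are inputs (or fixtures).
* No coordinate relaxation after disulfide formation; marginal poses (6–10 Å)
  are flagged for the user rather than rescued by restrained refinement.
* Electrostatics are switched-cutoff, not Ewald; energies are comparative,
  not absolute.
* SASA rigid-motion invariance holds to the lattice discretisation, not to
  machine precision.
* mmCIF and binary trajectory formats are out of scope; multi-model PDB is
  the ensemble interchange format.
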