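# crydimer

Structural analysis of disulfide-linked homodimers of cryptochrome-like
proteins. Cryptochrome 4a (Cry4a), the candidate magnetoreceptor protein of
migratory birds, forms covalent homodimers through surface cysteines; deciding
*which* cysteines can bond, and characterising the resulting dimer interface,
is a chain of geometric and surface-area computations that this package
implements as a reusable, tested pipeline:

1. **Solvent exposure** — per-atom solvent-accessible surface area (SASA) by
   the Shrake–Rupley method, normalised per residue by the maximum SASA (MSA)
   of that residue type in a Gly–X–Gly tripeptide:
   `exposure_i = 100 · SASA_i / MSA(X_i)` (percent). Cysteines are classified
   exposed (> 20%), intermediate, or buried (< 7%) by side-chain exposure.
2. **Dimer screening** — rigid two-chain poses are screened on the closest
   inter-monomer Sγ–Sγ distance: ≤ 6 Å → disulfide candidate, > 10 Å →
   rejected, in between → marginal. Candidate poses get an in-silico
   disulfide: thiol hydrogens removed, SSBOND record emitted. A chain-swap
   Kabsch superposition checks C2 symmetry.
3. **Interface panel** — over a coordinate ensemble (multi-model PDB standing
   in for a trajectory): inter-monomer non-bonded energy `E_tot` (Lennard-Jones
   12-6 + Coulomb, switched smoothly between 10 and 12 Å), radius of gyration
   `R_g`, backbone RMSD against a reference frame, per-carbon RMSF about the
   iteratively superposed mean structure, buried interface area
   `A_IS = SASA(A) + SASA(B) − SASA(AB)`, inter-chain hydrogen bonds
   (≤ 3.5 Å, ≥ 140°), and salt bridges retained only when present in strictly
   more than 10% of frames.
4. **Cross-link constraints** — residue pairs identified by cross-linking mass
   spectrometry (DSSO/DSBU lysine linkers, Cα–Cα ceiling ≈ 27 Å) or as
   disulfides (Sγ–Sγ) are mapped onto monomer/dimer models; every intra- and
   inter-chain assignment is evaluated, and self-pairs (the C412–C412
   pattern) are recognised as inter-only testable.
5. **Ellman assay arithmetic** — accessible cysteines per protein molecule
   from DTNB absorbance: `N_Cys = E / (a·c)` with the calibration slope `a`
   fitted from a free-cysteine dilution series.

A synthetic-data module generates every input the pipeline needs — idealised
α-helical monomers with surface or shielded cysteines, exactly C2-symmetric
dimer poses with a prescribed closest Sγ–Sγ distance, ensembles with
prescribed positional jitter and exact contact-occupancy schedules, extended
Gly–X–Gly tripeptides, and noisy calibration series — so every stage is
testable against analytic ground truth without any downloads.

## Worked example

```bash
python analysis/01_simulate_fixtures.py
python analysis/02_exposure_profile.py
python analysis/03_screen_poses.py
python analysis/04_interface_panel.py
```

The exposure step prints, for a 24-residue helical monomer with one surface
and one shielded cysteine:

```
MSA references (side chain, Å²): {'ALA': 52.2, 'CYS': 88.4, 'LYS': 153.1, 'ASP': 108.7}
  Cys A:10   43.7%  -> exposed
  Cys A:13    0.0%  -> buried
classification over 5 frames: 1 exposed / 0 intermediate / 1 buried
```

i.e. the surface cysteine sits at 43.7% of its tripeptide reference area and
clears the 20% threshold, while the shielded one is fully buried. Screening
then sorts three constructed poses into the three bands and bonds the
candidate:

```
pose_5A: min Sγ–Sγ  5.00 Å → candidate (C2 RMSD 3.40e-07 Å)
pose_8A: min Sγ–Sγ  8.00 Å → marginal (C2 RMSD 4.65e-07 Å)
pose_12A: min Sγ–Sγ 12.00 Å → rejected (C2 RMSD 5.64e-07 Å)
formed disulfide ('A', 10)–('B', 10) at 5.00 Å, removed 2 HG atoms
```

and the panel over a 25-frame jittered ensemble of the bonded dimer reads:

```
minus_E_tot_kcal_mol      R_g_A    RMSD_A    RMSF_A      A_IS_A2  hydrogen_bonds  salt_bridges
         24.3 ± 22.3 11.6 ± 0.0 0.3 ± 0.1 0.3 ± 0.0 272.6 ± 17.3             0.0             1
```

— a mildly attractive interface (−E_tot = 24.3 kcal/mol) burying ≈ 273 Å²,
with the one scheduled salt bridge (48% occupancy) passing the strict 10%
filter. Tables land in `results/`, coordinates in `scratch/`.

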