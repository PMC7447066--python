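# Methods

This note records the models, conventions and design choices behind each
analysis stage, what the synthetic generator does and does not emulate, and
the numerical details a user would need to reproduce or reinterpret the
outputs. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## System and conditions

The subject is a homodimeric saposin-fold domain: two identical ~104-residue
chains, each with three native disulfide bonds (Cys6–Cys99, Cys31–Cys71,
Cys37–Cys68) and a disordered loop spanning residues 40–63 inclusive
(1-based, inclusive intervals throughout). Conditions combine a pH
(3.0 or 7.4) with a disulfide-reduction code: AI (all intact), D1/D2/D3
(one bond reduced, in registry order), D4/D5/D6 (two reduced), AR (all
reduced). The eight codes enumerate the subsets of the three bonds exactly
once; `core.resolve_condition` is the single source of that mapping.

## Protonation model

No pKa calculation is performed. Charge states are categorical rules with a
per-residue override table:

* pH 3.0 — Asp/Glu protonated (neutral), His protonated (charged),
  Lys/Arg charged, C-terminus neutral, N-terminus charged.
* pH 7.4 — Asp/Glu deprotonated (charged), His neutral (and excluded from
  the salt-bridge census entirely), Lys/Arg charged, both termini charged.

Overrides (config key `protonation_overrides`, e.g. `Glu72: deprotonated`)
win over the rules and are flagged in the map's provenance, so any published
per-residue pKa set can be plugged in. Chemical wording is normalized per
residue type: a *protonated* carboxylate is neutral, a *protonated* amine is
charged.

## Analysis window

All summaries default to the last 10% of each trajectory by time, with an
inclusive threshold (t ≥ t₀ + 0.9·span), so the final frame is always kept
and a fraction of 1.0 is the identity. The window is a parameter
(`window_fraction`, or an explicit time interval) because different metrics
in this workflow have historically used different windows; every output
table records the window actually used via the run manifest.

## S-gamma separations

Distances are plain Euclidean norms between SG atoms, one series per
(pair, monomer, replicate). Histograms use uniform 0.01 nm bins on a shared
grid [0, ceil(max/0.01)·0.01]; each series is normalized to sum to 1 before
pooling so replicates with different frame counts are comparable, and the
per-bin mean and **population** SD across the pooled series (n = monomers x
replicates = 6 for three replicates) are reported; sample SD is a switch.
Reformability is the fraction of windowed samples below the 0.4 nm cutoff;
the verdict "likely reform" fires at fraction ≥ 0.5 by default, and the
fraction is always reported next to the verdict because the cutoff-majority
rule is a convention, not physics. The same operator runs on the non-native
pairs (31–37, 68–71) as an interchange-feasibility screen.

## Structure metrics

* **Superposition** is the Kabsch least-squares fit (SVD with determinant
  sign correction, proper rotations only), computed on a fit selection and
  applied to all atoms. Degenerate fit sets (< 3 atoms, collinear or
  coincident) are rejected. scipy's `Rotation.align_vectors` serves as an
  independent cross-check in the tests, never as the implementation.
* **RMSD** fits on non-loop backbone atoms (N, CA, C, O) and measures on
  either the full backbone ("with-loop") or the non-loop backbone
  ("no-loop"), unweighted; the reference is the first frame of the analysis
  window (the choice of reference structure is open in this workflow; first
  frame is the default and a parameter). Replicate summaries are mean ± SEM
  with n = replicates.
* **RMSF** is computed per chain on backbone atoms after superposing every
  frame on that chain's backbone: per-atom mean-square fluctuation about the
  time mean, averaged within each residue, square-rooted. The
  "pc1-filtered" mode first reconstructs the centered coordinate matrix
  from its projection onto the first right singular vector (the first
  eigenvector of the positional covariance — the essential-dynamics
  filter); being a rank-1 projection it can only remove variance, so the
  filtered profile is bounded by the raw one, and both are exposed. This is
  covariance PCA over the analysis window, not Hessian normal modes.
  Chain profiles pool across monomers and replicates as mean ± population
  SD (n = 2 x replicates).
* **R_g and COM separations** are mass-weighted; Rg selections are "all
  atoms" or "all non-loop atoms". No ordering between with-loop and
  no-loop Rg is asserted anywhere — it is not guaranteed in general.

## Secondary-structure variation

DSSP letters map surjectively to three classes: H/G/I → helix (3₁₀ and pi
helices count as helical character), E/B → beta, T/S/C/blank/`~` →
disordered. The variation index of residue i is the number of frames whose
3-class label differs from the previous frame, normalized by the maximum
possible count, frames − 1 — for a 1001-frame window that divisor is 1000,
i.e. a change every frame scores 1.0. The divisor is derived from the
window length, never hard-coded. Change events are counted on the 3-class
labels, not raw DSSP letters (flickering among coil letters is not
variation); this is the adopted reading of an ambiguous convention and the
letter-level alternative can be had by mapping each letter to its own class.
Pooling across monomers and replicates gives mean ± population SD (n = 6).
The per-residue mode breaks ties by the fixed precedence helix > beta >
disordered. Region summaries report the sum of pooled means over an
interval and that sum divided by the interval length; the dimer net
variation is the same sum over all residues of both chains, reported both
raw and per residue.

## Contact censuses

The contact unit is the **residue pair per frame**: however many atom pairs
qualify, a pair counts once per frame. Sequence-adjacent pairs (|i−j| < 2,
same chain) are excluded from every census so covalent neighbours cannot
inflate counts.

* Hydrogen bonds: donors are N/O that carry hydrogens (backbone amide N
  except proline, plus a sidechain table), acceptors are backbone carbonyl
  O plus sidechain O/N acceptors; criterion: donor–acceptor ≤ 0.35 nm and
  H–donor–acceptor angle ≤ 30°. When the topology has explicit hydrogens
  (element H within 0.12 nm of the donor) they are used; otherwise an
  idealized H along the donor→acceptor axis is assumed (the angle test then
  always passes) and the run manifest flags `idealized_hydrogens`.
* Hydrophobic contacts: minimum distance over sidechain heavy atoms
  ≤ 0.45 nm, both residues in the wholly-hydrophobic set — default
  {Ala, Val, Leu, Ile, Pro, Phe, Met, Trp}. Gly is excluded (no sidechain),
  Tyr (hydroxyl) and amphipathic sidechains such as Lys are excluded on the
  principle that partially polar sidechains do not count; the set is a
  config key.
* Salt bridges: acidic site = each sidechain carboxylate oxygen of a
  *deprotonated* Asp/Glu; basic site = Lys NZ, Arg center of mass of
  NE/NH1/NH2, His center of mass of ND1/NE2/CE1 (the delocalized charge);
  minimum site distance ≤ 0.45 nm; His is dropped from the census entirely
  at pH 7.4. With the default maps this makes the pH 3.0 count ≤ the
  pH 7.4 count on identical geometry (no charged carboxylates at pH 3.0).
* Cation-pi screen: cation sites (as above) within 0.6 nm of an aromatic
  ring centroid (Phe/Tyr six-ring, Trp six-ring). There is no angular term
  and the screen is deliberately loose; candidates are reported separately
  and never merged into census totals.

Partitions: each pair is exactly one of intra-A / intra-B / inter-monomer;
independently, a pair is intra-loop (both residues in the loop, same chain)
or loop–non-loop (exactly one residue in the loop; attributed to the loop
residue's chain for monomer-level pooling). Frame-level counts are pooled
into one data set per (kind, partition) — both chains x replicates for
intra and loop categories (n = 6 for three replicates), replicates only for
inter (n = 3) — and reported as mean ± population SD of the pooled frame
counts.

## Synthetic generator

The generator produces the *study conditions*, not physics: no forces,
solvent or thermostat.

* **Template**: a fixed 104-residue sequence with cysteines at
  6/31/37/68/71/99, Asp40 and Glu54/56/58/72, a Gly/Ser/Thr/Asn-rich loop
  at 40–63, helices at 3–19, 23–39, 64–78, 82–98, and hydrophobics lining
  the helices. It emulates, but does not claim to be, the true PSI sequence.
  Atoms are pseudo-atoms: full backbone plus exactly the sidechain atoms the
  analyses name (SG, NZ, guanidinium N, His ring triad, carboxylate O,
  aromatic rings, hydroxyls, and one or two aliphatic carbons).
* **Geometry**: chains fold as a two-leg hairpin (0.15 nm rise per residue,
  legs 0.3 nm apart) with an idealized helical twist (100°/residue, 0.1 nm
  radius) on helix spans; the two chains face each other 1.2 nm apart with
  sidechains pointing into the interface. The twist radius and leg/chain
  separations were chosen once so that backbone bonded distances stay far
  (> 5 sigma) below the 0.5 nm broken-image guard under the default jitter.
* **Dynamics**: per frame, each residue receives an isotropic Gaussian
  displacement (rigid within the residue, independent across residues and
  frames). Default amplitudes: sigma = 0.015 nm outside the loop, 0.04 nm
  inside it — the loop is the mobile element, as in the real system. An
  explicit per-residue profile can be planted instead; the recovery
  experiments use a strictly graded profile (0.01 → 0.05 nm) because a
  rank-based comparison against a two-level profile is dominated by ties
  and tests nothing.
* **S-gamma laws**: per condition, intact pairs draw from N(0.2038 nm,
  0.002) and reduced pairs from N(mu, sigma) with mu = 0.50 nm (6–99),
  0.35 nm (31–71) and 0.40 nm at pH 3.0 / 0.50 nm at pH 7.4 for the labile
  37–68 (sigma 0.02–0.05 nm) — the separations the reduced pairs settle to
  in the study system. The two SG atoms are moved symmetrically along their
  separation axis to the drawn distance each frame.
* **Planted contacts** (HI between hydrophobic CBs, SB between a
  carboxylate and Lys NZ) are enforced exactly: the second residue's
  sidechain site atoms are rigidly translated along the inter-site axis and
  the *minimum* site–site distance is driven onto the target by a
  fixed-point iteration (machine precision, every frame). Decoys placed at
  1.2 x the census cutoff therefore stay strictly undetectable. A single
  atom under two constraints (two laws, or a law plus a plant) is rejected.
* **Secondary structure**: each non-loop residue runs an independent
  two-state {H, C} Markov chain with per-step switch probability p (default
  0.1; initial state from the helix spans). Loop residues instead draw
  i.i.d. from the coil letters {C, T, S}: their letters flicker every frame
  but their 3-class label never leaves disordered — a fixture for the
  letter-vs-class distinction. SS dynamics are independent of the disulfide
  code: the generator plants no coupling between reduction state and
  switching rate, so condition-to-condition variation differences in
  synthetic runs reflect sampling noise only.
* **Determinism**: one seeded generator drives all randomness; the same
  spec reproduces byte-identical trajectories and series.

What passing tests on these fixtures shows: the estimators recover planted
ground truth (amplitudes up to the isotropic sqrt(3) factor, Spearman ≥
0.95 at 2000 frames; switch probabilities within binomial error; contact
geometries at 100%/0% for planted/decoys) and the operators match
brute-force oracles. What it does not show: correctness of any physical
interpretation on real MD data — correlated motions, anisotropic
fluctuations, real rotamer packing and solvent-mediated contacts are
outside the generator's vocabulary.

## Problem sizes and defaults

Default runs use 3 replicates x 1001 frames x 10 ps spacing for the full
dimer (≈ 1 300 pseudo-atoms), windowed to the last 10% (101 frames) for all
summaries; the recovery experiments use 2000 frames where variance demands
it. These sizes make every estimator's sampling error small relative to its
tolerance while keeping any run in seconds to minutes on one CPU.

## Degenerate inputs and tie-breaks

Empty selections, < 2-frame RMSF windows, empty analysis windows, zero
total mass, unknown condition codes, non-cysteine S-gamma references,
missing named site atoms and length-drifting DSSP tables are all rejected
with messages naming the offender. Coincident S-gamma atoms warn rather
than fail (distance 0 is defined). Mode ties use the fixed helix > beta >
disordered precedence. Histogram bin edges follow numpy's half-open
convention with the final edge closed.

## Known limitations

* DSSP itself is an input, not re-implemented; the package consumes
  per-frame code strings (a CSV dialect), not classic mkdssp output files.
* Idealized-hydrogen H-bond detection reduces to a distance criterion on
  hydrogen-free topologies; counts on such inputs are upper bounds relative
  to an explicit-hydrogen analysis.
* The cation-pi screen has no geometric orientation term.
* Periodic boundary conditions are not unwrapped; inputs are assumed whole,
  and a bonded-distance guard (0.5 nm) rejects frames that look broken
  across images.
* The interchange screen is geometry-only; no thermodynamic or electronic
  assessment of disulfide exchange is attempted.
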