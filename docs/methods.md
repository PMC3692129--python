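# Methods

## Depth by iterative pseudo-solvation

Residue depth measures burial as the distance to the closest *bulk*
water rather than to the molecular surface, which lets it distinguish a
residue lining an internal water-filled cavity from a truly exposed one.
The engine immerses the protein in a cubic lattice of water-oxygen sites
and repeats the immersion `n_iterations` times, each time rotating the
lattice about the protein centroid by a uniformly random rotation.
Rotating the solvent relative to a fixed protein frame is geometrically
equivalent to re-solvating rotated copies of the protein and has the
advantage that the waters of all iterations already share one frame, so
no structural superposition step is needed downstream.

Parameters (defaults in parentheses):

- `lattice_spacing` (3.1 Å): cubic spacing reproducing bulk water number
  density, 0.0334 molecules/Å³.  Only oxygen positions matter: every
  rule below uses O–O or O–heavy-atom distances.
- `clash_cutoff` (2.6 Å): waters closer than this to any protein heavy
  atom are deleted.  The value is just below the first-shell O–O
  distance (2.8 Å), so a solvent site survives only where a real water
  oxygen could sit.
- `box_padding` (10 Å): solvent box margin beyond the protein bounding
  box.
- bulk rule: a water with fewer than `min_neighbours_bulk` (2) other
  waters within `neighbour_cutoff` (4.2 Å, about 1.5 hydration shells)
  is non-bulk.  Neighbour counts are evaluated before the solvent box is
  cropped (the lattice is generated with a 4.2 Å boundary ring);
  otherwise box-edge waters with truncated neighbourhoods masquerade as
  cavity waters.
- depth: per iteration, an atom's depth is the Euclidean distance to the
  nearest bulk water; the final value is the mean over iterations.
  Residue depth is the mean over the residue's heavy atoms; main-chain,
  side-chain, polar-side-chain and minimum aggregates are also exposed
  because the pKa features need them.

A pure water box is its own fixed point: every interior lattice water
has six 3.1 Å neighbours and is bulk.  On a solid lattice ball of radius
12 Å the atom depth and the analytic burial depth (R − r) correlate with
Spearman ρ ≈ 0.97 at 10 iterations, and depths of a rigidly rotated copy
agree with the original to ≈ 0.2 Å mean absolute difference — the
Monte-Carlo noise floor of 10 random orientations.

## Cavities and calibrated volumes

Non-bulk waters pooled over all iterations are single-linkage clustered
at 1.2 Å; a cluster of at least two waters is a cavity.  Because
iterations share the protein frame, overlapping waters from different
orientations trace out the same physical void ("a set of sometimes
overlapping water molecules").

Volume uses a radius-weighted voxel assignment standing in for a full
weighted-Voronoi construction: each voxel centre inside the occupied
envelope (within atom radius + 2.8 Å of a protein atom) is assigned to
the site — protein atom or water (r = 1.4 Å) — minimising the power
distance |x − c|² − r².  The protein-assigned volume is measured twice:
with the complete pooled water ensemble, and with all non-bulk waters
removed.  Voxels the protein reclaims in the second run are the cavity
volume; each is credited to the cavity whose member waters are nearest
to the water that originally claimed it (capped at 4.2 Å), so that
non-bulk waters whose cluster stayed below the two-water threshold still
count toward the physical cavity they occupy.  Raw volumes are finally
re-calibrated by the affine fit V_c = 0.8·V + 21 Å³.  The raw estimator
systematically overestimates carved voids by ~10–25% (the water cells
extend past the nominal void boundary into the lattice grooves between
wall atoms); the calibration absorbs exactly this kind of systematic
bias.  Note the calibration maps a vanishing raw volume to 21 Å³; both
raw and calibrated values are reported, and raw volumes below ~10 Å³
should be treated as noise.

On the carved-sphere benchmark fixture (2.8 Å solid lattice, r = 4 Å
sphere removed, analytic volume 268 Å³) the pipeline at 20 iterations
reports a calibrated volume within ~10% of truth; grid refinement
1.0 → 0.5 → 0.25 Å changes the estimate by < 2% (discretisation error is
far below the orientation-sampling noise, so convergence is stated
against the fine-grid limit, not against the analytic value).  At the
default 10 iterations the pooled ensemble does not always saturate the
void and the spread grows to roughly ±12%.

A cavity is *buried* when the shallowest residue lining it (any heavy
atom within 5.6 Å of a member water) is deeper than 3.75 Å; the lining
shell reuses the binding-module shell radius since no separate value is
published.

## Conservation

Column conservation is the equal-weight Jensen–Shannon divergence (in
nats, bounded by ln 2) between the column's smoothed amino-acid
distribution and a background distribution (packaged BLOSUM62 marginal
frequencies).  Sparse columns are smoothed with substitution
pseudo-counts: B_i = m·R_i with m = 5 and R_i the number of distinct
residue types observed, pseudo-count mass distributed as
b_ia ∝ Σ_k (n_ik/N_i)(t_ka/T_k).  The substitution probabilities t are
reconstructed from the BLOSUM62 half-bit log-odds s via
q_ka ∝ p_k·p_a·2^(s/2) and row-normalised — the original target-count
table is not shipped with biopython, and any monotone distortion this
reconstruction introduces is absorbed by the downstream unity
normalisation.  Gaps and non-standard letters are excluded from counts
(not treated as a 21st symbol); an all-gap column scores 0; the query
row is included in the counts.  Scores are mapped to structure residues
through the ungapped query row; residues outside the alignment inherit
the protein's minimum score.

## Binding-site prediction

Each residue's prior binding probability P comes from a lookup table
over (residue type, depth bin, side-chain accessibility bin); the
packaged table is a small synthetic stand-in (documented format, 1 Å/10%
default binning for training) and `build_probability_table` fits a real
one from any labelled corpus with +1/+2 Laplace smoothing and
residue-type marginal fallback for empty bins.  P and conservation J are
normalised per protein against the means of their five smallest and five
largest values (clipped to [0, 1]; all residues enter the normalisation
by default) and combined as q = α·P′ + (1 − α)·J′ with α = 0.7.

Cavity-water displacement is a noisy-OR: per chain c,
D_c = 1 − Π(1 − q_ic) over residues within 5.6 Å, chains combining
independently — algebraically identical to the flat noisy-OR, which the
tests assert.  The two-water rule smooths D: each water's likelihood
becomes the mean of the two highest among itself and neighbouring
cavity waters within 4.2 Å, and a water with no such neighbour gets 0
(a ligand must displace at least two waters).  Smoothing runs over the
cavity's pooled member waters of all iterations: on a rigid solvent
lattice a single orientation rarely parks two non-bulk waters in the
same pocket, while the pooled ensemble is precisely the cavity object
the clustering step built.  Candidate residues are still nominated per
iteration (any heavy atom within 6.5 Å of a water with smoothed
likelihood > β = 0.8) and a residue is called only when nominated in
strictly more than 60% of all iterations.

Binary performance is summarised by confusion *rates* (fractions of all
residues), sensitivity, specificity, accuracy, precision and the
Matthews correlation coefficient; undefined ratios are reported as 0 and
flagged.

## pKa model

pKa = model pKa + c0 + c1·DEPTH_MC + c2·DEPTH_polarSC + c3·HB + c4·EE +
c5·ASA_SC, with per-residue-type coefficients packaged for ASP (model
3.8), GLU (4.5), HIS (6.5) and LYS (10.5).  Features:

- DEPTH_MC / DEPTH_polarSC: mean depths (Å) of main-chain and polar
  side-chain atoms (side-chain mean as fallback, flagged).
- HB: hydrogen bonds of the ionizable group, heavy-atom criterion —
  donor–acceptor distance ≤ 3.5 Å and donor–acceptor–antecedent angle
  ≥ 100°.  Hydrogens are not modelled; this is a deliberate
  simplification of an explicit-hydrogen protocol.
- EE: vacuum Coulomb energy (kcal/mol, k = 332.06) between the group and
  all charged atoms within 12 Å, using condensed heavy-atom charges that
  sum to the formal group charges (carboxylates −1, LYS ammonium +1,
  ARG guanidinium +1, HIS doubly protonated +1, backbone dipoles net 0).
- ASA_SC: side-chain accessible surface fraction in [0, 1] (not
  percent — the packaged c5 magnitudes are only plausible on the unit
  scale), from an in-package Shrake–Rupley implementation (1.4 Å probe,
  960 golden-spiral points per atom, validated against analytic sphere
  and two-sphere closed forms) divided by packaged fully exposed
  reference side-chain areas.

Whether the free-residue model pKa enters as an offset in addition to c0
is convention-dependent; the model implements model_pKa + c0 + Σ and
exposes `include_model_pka`.  The packaged coefficients are tied to the
exact feature conventions above; `fit_coefficients` refits them per
residue type by ordinary least squares (ridge fallback for
rank-deficient designs) and recovers generating coefficients to 1e-6 on
noiseless synthetic data.

## Synthetic fixtures: what they do and do not show

The generator produces (i) solid atom lattices (cube or ball) with
carved spherical/cuboid voids of known analytic volume, (ii) water boxes
at the solvation density, (iii) idealized extended peptides with full
heavy-atom topology, donors/acceptors and charged groups, and (iv)
single atoms.  They give exact ground truth for geometry-driven code
paths (depth ordering, cavity volume, clash and neighbour rules, ASA)
but are not proteins: there is no secondary structure, no realistic
packing density, no rotamer geometry and no evolutionary signal, so
passing tests demonstrate correctness of the algorithms and their
published operating point, not predictive performance on real
structures.  Predictive benchmarks require real coordinates, a
trained probability table and genuine alignments.

## Numerical choices

- All neighbour logic uses k-d trees; the power-distance voxel winner is
  found among the 16 Euclidean-nearest sites, exact for the 1.4–1.9 Å
  radius range in play.  Re-assignment after water removal is computed
  only on voxels whose winner was removed (exact, large speed-up).
- Randomness flows from a single integer seed; iteration i uses the
  stream seeded (seed, i), so runs are reproducible and individual
  iterations recomputable in isolation.
- Strict inequalities follow the published wording: non-bulk is "fewer
  than 2 within 4.2 Å" (≤ 1 neighbour in the closed ball), buried is
  depth > 3.75 Å, consensus is > 60%.
- Degenerate inputs: constant scores normalise to 0.5 with a warning; an
  empty displacement shell gives likelihood 0; a solvent box with no
  bulk water raises with advice to enlarge the padding; raw cavity
  volumes are clamped at ≥ 0 against grid noise.

## Known limitations

- The regular solvent lattice replaces an equilibrated disordered water
  box; water–water distances are quantised, which makes the strict
  per-iteration two-water coincidence rare (hence the pooled smoothing
  ensemble) and slightly sharpens the bulk/non-bulk boundary.
- Very large cavities that hold three or more mutually close waters can
  classify those waters as bulk and go undetected — inherent to the
  neighbour-count bulk rule at any solvent density.
- Heavy-atom H-bond and charge treatment shifts the absolute pKa feature
  scales relative to explicit-hydrogen protocols; refit the coefficients
  when changing conventions.
- mmCIF input, hydrogen placement and homology modelling of mutants are
  out of scope.
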