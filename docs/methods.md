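# Methods

This note documents the models, parameter choices, numerical schemes and
known limitations of `smppi`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem and model

Given a protein–protein complex, the package classifies each interface
residue of a reference chain as *overlap* (`O`: would also be contacted by
a small-molecule ligand binding at the interface) or *non-overlap* (`N`),
and aggregates the residue calls into surface patches marking the likely
small-molecule site.  The underlying signal is structural and
evolutionary: ligand-overlap residues sit in concave, densely packed,
solvent-occluded, conserved sub-regions of the interface.

### Interface definition

A residue belongs to the interface when (a) it is a surface residue of the
isolated query chain and (b) at least one of its heavy atoms lies within
5.0 Å of a partner heavy atom.  Hydrogens are excluded everywhere.  The
surface filter applies to the query side only; the partner contributes all
of its heavy atoms.

*Surface residue rule.* A residue is "surface" when its SASA in the
isolated chain is at least 5% of its fully exposed reference SASA.  The
reference is the residue's own atoms in isolation, computed by the same
SASA engine.  This self-referenced normalisation behaves identically for
standard amino acids and for the pseudo-residues of the synthetic
fixtures; a fixed per-type table would be undefined for the latter.

### Solvent accessibility

Shrake–Rupley sphere sampling: each atom's accessible sphere
(radius r + 1.4 Å probe) carries 960 quasi-uniform points (golden-section
spiral); a point is accessible when outside every other atom's accessible
sphere.  For one isolated sphere this converges to `4π(r+probe)²`; the
suite checks agreement within 1%.  Van der Waals radii default to
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, 1.70 Å otherwise (configurable).

### Protrusion index

`cx = V_empty / V_atoms` within a 10 Å sphere centred on each heavy atom,
where `V_atoms` is the *union* volume of all heavy-atom spheres in the
neighbourhood (overlaps counted once, the centre atom included — an
isolated atom therefore has a large finite cx rather than a division by
zero) and `V_empty` the remainder of the sphere.  Volumes are measured on
a uniform 0.5 Å grid with first-order partial-cell weighting at sphere
surfaces (occupancy `clip(0.5 + (r − d)/h, 0, 1)`, maximised over atoms),
which suppresses the lattice bias that plain inside/outside counting
shows for atom-sized spheres.  Against closed-form one- and two-sphere
volumes the estimator is accurate to ≤ 2% at the default spacing, and
halving the spacing reduces the residual error by at least half.
Per-residue values are means over the residue's atoms.

### Contact density

For residue i: `density_i = Σ_j contacts(atom_ij) / totalAtoms_i`, where j
runs over the residue's *solvent-accessible* heavy atoms (atom SASA > 0 in
the complex), contacts are heavy atoms of other residues of the same chain
within 5.0 Å, and the denominator counts all heavy atoms of residue i.
The denominator deliberately follows the totals-based formula rather than
an average over accessible atoms only; both appear in the literature and
the totals form is the one implemented and tested here.

### Relative surface fraction

`SASA_in_complex / reference`, clipped to [0, 1].  Two reference modes:

* `context` (default): the residue plus its two sequence neighbours,
  computed by the same SASA engine — the Ala-X-Ala tripeptide idea
  generalised to arbitrary residue compositions.  For a free extended
  tripeptide the central fraction is exactly 1.
* `table`: Hubbard–Thornton Ala-X-Ala totals (the Naccess reference
  values) for the 20 standard amino acids; unknown residue types raise.

The context mode slightly over-normalises residues flanked by bulky
neighbours (the neighbours occlude more than alanines would); this is a
uniform, monotonicity-preserving effect and irrelevant to the classifier,
which only needs a consistent burial scale.

### Conservation

Scores are ingested, not computed: Consurf-style grade files (3LATOM
column, header junk tolerated) or plain TSV.  Normalised scores have mean
≈ 0 per chain with negative = conserved.  Residues missing from the table
are imputed 0 (the normalised mean) with a warning; more than 20% of a
chain unmatched is treated as a numbering mismatch and is a hard error.

### Hot-spot surrogate

Established hot-spot predictors are
knowledge-based accessibility + packing rules; here a transparent
surrogate flags a residue when its complex-state surface fraction is
≤ 20% **and** its contact density is ≥ median + 0.5·IQR of the candidate
set (both configurable).  A user label file overrides the rule entirely,
so externally predicted or experimentally derived hot spots can be
supplied.  The surrogate is a stand-in by design and is labelled as such.

### Surface patches

Three-step construction: pre-patch = central + (n−1) nearest surface
residues by Cα distance; COM = unweighted mean of pre-patch Cα
coordinates; solvent vector of any surface residue = Cα − COM; final
members = central + up to n−1 closest surface residues whose solvent
vector is within [0°, 110°] (closed interval) of the central's.  Choices
made where the construction is under-specified: the candidate pool for
the final step is the whole surface set (not just the pre-patch); the
angle filter is applied first, then the n−1 closest qualifying residues
are taken; distance ties break by (chain, resnum, icode).  A central
residue whose Cα coincides with the COM (degenerate solvent vector)
raises and the patch is skipped with a warning.

### Classifier

K class-balanced random forests (scikit-learn).  Each member trains on
every minority-class residue plus an equal-count draw without replacement
from the majority class; a fresh draw per member.  Member forests use 500
unpruned Gini trees with 3 (= ⌊√13⌋) features per split — the classic
randomForest defaults.  K defaults to 1000 (tests and the acceptance
script use K ≤ 20: balanced accuracy saturates well below that on the
synthetic tables, and the vote semantics do not depend on K).  The
ensemble call is a majority vote; ties go to `N`, the conservative class.
Seeding: one `numpy` generator drives both the down-sampling draws and
the per-member forest seeds, so training is bit-reproducible.

Permutation feature importance is the mean decrease in ensemble accuracy
when one feature column is shuffled on a held-out labelled set.  Using an
explicit held-out set instead of out-of-bag samples is a deliberate
deviation: it is defined identically for any ensemble composition and
keeps the importance measure independent of the bootstrap internals.

Training pools residues across complexes, which leaks homology between
related interfaces; `reduce_redundancy` mitigates this at the pair level,
and evaluation on genuinely held-out complexes (as in the end-to-end
test) is the honest protocol.

### Binding-patch aggregation

Size-7 patches are built for interface residues (central and members both
restricted to the interface, where predictions exist).  A patch is
reported when its central residue is predicted `O` and at least 5 of its
7 members are predicted `O`; reported patches are sorted by predicted-O
ratio.  The 5-of-7 threshold is the high-precision operating point: on
the synthetic patch tables, precision rises monotonically with the
predicted-O count.

### Pair pipeline

`make_pair` applies, in order: global sequence alignment
(Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.5; identity counted
over aligned columns) with a 40% threshold → interface detection on both
complexes → overlap labelling (≥ 2 shared residues) → Kabsch superposition
on aligned Cα pairs → ligand mapping and collision test (strict
`d < r_i + r_j` on heavy atoms).  Rejection reasons are mutually
exclusive and exhaustive: `low_identity`, `insufficient_overlap`,
`collision_free`.  Redundancy reduction clusters reference sequences
greedily (longest sequence seeds a cluster; members join at ≥ 40%
identity to the seed), drops clusters whose partners are all peptides
shorter than 5 residues, and keeps the pair with the highest
interface-residue identity (identical residues over the union of aligned
PP/PL interface positions).  Multiple copies of the same HET code are
treated as separate ligand candidates.

## Synthetic data: what it emulates, what it does not

`make_pocket_complex` builds an 8×8 pseudo-residue sheet (Cα + one
Cβ-like atom per residue, 4 Å spacing, small seeded jitter) whose central
3×3 block is recessed by 4 Å into a pocket; a partner slab floats 4 Å
above the central ≈25 residues and extends a plug of atoms into the
pocket; the PL copy plants a 9-atom ligand in the pocket.  By
construction the pocket-lining residues are contacted by both partner and
ligand (the overlap truth), the superposed ligand clashes with the plug
(competitive), a `remote` placement puts the ligand outside the PP
interface (insufficient overlap), and a zero-depth variant leaves the
ligand on the solvent face with no clash (non-competitive).

`make_feature_table` draws the 13 features from class-conditional
Gaussians.  Baselines (non-overlap class): conservation N(0, 1),
protrusion N(5, 2) truncated at 0, surface fraction N(0.45, 0.18) clipped
to [0, 1], density N(4.0, 1.2); neighbour features share a residue-level
latent factor (ρ = 0.5).  Overlap-class shifts follow the directions
observed on real interfaces — conservation −0.6, protrusion −1.5, surface
fraction −0.13, density +0.97 (the reported magnitude), hot-spot
probability 0.48 vs 0.37 — with the default 377:1623 (≈ 1:4.3) class
imbalance at n = 2000.  Where only a direction is reported, the shift
magnitudes are set to roughly half a baseline standard deviation, a
moderate, realistic separation.  `make_patch_table` adds spatial label
coherence: each patch draws a latent overlap propensity q ~ Beta(1, 2)
and labels its members i.i.d. Bernoulli(q).

What passing on these fixtures shows: the estimators are numerically
correct, the pipeline's decision logic is right, and the classifier
recovers class structure of the stated shape and strength at the stated
imbalance.  What it does not show: performance on real PP interfaces,
whose feature distributions are neither Gaussian nor independent of
sequence context, whose interfaces are far from flat grids, and whose
homology structure is richer than the generator's.  Corpus-level accuracy
figures require hundreds of curated complex pairs with matched
conservation profiles — out of desk-scale reach — so the acceptance
checks are property-based rather than value-reproducing.

## Numerical choices and degenerate inputs

* Altloc resolution: highest occupancy, ties to file order; first NMR
  model only.
* Protrusion grid: 0.5 Å default; memory grows with the bounding box
  (the grid covers the structure inflated by the 10 Å sphere), so very
  large complexes should use a coarser grid or chain selections.
* Angle comparison at the 110° patch bound uses a 1e-12 cosine tolerance
  so the closed interval survives floating point.
* Collinear (< rank-2) coordinate sets are rejected by the superposition
  (the rotation would be under-determined).
* Ensemble vote ties (fraction exactly 0.5) resolve to `N`.
* `K`, tree count, every cutoff and both hot-spot thresholds are
  `RunConfig` keys; defaults are the method's standard operating point.

## Problem sizes used by tests and the acceptance script

Fixture complexes are 64 + ≈25 residues (≈ 210 heavy atoms); feature
tables use n = 2000 (classifier recovery, K = 20), 40 000 (generator
statistics), and 1500 patches × 7 members (patch voting); the end-to-end
check trains on three fixture pairs and predicts a fourth.  These sizes
give stable statistics for every asserted property while keeping a full
run in tens of seconds.

## Known limitations

* The hot-spot surrogate is not an established server-grade predictor; treat
  `hsfPatch8` from the surrogate as a packing/burial composite unless
  user-supplied hot-spot labels are given.
* mmCIF input, NMR multi-model ensembles, and assembly generation are out
  of scope; inputs are explicit PDB files and chain selections.
* Conservation must be supplied externally; without it the `cons*`
  features are zero and the classifier runs on structure alone.
* Greedy identity clustering approximates CD-hit; adequate at desk scale,
  not tuned for thousands of sequences.
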