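# smppi — predicting where small molecules bind at protein–protein interfaces

Small molecules that act on protein–protein interactions (SMPPIs) do not
bind just anywhere on a binding interface: they favour a sub-region of the
interface that is concave, tightly packed, evolutionarily conserved and
enriched in hot-spot residues.  `smppi` implements a structure-based
pipeline that, given a protein–protein (PP) complex, predicts which
interface residues of a reference protein would also be contacted by a
small-molecule ligand (*overlap* residues, `O`) and aggregates those
predictions into high-confidence binding patches.  It is aimed at
structural bioinformaticians and drug-discovery researchers who want to
focus screening efforts on the druggable portion of a known interface.

## Method

**Labels from structure pairs.** Training data comes from PP:PL pairs: a
PP complex (reference protein P1 bound to partner P2) matched with a
protein–ligand (PL) complex (homologous reference P3, ≥ 40% sequence
identity, bound to ligand L).  Interface residues are surface residues
with a heavy atom within 5 Å of the partner.  Aligning P1 to P3 maps the
PL interface onto the PP interface; residues in both interfaces are
overlap (`O`), the rest non-overlap (`N`); pairs sharing fewer than two
overlap residues are discarded.  To keep only *competitive* pairs, P3 is
superposed onto P1 (Kabsch fit on aligned Cα atoms) and the mapped ligand
must sterically collide with P2 (some heavy-atom pair closer than the sum
of its van der Waals radii, strictly).  Redundancy is removed by greedy
sequence clustering of the reference proteins at 40% identity.

**Per-residue features (13 inputs).** For each interface residue:

* protrusion index `cx = V_empty / V_atoms` in a 10 Å sphere around each
  atom (0 = fully buried), residue value = mean over atoms;
* contact density = Σ_j contacts(atom_ij) / totalAtoms_i, counting
  intra-chain heavy-atom contacts within 5 Å of the residue's
  solvent-accessible atoms;
* relative surface fraction = SASA in the complex / tripeptide-reference
  surface of the residue type;
* normalised evolutionary conservation (Consurf-style scores, negative =
  conserved), ingested from grade files or TSV;
* hot-spot flag from a knowledge-based surrogate (strong burial in the
  complex plus dense packing), overridable by user labels.

The classifier input combines the central residue's surface fraction and
contact density, protrusion and conservation of its five nearest surface
residues (`protru1..5`, `cons1..5`, index 1 = the residue itself), and the
hot-spot frequency in its size-8 surface patch (`hsfPatch8`).  Surface
patches follow the centre-of-mass / solvent-vector construction: a patch
keeps the central residue plus the closest n−1 surface residues whose
solvent vector (Cα − patch COM) lies within 110° of the central one.

**Class-balanced random forest.** Interface data is imbalanced (≈ 1 `O`
per 4.3 `N`), so K balanced forests are trained, each on all minority-class
residues plus an equal-size draw from the majority class (K = 1000 by
default; 500 Gini trees, 3 features per split).  Prediction is a majority
vote; a residue is `O` when more than half the members vote `O`.  Patch
aggregation reports size-7 patches whose central residue is predicted `O`
with at least 5 of 7 members predicted `O` — the high-precision operating
point for locating the ligand-binding sub-region.

## Worked example

The package ships a deterministic synthetic-fixture generator (pseudo
protein complexes with a concave interface pocket and a planted ligand)
so the whole pipeline runs without downloads:

```bash
smppi fixtures --kind pocket_complex --seed 1 -o fx1
smppi fixtures --kind pocket_complex --seed 2 -o fx2
printf 'pp_file\tpp_chain1\tpp_chain2\tpl_file\tpl_chain\tligand_code\n\
fx1/pp.pdb\tA\tB\tfx1/pl.pdb\tA\tLIG\nfx2/pp.pdb\tA\tB\tfx2/pl.pdb\tA\tLIG\n' > manifest.tsv
smppi pair manifest.tsv -o pairs
# -> 2 accepted, 2 after redundancy reduction; training table -> pairs.training.tsv

smppi train pairs.training.tsv -o model.joblib -k 10 --trees 200 --seed 0
# -> trained K=10 ensemble -> model.joblib

smppi fixtures --kind pocket_complex --seed 5 -o fx5
smppi predict model.joblib --pdb fx5/pp.pdb --chains A,B -o pred
# -> wrote residue predictions -> pred.residues.tsv
# -> wrote 5 binding patch(es) -> pred.patches.tsv
```

`pred.residues.tsv` holds one row per interface residue with the ensemble
vote fraction and `O`/`N` call; `pred.patches.tsv` lists the reported
binding patches, e.g.

```
central  members                                    complete
A:37     A:37,A:36,A:45,A:29,A:38,A:39,A:21        1
```

Here every reported patch is centred on a pocket-lining residue of the
held-out fixture — exactly the residues whose ground-truth label is `O`
in `fx5/overlap_truth.tsv` — so the predicted binding patches coincide
with the planted small-molecule site.

The same steps run on real structures: pass PDB files, a Consurf grade
file per chain (`--conservation grades.txt --dialect consurf_grades`),
and the chain pair of interest.

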