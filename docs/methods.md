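# Methods

## Model and procedure

The package chains two classifiers around a docking-derived contact count.

**Chemical-space stage.** The training substrate is a descriptor matrix
D = {(x_n, y_n)} with binary potency labels (inhibitor iff IC50 < 0.05 µM,
strict inequality; a label supplied in the input that contradicts the
derived one is an error, never silently preferred). Before training, three
filters run in a fixed order:

1. *sparsity* — drop columns whose fraction of exact zeros is > 0.85
   (exact 0.0 only; values are not rounded first);
2. *variance* — drop columns with sample SD (ddof = 1) < 0.03, read as an
   absolute threshold on raw descriptor values; a coefficient-of-variation
   reading is available via `FilterConfig(sd_relative=True)` since the
   convention is ambiguous for unnormalized descriptors;
3. *redundancy* — drop the later column of any pair with |Pearson ρ| >
   0.90. Absolute correlation is used (an anti-correlated duplicate is
   equally redundant); removal is greedy left-to-right, so the earlier
   column of a redundant pair always survives and a removed column cannot
   trigger further removals. All three thresholds are strict, so boundary
   columns survive; the chain is idempotent.

The order is load-bearing: the correlation filter requires positive
variance, which the variance stage guarantees.

Stacking follows the standard two-tier scheme. Folds are dealt
round-robin from a seeded permutation (sizes differ by ≤ 1; stratification
keeps per-fold class counts within 1 of proportionality). For each fold j
and base learner t, a fresh model trains on the complement and predicts
fold j, giving out-of-fold probabilities z_nt; the level-one data
(z_n1…z_nT, y_n) trains the super learner, a multilayer perceptron with
hidden layers (200, 400), Tanh activation and a 2-way softmax output
(class probabilities must sum to one; Tanh is specified only for the
hidden layers). Base-learner outputs enter as graded probabilities, not
hard labels — a weighted combination of hard votes would collapse the
meta-learner's input space. For deployment the base learners are refitted
on the full training matrix. The decision rule is probability ≥ 0.5, ties
to the positive class.

**Protein-space stage.** Ligands are encoded as substructure-count
vectors over a fixed 4860-pattern SMARTS library; the binary view is
count > 0. Match counting collapses automorphic matches on the same atom
set (configurable), since match-semantics conventions differ between
fingerprinting tools. The classifier is an MLP with hidden layers
(400, 200, 400), Tanh, softmax output, trained 50 epochs by minibatch SGD
(batch 32) under stratified fivefold CV, grid-searched over momentum,
rate annealing and input-dropout ratio; the winner is the highest mean CV
AUC, ties broken by mean accuracy then grid order, and is refitted on all
data. Counts are scaled by their global maximum before entering the Tanh
network. The input layer computes the affine map α = Σ w_i x_i + b; f(α)
denotes the positive-class probability.

**Contact profiling.** A docked complex (PDB; MODEL 1 only; first altloc;
waters excluded) is reduced to typed protein–ligand contacts:

| type | rule | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance | 2.0–4.1 Å (donor angle ≥ 100° when H present) |
| hydrophobic | apolar C – apolar C distance | ≤ 4.0 Å |
| salt bridge | opposite charged-group centroid distance | ≤ 5.5 Å |
| π-stacking | ring-centroid distance; interplanar angle | ≤ 5.5 Å; ≤ 30° or 60–90°; offset ≤ 2.5 Å |
| π-cation | ring centroid – cation distance | ≤ 6.0 Å |

Without explicit hydrogens, donor capability is inferred from heavy-atom
connectivity (N with < 4 heavy neighbours; O with ≤ 1). Charges come from
residue templates (Asp/Glu acidic; Lys/Arg/His basic) and the ligand's PDB
formal-charge column; there is no pKa model. Ligand rings are perceived
from a distance-inferred bond graph (5/6-cycles, planarity < 0.35 Å).
Each contact is reported once per (type, residue, ligand atom/ring);
hydrophobic contacts between a ring pair that also stacks are suppressed
in favour of the stacking record. d_i is the record count. Real PLIP
reports (XML or text) can be ingested instead; their water-bridge /
halogen-bond / metal categories map to an `other` type counted in d_i by
default.

**Ranking.** β = f(α) + d_i. Candidates are the classifier positives
(when truth labels are supplied — the published evaluation mode — only
true positives). Those with d_i inside the inclusive target window (9–12
CXCR4, 6–8 androgen receptor) are ranked by β descending, ties by higher
f(α) then lexicographic id; out-of-window candidates are listed after,
unranked. f(α) is the graded probability rather than a 0/1 label: a hard
label would make β degenerate (1 + d_i) inside the window and destroy the
re-ranking.

## Parameters that matter

| parameter | default | unit | note |
|---|---|---|---|
| potency cutoff | 0.05 | µM | strict `<` |
| zero-fraction cutoff | 0.85 | fraction | strict `>` |
| SD cutoff | 0.03 | descriptor units | strict `<`, ddof = 1 |
| correlation cutoff | 0.90 | \|ρ\| | strict `>` |
| CV folds | 10 (chemical), 5 (protein) | — | stratified |
| epochs | 50 | — | both networks |
| internal split | 10 % holdout | — | `70:30` option |
| window | (9, 12) / (6, 8) | contacts | inclusive, per target |
| contact cutoffs | table above | Å, degrees | `InteractionRules` |

Every stochastic step (fold draw, learner seeds, network init, generator
draws) takes an explicit integer seed recorded in run manifests.

## The substructure library

The 4860-pattern library is generated deterministically in code: a curated
block of organic functional-group SMARTS followed by enumerated bonded
pairs and reverse-deduplicated bonded triples over an organic alphabet,
truncated to exactly 4860 entries. It is a *synthetic* library with the
canonical fingerprint's dimensionality and contract (fixed order, stable
indices, every pattern a valid substructure query), not the original
redistributed pattern list; absolute counts therefore differ from other
implementations, while every dimensionality, ordering, monotonicity and
match-semantics property holds. Nothing downstream depends on specific
pattern identities.

## What the synthetic generators emulate — and what they do not

`gen_descriptor_matrix` plants class-shifted informative columns plus
sparse/constant/duplicated junk whose removal is known by construction;
real descriptor matrices have correlated blocks and heavier tails, so
passing the filter-recovery tests shows rule correctness, not robustness
to collinearity structure. `gen_fingerprint_dataset` draws Poisson counts
with class-raised rates in a few columns; real fingerprints have
pattern-hierarchy correlations the generator omits. `gen_complex` builds
geometric, not chemical, structures: each planted contact occupies an
isolated site 30 Å from the others with margins chosen so exactly one
rule fires (the salt-bridge site keeps only ~0.8 Å clearance over the
hydrogen-bond cutoff because the two cutoffs genuinely overlap). Passing
tests therefore demonstrate the profiler's rules and bookkeeping, not its
agreement with a physics-grade profiler on real poses — for that, ingest
a real PLIP report. `gen_study` sizes (120 training / 40 screening
molecules, separation 3.0) were chosen as the smallest study on which
both stages have clear signal.

## Numerical choices

- The diversity entropy is implemented as
  E = (1/N) Σ min(θ_i, T−θ_i)/(T − ⌈T/2⌉) — the standard non-pairwise
  diversity measure. A product reading min{θ_i(T−θ_i)} of the bracketed
  numerator is unbounded and contradicts E ∈ [0, 1].
- AUC is the rank-based Mann–Whitney statistic with ties at mid-rank
  (scikit-learn's implementation); tests verify it against brute-force
  pairwise comparison.
- Rate annealing maps onto SGD's inverse-scaling schedule
  (power_t = 0.5·(1 + min(1, rate·10⁴))); input dropout is emulated by a
  seeded Bernoulli mask applied to the training matrix, the closest
  available mechanism in the MLP backend.
- Probability 0.5 classifies as positive; equal-β ties rank by higher
  f(α), then id — all deterministic.
- Degenerate inputs fail loudly: single-class labels, non-finite
  descriptors, negative or fractional counts, zero-variance columns
  reaching the correlation filter, candidates without profiles.

## Known limitations

- The contact profiler is a simplified geometric re-implementation; it
  omits water bridges, halogen-bond sigma-hole angles, metal coordination
  and pKa-dependent protonation.
- The grid search defaults are minimal (one point); widen the grids in
  `PSModelConfig` for real studies.
- Binary classification only; no multiclass or regression potency models.
- Descriptor computation, 3D conformer generation, and docking are out of
  scope: descriptors arrive as CSV, complexes as PDB.
- Published benchmark figures on external compound collections (DUD-E
  sets) are not reproduced here; they require those datasets and the
  original descriptor/docking toolchain.
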