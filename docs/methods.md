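# Methods

This note records the models, parameter choices and known limitations of
`dynaglep`, in the order the pipeline runs.

## Contact-score state calls (ΔRRCS)

The contact score between two residues is the sum over their heavy-atom cross
pairs of a piecewise-linear kernel: a pair contributes 1 at distances ≤
`d_full` = 3.23 Å, 0 at ≥ `d_zero` = 4.63 Å, and `(d_zero − d)/(d_zero −
d_full)` between. Both constants are exposed in `RRCSKernelParams`.
Hydrogens are parsed but excluded (`is_heavy`), matching the heavy-atom
semantics of residue contacts. Contributions are summed with `math.fsum`, so
the score is exactly symmetric in its two arguments regardless of atom order.

Per frame, the scores of the four TM3–TM7 microswitch pairs are divided by the
reference (initial activated) conformation's scores. *Normalization is a
ratio, not a difference*: the activation threshold of 1 only makes sense on a
ratio scale. A difference mode exists behind a flag for exploratory use.
Pairs whose reference score is below ε = 1e-9 are flagged undefined rather
than divided.

Per-pair calls are strict: ratio > 1 favours active, < 1 inactive, exactly 1
is neutral and does not vote. The frame call is the majority over voting
pairs; an exact tie — including the reference frame itself, whose ratios are
all exactly 1 — is *intermediate*. The majority rule and the tie-break are
this package's choice; alternatives (e.g. requiring unanimity) can be built
from the per-pair calls, which are always returned.

Frame filtering runs three passes in a fixed order: (1) frames whose backbone
RMSD deviates from the trailing-window median by more than 5 window-MADs are
dropped (window 20 frames; frames earlier than one full window are kept —
there is no history to judge them against); (2) frames whose profile,
rounded to 3 decimals, duplicates an earlier frame's are dropped (the earlier
frame_id wins); (3) an optional user-supplied pocket filter (e.g. a
pocket-volume consistency check) is applied last — no volume algorithm is
built in because none is canonical.

Representative selection deduplicates rounded profiles, splits the target
count across frame-call groups proportionally to group size
(largest-remainder rounding; every nonempty group gets a slot when the budget
allows), and within each group runs greedy farthest-point sampling in
normalized-profile space seeded at the group's lowest frame_id. Ties in the
farthest-point step resolve to the lowest index, so selection is fully
deterministic and idempotent on an already-selected set. Whether real
"nonredundant snapshot" selections used clustering or uniqueness of contact
patterns is not specifiable from published protocols; this deterministic
procedure is one admissible reading, and published selection counts are not
treated as targets.

## Superposition and PCA

Kabsch superposition uses `scipy`'s SVD solver (proper rotations only; the
determinant correction excludes reflections, so a chiral partner keeps RMSD >
0). The residual RMSD is recomputed from the aligned coordinates rather than
taken from the solver's accumulated residual, which carries ~1e-7
cancellation noise. Inputs with fewer than 3 points or collinear point sets
are rejected.

PCA operates on the Kabsch-aligned, flattened Cα matrix (n frames × 3N),
mean-centered, covariance with the (n − 1) denominator; EVR = eigenvalue /
total variance. Component signs are fixed by making each component's
largest-magnitude loading positive, so projections are reproducible across
runs and libraries. PCA is run per state ensemble, not jointly. Published
EVR values from real MD trajectories depend on those trajectories and are not
reproduction targets.

## Complex graphs

Protein nodes are residue-level and sit at the Cα; ligand atoms are nodes;
each aromatic ring (smallest-set-of-smallest-rings over atoms flagged
aromatic) contributes a virtual node at its unweighted centroid, tied to its
member atoms by structural `ring_member` edges. Geometric edges connect
nodes within per-kind-pair cutoffs — 8.0 Å for Cα–Cα protein adjacency,
4.5 Å otherwise — with distances binned at 0.5 Å; the pocket is every residue
with a heavy atom within 8.0 Å of the ligand (closed interval). All cutoffs
are config. The built-in interaction detector is deliberately minimal
(H-bond ≤ 3.5 Å with D–H···A ≥ 120° when the hydrogen is available; π–π
centroid ≤ 5.5 Å; cation–π ≤ 6.0 Å; salt bridge ≤ 4.0 Å) and can be replaced
by an externally supplied interaction list. Ligands enter as explicit
atom/bond/aromaticity tables; SMILES perception via RDKit is a convenience
wrapper, not a core dependency.

## Equivariant scorer

Each of T = 3 blocks runs (i) multi-head (4) self-attention restricted to
graph neighbourhoods plus a self-loop, with an additive logit bias projected
from the current edge features; (ii) the equivariant message/coordinate/node
updates given in the README, with φ_e, φ_x, φ_h as small ReLU MLPs (φ_h
residual, φ_x scalar-output with small-scale final-layer init for coordinate
stability); (iii) an edge update that maps the per-edge attention weights
through two projections and adds them residually. Hidden width D = 64, edge
width E = 16 by default (tests use smaller widths). Readout is mean pooling
over ligand + virtual nodes; the pooled vector (dimension = D) is the
penultimate feature, followed by a 32-unit head.

Because coordinates influence invariant quantities only through pairwise
distances, and the coordinate stream is updated by weighted difference
vectors, scores and penultimate features are E(3)-invariant and coordinates
E(3)-equivariant; with φ_x ≡ 0 the block reduces to an invariant-feature GNN.
The network runs on a compact reverse-mode autodiff core written for this
package (float64 internally; public tolerances quoted at 1e-5, i.e.
32-bit-equivalent). Analytic gradients are validated against central
differences (relative error ≤ 1e-4) in the test suite. No pretrained weights
are shipped: "transfer learning" is realized by pretraining the trunk on a
synthetic docking-score regression task, freezing it (head-only training is
the default; full fine-tuning is a flag) and extracting penultimate features.

## Efficacy models and metrics

Agonist iff Emax > 50% (strict; 50% exactly is a nonagonist; values above
100% — superagonists — are allowed). The transfer-learning head is a
64–32–1 MLP with ReLU/ReLU/sigmoid trained by Adam on binary cross-entropy,
batch 32, 25 epochs, five repetitions at seeds base+0…base+4, reported as
mean ± SD; it is realized with scikit-learn's `MLPClassifier`, whose binary
log-loss with a logistic output unit is exactly that objective.

Score-based baselines adopt the orientation *lower docking score against the
active structure ⇒ more agonist-like* (flag to flip; the choice only reflects
AUC about 0.5). The two-state baseline ranks by the active−inactive score
difference, more negative being more agonist-like. The dynamic baseline is a
random forest over the per-ligand vector of scores across all conformations,
evaluated out-of-fold.

AUC is the midrank Mann–Whitney statistic — identical to the ROC integral in
the continuous case and exact under ties; the test suite checks it against an
O(n²) pair-count oracle. ACC/MCC/precision/recall come from confusion counts
at threshold 0.5; MCC's zero-denominator case is defined as 0 (tested).
Welch's unequal-variance t-test is used for per-state score comparisons; the
degenerate two-constant-samples case returns p = 1. Cross-validation is
3-fold, either randomized or scaffold-based: single-linkage clusters at
Tanimoto ≥ 0.4 (ECFP-style bit vectors), clusters assigned whole to the
currently smallest fold, so a scaffold never spans folds. Fold-pooled and
per-fold-averaged AUCs are both reported, since either aggregation is
defensible.

## Synthetic data: what it emulates, and what it does not

`gen_two_state_ensemble` builds a toy receptor: two strands of Cα atoms far
from each other, plus one dedicated proxy heavy atom per contact-pair
membership, placed symmetrically about well-separated anchors so every pair
distance is controlled independently. Active frames hold the designated
pairs at 3.4 Å (strong contact), inactive frames at 3.4 Å + displacement
(2.0 Å default, breaking the contact), and the reference conformation at
3.9 Å — slightly looser than the active frames, as an initial structure
typically is relative to a relaxed trajectory — so active-frame ratios sit
clearly above 1 rather than straddling it. Isotropic Gaussian noise
(0.1 Å default) models thermal fluctuation. This captures the *signal
structure* of activation microswitches, not protein geometry: no backbone
connectivity constraints, no correlated motions, no pocket. Passing state
recovery here shows the calling logic is correct, not that real trajectories
are this clean.

`gen_score_table` draws Normal scores whose per-class per-state means/SDs
default to the published serotonin (−6.53 ± 0.55 active, −6.02 ± 0.66
inactive) and methiothepin (−4.95 ± 0.55 active, −5.36 ± 0.79 inactive)
kcal/mol values, with 200 conformations per state. Normality is the minimal
assumption consistent with the published box distributions and is
config-replaceable.

`gen_feature_ensemble` plants the class signal in one of two modes.
*uniform-signal*: a ±δ/2 class shift along a per-block random direction —
any single block separates the classes. *state-contrast*: the shift has
opposite sign in active and inactive blocks and rides on a shared per-ligand
nuisance (SD 3, the overall-affinity analogue) along the same axis; a
single-state model sees signal buried in nuisance, while comparing states
cancels the nuisance and doubles the signal. This is the construction behind
the dynamic-over-static comparison: it encodes the *mechanistic claim* that
efficacy lives in the contrast between states, and the advantage measured on
it (≈ 0.4 AUC at δ = 2) quantifies that construction, not any real dataset.
δ = 2 (in within-block feature-SD units) is the default "strong but not
trivial" effect; δ = 0 gives an exact null.

`gen_fingerprints` plants scaffold clusters on disjoint bit blocks (90% core
bit retention), giving within-cluster Tanimoto ≈ 0.8 and between-cluster 0.

## Problem sizes and determinism

Default test/workflow sizes — 40–200 frames per state, 120 ligands, 8
conformation blocks, feature dimension 16, scorer widths 16–64 — were chosen
so every component's statistical behaviour is measurable at desk scale;
generators scale to larger sizes by spec. All randomness flows through
`numpy.random.default_rng` seeds carried in the generator parameter
dataclasses; identical parameters produce bit-identical outputs, and the pipeline manifest records the
config hash and seed of each run.

## Known limitations

- The toy receptor has no real geometry; RRCS kernel constants are taken
  from the cited contact-score literature, not refit.
- The built-in interaction detector ignores protonation, tautomers and
  aromatic-plane angles; supply an external interaction list for real
  complexes.
- The scorer is desk-scale and CPU-bound; it is not a reimplementation of
  any published pretrained scorer, and its penultimate dimension (= hidden
  width) is a free parameter.
- Multi-class efficacy (partial/inverse agonism) and probability calibration
  are out of scope.
- mmCIF and binary trajectory formats (XTC/DCD) are not read; convert to
  multi-model PDB upstream (a converter hook is the documented extension
  point).
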