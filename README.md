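# dynaglep

Dynamics-aware prediction of GPCR ligand efficacy (agonist vs nonagonist).

Class A G protein–coupled receptors exist in an equilibrium of active and
inactive conformations, and whether a ligand *activates* the receptor — its
efficacy, summarized by Emax, the maximal response relative to a full agonist —
depends on which conformations it stabilizes. A single docking score against
one crystal structure cannot see this. `dynaglep` implements a
dynamics-aware workflow:

1. **State calls from contact scores.** For a conformational ensemble (e.g.
   MD snapshots), the residue–residue contact score (RRCS) of a small set of
   TM3–TM7 activation-microswitch pairs (`3x43–7x49`, `3x43–7x53`, `3x46–7x53`,
   `3x50–7x53` in Ballesteros–Weinstein numbering) is computed per frame with a
   piecewise-linear heavy-atom distance kernel (full contact ≤ 3.23 Å, zero
   ≥ 4.63 Å) and normalized to a reference activated conformation. Ratios
   above 1 favour the active arrangement, below 1 the inactive one; a majority
   over the pairs calls each frame active / inactive / intermediate.
2. **Representative-conformer selection** — deduplication plus
   state-stratified farthest-point sampling in the normalized contact-score
   space — and **Cα PCA** (Kabsch alignment, explained-variance ratios,
   PC1–PC2 maps) to visualize coverage of the conformational landscape.
3. **Heterogeneous complex graphs** G = (V, E_geometric, E_structural) with
   protein (residue/Cα), ligand-atom and aromatic-ring-centroid virtual nodes;
   distance-binned geometric edges (incl. Cα–Cα protein adjacency) and
   covalent/interaction-fingerprint structural edges.
4. **An E(3)-equivariant message-passing scorer** whose blocks stack
   neighbourhood-masked attention with edge bias, the equivariant updates

       m_ij = φ_e(h_i, h_j, ‖x_i − x_j‖, a_ij)
       x_i' = x_i + Σ_{j≠i} (x_i − x_j) φ_x(m_ij)
       m_i  = Σ_{j∈N(i)} m_ij
       h_i' = φ_h(h_i, m_i)

   and a projection-based edge update. The pooled pre-head representation
   ("penultimate feature") is extracted per complex.
5. **Transfer-learning efficacy classification**: per ligand, penultimate
   features across the selected conformations are concatenated and fed to a
   64–32–1 MLP (ReLU/ReLU/sigmoid; Adam, binary cross-entropy, batch 32,
   25 epochs; five seeded repetitions reported as mean ± SD). Ligands are
   labelled agonist iff Emax > 50%. Baselines cover single-state docking-score
   ranking, active–inactive score differences, and a random forest over the
   full per-conformation score vector; evaluation uses AUC (midrank
   Mann–Whitney), ACC, MCC, precision and recall under random or
   Tanimoto-scaffold 3-fold cross-validation.

Every upstream input that would normally come from MD, a docking engine or a
pretrained scorer can be emulated by the seeded generators in
`dynaglep.synthdata`, so the whole workflow runs end-to-end with no external
data.

## Worked example

```python
from dynaglep import synthdata, rrcs, efficacy

# two-state ensemble with known ground truth (40 frames/state, 0.2 Å noise)
ts = synthdata.gen_two_state_ensemble(
    synthdata.TwoStateEnsembleSpec(n_frames=40, noise_sd=0.2, seed=0))
merged, truth = ts.merged()
profile = rrcs.delta_rrcs(merged, ts.pairs, ts.reference, ts.bw_map)
calls = rrcs.call_state(profile)
print("state-call accuracy:", (calls.frame_call == truth).mean())

# per-state docking-score significance for the two reference ligands
samples = synthdata.gen_reference_ligand_scores(n_per_state=200, seed=1)
for name in ("serotonin", "methiothepin"):
    t, p = efficacy.welch_test(samples[name]["active"], samples[name]["inactive"])
    print(f"{name}: Welch t = {t:.2f}, p = {p:.2e}")
```

prints

```
state-call accuracy: 0.975
serotonin: Welch t = -8.88, p = 2.47e-17
methiothepin: Welch t = 7.48, p = 6.34e-13
```

— nearly every frame's activation state is recovered from the contact-score
profile even at 0.2 Å coordinate noise,
and both reference ligands discriminate their preferred receptor state far
below the p < .05 level (serotonin, a full agonist with Emax 100%, docks
better against active conformations; methiothepin, Emax 10%, against inactive
ones).

The full pipeline (`dynaglep run --seed 1 --out run/`) writes per-stage
outputs (`profile.csv`, `selection.csv`, `pca.csv`/`pca.svg`, `metrics.json`)
plus a manifest with the config hash, and is bit-reproducible under a fixed
config and seed.

## Command-line interface

`dynaglep` exposes subcommands `io validate`, `rrcs`, `select-conformers`,
`pca`, `graph`, `score`, `evaluate`, `baselines`, `simulate` and `run`; see
`dynaglep --help`. CSV/TSV schemas (BW mapping, ligand tables, score tables,
profiles) are documented in the module docstrings of
`dynaglep.conformers_io` and `dynaglep.efficacy`.
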