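"""Seeded generators emulating the upstream inputs of the efficacy pipeline.

Three kinds of synthetic input stand in for what would otherwise require
molecular-dynamics trajectories, a docking engine and a pretrained scorer:

* **two-state receptor ensembles** — toy Cα/side-chain-proxy geometries where
  designated activation-microswitch residue pairs are in contact in the active
  state and displaced apart in the inactive one, with Gaussian coordinate
  noise; the reference ("initial activated") conformation carries a slightly
  looser contact than the active frames so that contact ratios of active frames
  sit clearly above 1;
* **docking-score tables** — Normal score distributions whose per-class,
  per-state means and SDs default to the published serotonin / methiothepin
  ensemble-docking values (agonists score better against active conformations,
  nonagonists against inactive ones);
* **feature ensembles** — per-ligand, per-conformation feature blocks with a
  tunable class signal: either a uniform mean shift in every block, or a
  state-contrast signal (opposite sign in active vs inactive blocks, riding on
  a large per-ligand nuisance) that rewards models which compare states.

Every generator is a pure function of its spec, seed included.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformers_io import BWMap, ConformationEnsemble, Frame
from .efficacy import DockingScoreTable, FeatureEnsemble
from .rrcs import DEFAULT_PAIRS, ResiduePairSpec

#: published per-state ensemble-docking score distributions (kcal/mol): the
#: full agonist serotonin (Emax 100%) scores better against active
#: conformations, the nonagonist methiothepin (Emax 10%) against inactive ones.
REFERENCE_LIGAND_SCORES = {
    "serotonin": {"emax": 100.0, "active": (-6.53, 0.55), "inactive": (-6.02, 0.66)},
    "methiothepin": {"emax": 10.0, "active": (-4.95, 0.55), "inactive": (-5.36, 0.79)},
}


# ---------------------------------------------------------------------------
# two-state receptor ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateEnsembleSpec:
    n_frames: int = 200            # per state, matching 200 active + 200 inactive
    n_residues: int = 24           # split across two strands (TM3-like / TM7-like)
    contact_pairs: tuple = DEFAULT_PAIRS
    contact_distance: float = 3.4  # Å between pair proxy atoms in active frames
    reference_distance: float = 3.9  # Å in the reference conformation
    displacement: float = 2.0      # Å added to the pair distance in inactive frames
    noise_sd: float = 0.1          # Å isotropic Gaussian noise per atom
    seed: int = 0

    def __post_init__(self):
        if self.displacement <= 0 and self.noise_sd == 0:
            raise ValueError("displacement must be positive (or allow noise)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TwoStateEnsembles:
    active: ConformationEnsemble
    inactive: ConformationEnsemble
    reference: Frame
    bw_map: BWMap
    pairs: list[ResiduePairSpec]

    def merged(self) -> tuple[ConformationEnsemble, np.ndarray]:
        """Single ensemble (active frames first) plus ground-truth state array."""
        frames = []
        for i, fr in enumerate(self.active.frames + self.inactive.frames):
            fr2 = Frame(i, fr.atom_name, fr.element, fr.residue_seq, fr.chain,
                        fr.res_name, fr.coords)
            frames.append(fr2)
        truth = np.array(["active"] * len(self.active) + ["inactive"] * len(self.inactive))
        return ConformationEnsemble(frames, state_tag="unknown", source="synthetic"), truth


def _toy_layout(spec: TwoStateEnsembleSpec):
    """Residue labels, BW map and the static coordinate template.

    Strand A residues carry TM3-style labels (3x40, 3x41, …), strand B TM7-style
    labels (7x45, 7x46, …).  Each residue has a Cα far from every contact zone;
    each contact pair gets a dedicated proxy heavy atom on both partners, placed
    symmetrically about a well-separated per-pair anchor so pair distances are
    controlled independently.
    """
    n_a = spec.n_residues // 2
    n_b = spec.n_residues - n_a
    labels = [f"3x{40 + i}" for i in range(n_a)] + [f"7x{45 + i}" for i in range(n_b)]
    label_to_res = {lab: ("A", 100 + i) for i, lab in enumerate(labels)}
    bw_map = BWMap([(c, s, lab) for lab, (c, s) in label_to_res.items()])
    pairs = [ResiduePairSpec(a, b) for a, b in spec.contact_pairs]
    for p in pairs:
        for lab in (p.bw_a, p.bw_b):
            if lab not in bw_map:
                raise ValueError(
                    f"pair residue {lab} not in the toy receptor; increase n_residues")

    atom_name, element, residue_seq, res_name = [], [], [], []
    coords = []
    pair_atom_rows: list[tuple[int, int]] = []  # (row of a-side atom, row of b-side atom)
    for i, lab in enumerate(labels):
        _, seq = label_to_res[lab]
        strand = 1.0 if lab.startswith("3x") else -1.0
        atom_name.append("CA")
        element.append("C")
        residue_seq.append(seq)
        res_name.append("ALA")
        coords.append([4.0 * i, strand * 40.0, 0.0])
    for p_idx, p in enumerate(pairs):
        anchor_x = 200.0 + 30.0 * p_idx
        rows = []
        for side, lab in enumerate((p.bw_a, p.bw_b)):
            _, seq = label_to_res[lab]
            atom_name.append(f"CP{p_idx}")
            element.append("C")
            residue_seq.append(seq)
            res_name.append("ALA")
            sign = 1.0 if side == 0 else -1.0
            coords.append([anchor_x, sign * 0.5, 0.0])  # half-distance filled in later
            rows.append(len(coords) - 1)
        pair_atom_rows.append(tuple(rows))
    chain = np.array(["A"] * len(atom_name))
    template = np.asarray(coords, dtype=float)
    return (labels, bw_map, pairs,
            np.array(atom_name), np.array(element),
            np.array(residue_seq, dtype=int), chain, np.array(res_name),
            template, pair_atom_rows)


def gen_two_state_ensemble(spec: TwoStateEnsembleSpec = TwoStateEnsembleSpec()
                           ) -> TwoStateEnsembles:
    """Active and inactive toy ensembles with known per-frame ground truth."""
    (labels, bw_map, pairs, atom_name, element, residue_seq, chain, res_name,
     template, pair_rows) = _toy_layout(spec)
    rng = np.random.default_rng(spec.seed)

    def _frame(pair_distance: float, frame_id: int, noisy: bool) -> Frame:
        c = template.copy()
        for ra, rb in pair_rows:
            c[ra, 1] = +pair_distance / 2
            c[rb, 1] = -pair_distance / 2
        if noisy and spec.noise_sd > 0:
            c = c + rng.normal(0, spec.noise_sd, c.shape)
        return Frame(frame_id, atom_name, element, residue_seq, chain, res_name, c)

    reference = _frame(spec.reference_distance, -1, noisy=False)
    active_frames = [_frame(spec.contact_distance, i, noisy=True)
                     for i in range(spec.n_frames)]
    inactive_frames = [_frame(spec.contact_distance + spec.displacement, i, noisy=True)
                       for i in range(spec.n_frames)]
    return TwoStateEnsembles(
        active=ConformationEnsemble(active_frames, state_tag="active", source="synthetic"),
        inactive=ConformationEnsemble(inactive_frames, state_tag="inactive", source="synthetic"),
        reference=reference, bw_map=bw_map, pairs=pairs,
    )


# ---------------------------------------------------------------------------
# docking-score tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTableSpec:
    n_ligands_per_class: int = 20
    n_conformations_per_state: int = 200
    agonist_active: tuple[float, float] = REFERENCE_LIGAND_SCORES["serotonin"]["active"]
    agonist_inactive: tuple[float, float] = REFERENCE_LIGAND_SCORES["serotonin"]["inactive"]
    nonagonist_active: tuple[float, float] = REFERENCE_LIGAND_SCORES["methiothepin"]["active"]
    nonagonist_inactive: tuple[float, float] = REFERENCE_LIGAND_SCORES["methiothepin"]["inactive"]
    seed: int = 0

    def __post_init__(self):
        for mu, sd in (self.agonist_active, self.agonist_inactive,
                       self.nonagonist_active, self.nonagonist_inactive):
            if sd <= 0:
                raise ValueError("score SDs must be positive")


def gen_score_table(spec: ScoreTableSpec = ScoreTableSpec()
                    ) -> tuple[DockingScoreTable, np.ndarray]:
    """Normal docking scores per ligand × conformation, plus binary labels.

    Agonists follow the serotonin pattern (better scores against active
    conformations); nonagonists the methiothepin pattern (better against
    inactive ones).
    """
    rng = np.random.default_rng(spec.seed)
    n_c = spec.n_conformations_per_state
    states = np.array(["active"] * n_c + ["inactive"] * n_c)
    conf_ids = [f"{s}_{i}" for s in ("active", "inactive") for i in range(n_c)]
    rows, labels, ligand_ids = [], [], []
    for cls, (p_act, p_inact) in (
            (1, (spec.agonist_active, spec.agonist_inactive)),
            (0, (spec.nonagonist_active, spec.nonagonist_inactive))):
        for i in range(spec.n_ligands_per_class):
            act = rng.normal(p_act[0], p_act[1], n_c)
            inact = rng.normal(p_inact[0], p_inact[1], n_c)
            rows.append(np.concatenate([act, inact]))
            labels.append(cls)
            ligand_ids.append(f"{'ago' if cls else 'nonago'}_{i}")
    table = DockingScoreTable(ligand_ids, conf_ids, states, np.vstack(rows))
    return table, np.asarray(labels, dtype=int)


def gen_reference_ligand_scores(n_per_state: int = 200, seed: int = 0) -> dict:
    """Per-state score samples for the two published reference ligands."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, params in REFERENCE_LIGAND_SCORES.items():
        out[name] = {
            state: rng.normal(*params[state], n_per_state)
            for state in ("active", "inactive")
        }
        out[name]["emax"] = params["emax"]
    return out


# ---------------------------------------------------------------------------
# feature ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureEnsembleSpec:
    n_ligands: int = 120           # balanced classes
    n_conformations: int = 8       # first half active, second half inactive
    feature_dim: int = 16
    delta: float = 2.0             # class-mean separation in feature-SD units
    mode: str = "uniform-signal"   # or "state-contrast"
    nuisance_sd: float = 3.0       # per-ligand affinity nuisance (state-contrast mode)
    seed: int = 0

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.mode not in ("uniform-signal", "state-contrast"):
            raise ValueError("mode must be 'uniform-signal' or 'state-contrast'")


def gen_feature_ensemble(spec: FeatureEnsembleSpec = FeatureEnsembleSpec()
                         ) -> FeatureEnsemble:
    """Labelled per-ligand, per-conformation feature blocks with a planted signal.

    ``uniform-signal``: each conformation block carries a class-mean shift of
    ±δ/2 along a block-specific random unit direction — any single block
    separates the classes.

    ``state-contrast``: the shift is applied with opposite sign in active and
    inactive blocks, and every block additionally carries a shared per-ligand
    nuisance (overall-affinity analogue, SD ``nuisance_sd``) along the same
    direction.  A model looking at one state's block sees the signal buried in
    nuisance; comparing states cancels the nuisance and doubles the signal —
    the construction that rewards multi-conformation concatenation.
    """
    rng = np.random.default_rng(spec.seed)
    n, c, p = spec.n_ligands, spec.n_conformations, spec.feature_dim
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    labels = rng.permutation(labels)
    states = np.array(["active"] * (c // 2) + ["inactive"] * (c - c // 2))
    feats = rng.normal(0, 1.0, (n, c, p))
    directions = rng.normal(0, 1.0, (c, p))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    sign_cls = np.where(labels == 1, 1.0, -1.0)
    if spec.mode == "uniform-signal":
        for j in range(c):
            feats[:, j, :] += np.outer(sign_cls * spec.delta / 2, directions[j])
    else:
        u = directions[0]  # one shared axis so nuisance and signal compete
        nuisance = rng.normal(0, spec.nuisance_sd, n)
        for j in range(c):
            sign_state = 1.0 if states[j] == "active" else -1.0
            shift = nuisance + sign_cls * sign_state * spec.delta / 2
            feats[:, j, :] += np.outer(shift, u)
    ligand_ids = [f"lig_{i}" for i in range(n)]
    return FeatureEnsemble(ligand_ids, feats, states, labels)


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def gen_fingerprints(n: int, n_clusters: int = 3, bits: int = 192, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Binary fingerprints with planted cluster structure.

    Clusters occupy disjoint bit blocks, so between-cluster Tanimoto similarity
    is 0; within a cluster members share ~90% of the block's core bits, keeping
    within-cluster similarity comfortably above 0.6.  Returns (fingerprints,
    cluster labels).
    """
    if n < n_clusters:
        raise ValueError("need n >= n_clusters")
    block = bits // n_clusters
    if block < 16:
        raise ValueError("too few bits per cluster; increase bits")
    rng = np.random.default_rng(seed)
    assignments = np.arange(n) % n_clusters
    assignments = rng.permutation(assignments)
    fps = np.zeros((n, bits), dtype=np.uint8)
    for i in range(n):
        c = assignments[i]
        lo = c * block
        keep = rng.random(block) < 0.9
        fps[i, lo:lo + block] = keep.astype(np.uint8)
        if fps[i].sum() == 0:
            fps[i, lo] = 1
    return fps, assignments
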