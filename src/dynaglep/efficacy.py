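"""Efficacy labeling, multi-conformation classifiers, baselines, splits and metrics.

Ligands are labelled from their maximal functional response: **agonist** when
Emax > 50%, **nonagonist** otherwise (strict threshold; exactly 50% is a
nonagonist).  The transfer-learning classifier consumes, per ligand, the
concatenation of pooled complex representations across an ordered set of
receptor conformations and feeds them to a 64–32–1 MLP (ReLU/ReLU/sigmoid,
Adam, binary cross-entropy, batch 32, 25 epochs), repeated five times with
shifted seeds to report mean ± SD.

Baselines mirror the static / dynamic hierarchy used in ensemble-docking
studies: ranking by a single active- or inactive-state docking score, ranking
by the active–inactive score difference, and a random forest over the full
per-conformation score vector.

AUC is computed by the midrank Mann–Whitney statistic (exact tie handling,
identical to the TPR–FPR integral in the continuous case); ACC, MCC, precision
and recall come from confusion counts at a 0.5 threshold, with the MCC's
zero-denominator case defined as 0.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)

EMAX_AGONIST_THRESHOLD = 50.0  # % of full-agonist response


# ---------------------------------------------------------------------------
# records and containers
# ---------------------------------------------------------------------------

@dataclass
class LigandRecord:
    ligand_id: str
    emax: float
    fingerprint: np.ndarray | None = None
    smiles: str | None = None

    @property
    def label(self) -> str:
        return "agonist" if self.emax > EMAX_AGONIST_THRESHOLD else "nonagonist"

    @property
    def y(self) -> int:
        return int(self.emax > EMAX_AGONIST_THRESHOLD)


def label_from_emax(emax: float) -> str:
    """Agonist iff Emax strictly exceeds 50% of the full-agonist response."""
    if emax is None or (isinstance(emax, float) and np.isnan(emax)):
        raise ValueError("missing Emax; exclude the record upstream")
    if emax < 0:
        raise ValueError("Emax must be non-negative")
    return "agonist" if emax > EMAX_AGONIST_THRESHOLD else "nonagonist"


def load_ligand_table(path) -> list[LigandRecord]:
    """Read ligands.csv (ligand_id, emax, optional smiles / fingerprint hex)."""
    df = pd.read_csv(path, dtype={"ligand_id": str})
    records = []
    for _, row in df.iterrows():
        if pd.isna(row.get("emax")):
            logger.info("ligand %s dropped: missing Emax", row.get("ligand_id"))
            continue
        fp = None
        if "fingerprint" in df.columns and not pd.isna(row["fingerprint"]):
            raw = bytes.fromhex(str(row["fingerprint"]))
            fp = np.unpackbits(np.frombuffer(raw, dtype=np.uint8))
        records.append(LigandRecord(str(row["ligand_id"]), float(row["emax"]),
                                    fingerprint=fp,
                                    smiles=row.get("smiles") if "smiles" in df.columns else None))
    return records


@dataclass
class DockingScoreTable:
    """Ligands × conformations docking scores (kcal/mol, lower = better)."""

    ligand_ids: list[str]
    conformation_ids: list[str]
    states: np.ndarray             # per-conformation "active" / "inactive"
    scores: np.ndarray             # (n_ligands, n_conf), NaN = missing

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.states = np.asarray(self.states)
        if self.scores.shape != (len(self.ligand_ids), len(self.conformation_ids)):
            raise ValueError("scores shape must be (n_ligands, n_conformations)")
        if len(self.states) != len(self.conformation_ids):
            raise ValueError("one state tag per conformation required")

    def state_scores(self, ligand_idx: int, state: str) -> np.ndarray:
        col = self.states == state
        vals = self.scores[ligand_idx, col]
        return vals[~np.isnan(vals)]

    @classmethod
    def from_long_csv(cls, path) -> "DockingScoreTable":
        """Read scores.csv with columns ligand_id, conformation_id, state, score."""
        df = pd.read_csv(path, dtype={"ligand_id": str, "conformation_id": str})
        ligand_ids = list(dict.fromkeys(df["ligand_id"]))
        conf = df.drop_duplicates("conformation_id")
        conf_ids = list(conf["conformation_id"])
        states = conf.set_index("conformation_id")["state"]
        mat = np.full((len(ligand_ids), len(conf_ids)), np.nan)
        li = {l: i for i, l in enumerate(ligand_ids)}
        ci = {c: j for j, c in enumerate(conf_ids)}
        for _, row in df.iterrows():
            mat[li[row["ligand_id"]], ci[row["conformation_id"]]] = row["score"]
        return cls(ligand_ids, conf_ids, states.loc[conf_ids].to_numpy(), mat)


@dataclass
class FeatureEnsemble:
    """Per-ligand penultimate features across an ordered conformation set."""

    ligand_ids: list[str]
    features: np.ndarray          # (n_ligands, n_conformations, P)
    conformation_states: np.ndarray   # per-conformation state tags
    labels: np.ndarray            # 1 = agonist

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 3:
            raise ValueError("features must be (n_ligands, n_conformations, P)")
        if len(self.conformation_states) != self.features.shape[1]:
            raise ValueError("one state tag per conformation required")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("one label per ligand required")


def concat_features(fe: FeatureEnsemble) -> np.ndarray:
    """Flatten each ligand's conformation blocks in the recorded order → (n, n_conf·P)."""
    n, c, p = fe.features.shape
    return fe.features.reshape(n, c * p)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    auc: float
    acc: float
    mcc: float
    precision: float
    recall: float
    confusion: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        return {"auc": self.auc, "acc": self.acc, "mcc": self.mcc,
                "precision": self.precision, "recall": self.recall}


def auc_score(scores, labels) -> float:
    """ROC AUC via the midrank Mann–Whitney statistic (exact tie handling)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews correlation; the degenerate zero-denominator case is defined as 0."""
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return float((c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom))


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """AUC, ACC, MCC, precision and recall from scores against binary labels."""
    c = confusion_counts(scores, labels, threshold)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    acc = (c.tp + c.tn) / c.total if c.total else 0.0
    return MetricsReport(auc=auc_score(scores, labels), acc=acc,
                         mcc=mcc_from_counts(c), precision=precision,
                         recall=recall, confusion=c)


def summarize_reports(reports: list[MetricsReport]) -> dict:
    """Mean ± SD of each metric over repetitions."""
    out = {}
    for key in ("auc", "acc", "mcc", "precision", "recall"):
        vals = np.array([getattr(r, key) for r in reports])
        out[key] = {"mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "values": vals.tolist()}
    return out


# ---------------------------------------------------------------------------
# statistical test
# ---------------------------------------------------------------------------

def welch_test(samples_a, samples_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test, (t, p).

    The degenerate case of two zero-variance samples with equal means returns
    (0, 1) rather than NaN.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# baseline classifiers
# ---------------------------------------------------------------------------

def static_classifier(scores, orientation: str = "active") -> np.ndarray:
    """Ranking scores from single-conformation docking scores.

    Under the default orientation a lower (better) docking score against the
    active structure ranks the ligand as more agonist-like, so the ranking
    score is the negated docking score; ``orientation="inactive"`` flips it.
    """
    scores = np.asarray(scores, dtype=float)
    if orientation not in ("active", "inactive"):
        raise ValueError("orientation must be 'active' or 'inactive'")
    return -scores if orientation == "active" else scores.copy()


def two_states_classifier(score_active, score_inactive) -> np.ndarray:
    """Ranking by Δ = score_active − score_inactive; more negative = agonist-like.

    Returned as −Δ so that higher ranking score means more agonist-like,
    consistent with every other classifier in the module.
    """
    delta = np.asarray(score_active, dtype=float) - np.asarray(score_inactive, dtype=float)
    return -delta


def rf_ensemble_classifier(table: DockingScoreTable, labels, plan: "SplitPlan",
                           seed: int = 0, n_estimators: int = 200) -> np.ndarray:
    """Out-of-fold RF probabilities from the per-ligand conformation-score vector."""
    X = table.scores.copy()
    labels = np.asarray(labels).astype(int)
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing conformation columns",
                      stacklevel=2)
        X = X[:, ~all_missing]
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    if len(np.unique(labels)) < 2:
        raise ValueError("RF baseline requires both classes")
    prob = np.full(len(labels), np.nan)
    for fold in range(plan.k):
        test = plan.folds == fold
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        rf.fit(X[~test], labels[~test])
        prob[test] = rf.predict_proba(X[test])[:, list(rf.classes_).index(1)]
    return prob


# ---------------------------------------------------------------------------
# transfer-learning head
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TLConfig:
    """Prediction-head hyperparameters (64–32–1 MLP, Adam, BCE)."""

    hidden: tuple[int, int] = (64, 32)
    batch_size: int = 32
    epochs: int = 25
    n_repetitions: int = 5
    learning_rate: float = 1e-3


def train_tl_head(features: np.ndarray, labels, seed: int = 0,
                  config: TLConfig = TLConfig()) -> MLPClassifier:
    """Train the sigmoid-output MLP head on concatenated conformation features."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes present")
    clf = MLPClassifier(hidden_layer_sizes=config.hidden, activation="relu",
                        solver="adam", batch_size=min(config.batch_size, len(labels)),
                        max_iter=config.epochs, learning_rate_init=config.learning_rate,
                        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(features, labels)
    return clf


def predict_tl(clf: MLPClassifier, features: np.ndarray) -> np.ndarray:
    """Probability of the agonist class for each row."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != clf.n_features_in_:
        raise ValueError(f"feature dim {features.shape[1]} != trained dim {clf.n_features_in_}")
    return clf.predict_proba(features)[:, list(clf.classes_).index(1)]


# ---------------------------------------------------------------------------
# split strategies
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    folds: np.ndarray      # fold id per ligand, 0..k-1
    strategy: str
    k: int

    def __post_init__(self):
        self.folds = np.asarray(self.folds, dtype=int)
        present = set(np.unique(self.folds))
        if not present.issubset(set(range(self.k))):
            raise ValueError("fold ids must lie in [0, k)")


def tanimoto_matrix(fingerprints: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity of binary fingerprint rows."""
    X = np.asarray(fingerprints, dtype=float)
    inter = X @ X.T
    pop = X.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def make_split(n: int, strategy: str = "random", k: int = 3, seed: int = 0,
               fingerprints: np.ndarray | None = None,
               similarity: np.ndarray | None = None,
               tanimoto_threshold: float = 0.4) -> SplitPlan:
    """Assign ligands to k folds randomly or by Tanimoto scaffold clusters.

    The scaffold split single-links ligands whose Tanimoto similarity is at or
    above the threshold into clusters, then assigns clusters whole to folds,
    always to the currently smallest fold (largest clusters first), so no
    cluster ever spans folds.
    """
    if strategy == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for pos, idx in enumerate(order):
            folds[idx] = pos % k
        return SplitPlan(folds, "random", k)
    if strategy != "tanimoto":
        raise ValueError("strategy must be 'random' or 'tanimoto'")
    if similarity is None:
        if fingerprints is None:
            raise ValueError("tanimoto split needs fingerprints or a similarity matrix")
        similarity = tanimoto_matrix(fingerprints)
    dist = 1.0 - np.asarray(similarity, dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    if n == 1:
        return SplitPlan(np.zeros(1, dtype=int), "tanimoto", k)
    Z = linkage(squareform(dist, checks=False), method="single")
    clusters = fcluster(Z, t=1.0 - tanimoto_threshold, criterion="distance")
    sizes = {c: int((clusters == c).sum()) for c in np.unique(clusters)}
    if max(sizes.values()) > n / k:
        warnings.warn("a scaffold cluster exceeds one fold's share; folds will be unbalanced",
                      stacklevel=2)
    folds = np.empty(n, dtype=int)
    load = np.zeros(k, dtype=int)
    for c in sorted(sizes, key=lambda c: (-sizes[c], c)):
        target = int(np.argmin(load))
        folds[clusters == c] = target
        load[target] += sizes[c]
    return SplitPlan(folds, "tanimoto", k)


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def crossval_scores(features: np.ndarray, labels, plan: SplitPlan, seed: int = 0,
                    config: TLConfig = TLConfig()) -> np.ndarray:
    """Out-of-fold TL-head probabilities under a split plan."""
    labels = np.asarray(labels).astype(int)
    prob = np.full(len(labels), np.nan)
    for fold in range(plan.k):
        test = plan.folds == fold
        if not test.any():
            continue
        clf = train_tl_head(features[~test], labels[~test], seed=seed, config=config)
        prob[test] = predict_tl(clf, features[test])
    return prob


def evaluate_tl(features: np.ndarray, labels, strategy: str = "random", k: int = 3,
                base_seed: int = 0, config: TLConfig = TLConfig(),
                fingerprints: np.ndarray | None = None) -> dict:
    """Five-repetition cross-validated evaluation of the TL head.

    Each repetition re-splits (seed = base_seed + r) and retrains; metrics are
    computed both on the pooled out-of-fold predictions and per fold, and
    summarized as mean ± SD across repetitions.
    """
    labels = np.asarray(labels).astype(int)
    pooled_reports, per_fold_auc = [], []
    for r in range(config.n_repetitions):
        seed = base_seed + r
        plan = make_split(len(labels), strategy=strategy, k=k, seed=seed,
                          fingerprints=fingerprints)
        prob = crossval_scores(features, labels, plan, seed=seed, config=config)
        pooled_reports.append(compute_metrics(prob, labels))
        fold_aucs = []
        for fold in range(k):
            mask = plan.folds == fold
            if mask.any() and len(np.unique(labels[mask])) == 2:
                fold_aucs.append(auc_score(prob[mask], labels[mask]))
        if fold_aucs:
            per_fold_auc.append(float(np.mean(fold_aucs)))
    out = {"pooled": summarize_reports(pooled_reports), "strategy": strategy, "k": k}
    if per_fold_auc:
        vals = np.array(per_fold_auc)
        out["per_fold_auc"] = {"mean": float(vals.mean()),
                               "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out
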