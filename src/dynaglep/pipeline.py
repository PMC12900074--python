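"""End-to-end workflow: ensemble → state calls → selection → features → metrics.

The pipeline runs entirely on synthetic inputs by default (the generators in
:mod:`dynaglep.synthdata` stand in for MD, docking and scorer pretraining), and
writes every stage's output plus a JSON manifest (config hash, seed) into a run
directory, so a rerun with the same config is bit-reproducible.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import efficacy, ensemble_pca, rrcs, synthdata
from .conformers_io import ca_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Workflow configuration; defaults follow the study protocol.

    Training uses batch size 32 over 25 epochs with five seeded repetitions;
    cross-validation is three-fold under a random or Tanimoto scaffold split.
    """

    seed: int = 0
    strategy: str = "random"          # "random" | "tanimoto"
    k_folds: int = 3
    n_repetitions: int = 5
    epochs: int = 25
    batch_size: int = 32
    pairs: str = "3x43:7x49,3x43:7x53,3x46:7x53,3x50:7x53"
    ensemble: dict = field(default_factory=dict)     # TwoStateEnsembleSpec overrides
    features: dict = field(default_factory=dict)     # FeatureEnsembleSpec overrides
    scores: dict = field(default_factory=dict)       # ScoreTableSpec overrides

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full synthetic workflow and write stage outputs + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.digest(),
                "seed": config.seed, "stages": {}}
    try:
        # --- stage 1: conformational ensemble + ΔRRCS state calls ------------
        ens_spec = synthdata.TwoStateEnsembleSpec(
            **{"seed": config.seed, **config.ensemble})
        two_state = synthdata.gen_two_state_ensemble(ens_spec)
        merged, truth = two_state.merged()
        profile = rrcs.delta_rrcs(merged, two_state.pairs, two_state.reference,
                                  two_state.bw_map)
        calls = rrcs.call_state(profile)
        accuracy = float((calls.frame_call == truth).mean())
        rows = []
        for i in range(profile.n_frames):
            for j, pair in enumerate(profile.pairs):
                rows.append({"frame_id": int(profile.frame_ids[i]), "pair": str(pair),
                             "raw": profile.raw[i, j],
                             "normalized": profile.normalized[i, j],
                             "call": calls.per_pair[i, j]})
        pd.DataFrame(rows).to_csv(out / "profile.csv", index=False)
        manifest["stages"]["rrcs"] = {"n_frames": profile.n_frames,
                                      "state_call_accuracy": accuracy}

        # --- stage 2: representative selection --------------------------------
        selected = rrcs.select_representatives(profile, calls, n_target="auto")
        pd.DataFrame({"frame_id": profile.frame_ids[selected]}).to_csv(
            out / "selection.csv", index=False)
        manifest["stages"]["selection"] = {"n_selected": int(len(selected))}

        # --- stage 3: PCA ------------------------------------------------------
        coords = ca_matrix(merged)
        aligned = ensemble_pca.align_frames(coords, coords[0])
        pca = ensemble_pca.run_pca(aligned, n_components=2)
        ensemble_pca.project_selection(pca, selected, out_csv=out / "pca.csv",
                                       out_plot=out / "pca.svg")
        manifest["stages"]["pca"] = {"evr": pca.evr.tolist()}

        # --- stage 4: features + TL evaluation --------------------------------
        feat_spec = synthdata.FeatureEnsembleSpec(
            **{"seed": config.seed, **config.features})
        fe = synthdata.gen_feature_ensemble(feat_spec)
        X = efficacy.concat_features(fe)
        tl_cfg = efficacy.TLConfig(epochs=config.epochs, batch_size=config.batch_size,
                                   n_repetitions=config.n_repetitions)
        result = efficacy.evaluate_tl(X, fe.labels, strategy=config.strategy,
                                      k=config.k_folds, base_seed=config.seed,
                                      config=tl_cfg)
        manifest["stages"]["transfer_learning"] = {"strategy": config.strategy}

        # --- stage 5: baselines ------------------------------------------------
        score_spec = synthdata.ScoreTableSpec(**{"seed": config.seed, **config.scores})
        table, labels = synthdata.gen_score_table(score_spec)
        act_col = int(np.flatnonzero(table.states == "active")[0])
        inact_col = int(np.flatnonzero(table.states == "inactive")[0])
        static_auc = efficacy.auc_score(
            efficacy.static_classifier(table.scores[:, act_col]), labels)
        two_auc = efficacy.auc_score(
            efficacy.two_states_classifier(table.scores[:, act_col],
                                           table.scores[:, inact_col]), labels)
        plan = efficacy.make_split(len(labels), "random", k=config.k_folds,
                                   seed=config.seed)
        rf_auc = efficacy.auc_score(
            efficacy.rf_ensemble_classifier(table, labels, plan, seed=config.seed),
            labels)
        baselines = {"static_active_auc": static_auc, "two_states_auc": two_auc,
                     "rf_ensemble_auc": rf_auc}

        metrics = {"transfer_learning": result, "baselines": baselines,
                   "state_call_accuracy": accuracy}
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
        manifest["status"] = "ok"
        return metrics
    finally:
        with open(out / "manifest.json", "w") as fh:
            if "status" not in manifest:
                manifest["status"] = "failed"
            json.dump(manifest, fh, indent=1)
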