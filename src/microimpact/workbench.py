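"""Run configuration and the end-to-end pipeline driver.

A run is described by a single YAML document with per-stage blocks; all
randomness flows from one master seed through named substreams, so
identical configurations reproduce identical outputs. Stages execute in
dependency order: simulate -> featurize -> train -> evaluate / predict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, io, model, synthetic_data
from .genomefeat import build_feature_matrix

STAGES = ("simulate", "featurize", "train", "evaluate", "predict")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    inputs: dict = field(default_factory=dict)     # name -> path
    simulate: dict = field(default_factory=dict)   # n_drugs, n_taxa, ...
    train: dict = field(default_factory=dict)      # hyperparams
    evaluate: dict = field(default_factory=dict)   # scheme, k, ...

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def validate(self) -> None:
        for name, p in self.inputs.items():
            if not Path(p).exists():
                raise PipelineError(f"input {name!r} refers to missing file: {p}")

    def substream(self, name: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = np.uint32(abs(hash((self.seed, name))) % (2**31))
        return int(h)

    def as_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "inputs": self.inputs,
            "simulate": self.simulate,
            "train": self.train,
            "evaluate": self.evaluate,
        }


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order.

    Returns a dict of produced artifact paths. Missing upstream
    artifacts raise PipelineError naming the stage.
    """
    config.validate()
    stages = [s for s in STAGES if s in set(stages)]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    cfg = config.as_dict()

    def emit(frame, name, index=True):
        path = out / name
        io.write_with_sidecar(frame, path, seed=config.seed, config=cfg, index=index)
        artifacts[name] = str(path)
        return path

    dataset = None
    fingerprints = None

    if "simulate" in stages:
        sim = {"n_drugs": 60, "n_taxa": 20, "mode": "smiles-fixture",
               "rule_strength": 2.0, **config.simulate}
        drugs = synthetic_data.gen_drugs(
            sim["n_drugs"], seed=config.substream("drugs"), mode=sim["mode"]
        )
        pmap = synthetic_data.gen_pathway_map(seed=config.substream("map"))
        panel = synthetic_data.gen_genomes(
            sim["n_taxa"], pmap, seed=config.substream("genomes")
        )
        microbe_features = build_feature_matrix(panel.records, pmap)
        rule = synthetic_data.default_rule(sim["rule_strength"])
        dataset = synthetic_data.plant_labels(
            drugs.features, microbe_features, rule,
            seed=config.substream("labels"), families=drugs.families,
        )
        fingerprints = drugs.fingerprints
        emit(dataset.pairs, "interactions.tsv", index=False)
        emit(drugs.features, "drug_features.tsv")
        emit(microbe_features, "microbe_features.tsv")
        emit(panel.taxonomy, "taxonomy.tsv")
        emit(panel.distances, "phylo_distances.tsv")

    if dataset is None and {"train", "evaluate", "predict"} & set(stages):
        needed = ["interactions", "drug_features", "microbe_features"]
        missing = [n for n in needed if n not in config.inputs]
        if missing:
            raise PipelineError(
                f"stage requires upstream artifact(s) {missing}; "
                "run 'simulate' or provide them as inputs"
            )
        dataset = model.InteractionDataset(
            io.read_interactions(config.inputs["interactions"]),
            io.read_feature_matrix(config.inputs["drug_features"]),
            io.read_feature_matrix(config.inputs["microbe_features"]),
        )

    trained = None
    if "train" in stages:
        trained = model.train(
            dataset, hyperparams=config.train or None, seed=config.substream("train")
        )
        model.save_model_metadata(trained, out / "model_metadata.json")
        artifacts["model_metadata.json"] = str(out / "model_metadata.json")

    if "evaluate" in stages:
        ev = {"scheme": "cv", "k": 10, **config.evaluate}
        seed = config.substream("evaluate")
        hp = config.train or None
        if ev["scheme"] == "cv":
            res = evaluation.kfold_cv(dataset, k=ev["k"], seed=seed, hyperparams=hp)
        elif ev["scheme"] == "lodo":
            res = evaluation.leave_one_drug_out(
                dataset, tc_cutoff=ev.get("tc_cutoff"),
                fingerprints=fingerprints, seed=seed, hyperparams=hp,
            )
        else:
            raise PipelineError(f"unknown evaluate scheme {ev['scheme']!r}")
        payload = {
            "scheme": res.scheme,
            "roc_auc": res.roc_auc,
            "pr_auc": res.pr_auc,
            "params": res.params,
            "seed": config.seed,
        }
        (out / "evaluation.json").write_text(json.dumps(payload, indent=2, default=str))
        artifacts["evaluation.json"] = str(out / "evaluation.json")
        emit(res.per_unit, "evaluation_per_unit.tsv", index=False)

    if "predict" in stages:
        if trained is None:
            trained = model.train(
                dataset, hyperparams=config.train or None,
                seed=config.substream("train"),
            )
        catalog = model.predict_impact(
            trained, dataset.drug_features, dataset.microbe_features
        )
        emit(catalog, "catalog.tsv", index=False)

    return artifacts
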