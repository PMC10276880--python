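"""The drug-microbe interaction classifier and impact-score catalogs.

Each (drug, microbe) pair is represented by the concatenation of the
microbe's pathway-score vector and the drug's descriptor vector (148 + 92
= 240 features under the default registries). A random forest is trained
on binary growth-inhibition labels from a screen; its predicted
probability of inhibition for an unscreened pair is the "impact score" in
[0, 1]. Defaults mirror a stock probability forest: 500 trees, impurity
splitting, sqrt-p feature subsampling, no feature scaling or class
re-weighting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

DEFAULT_HYPERPARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "min_samples_leaf": 1,
}


@dataclass
class InteractionDataset:
    """A binary interaction screen plus aligned feature matrices.

    pairs: DataFrame with columns drug_id, microbe_id, label (0/1).
    drug_features: DataFrame indexed by drug_id.
    microbe_features: DataFrame indexed by microbe_id.
    """

    pairs: pd.DataFrame
    drug_features: pd.DataFrame
    microbe_features: pd.DataFrame

    def __post_init__(self):
        required = {"drug_id", "microbe_id", "label"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"pairs table missing columns: {sorted(missing)}")
        labels = set(self.pairs["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(labels)}")
        dup = self.pairs.duplicated(["drug_id", "microbe_id"])
        if dup.any():
            offenders = self.pairs.loc[dup, ["drug_id", "microbe_id"]]
            raise ValueError(
                f"duplicate (drug, microbe) pairs: {offenders.values[:5].tolist()}"
            )
        bad_d = sorted(set(self.pairs["drug_id"]) - set(self.drug_features.index))
        bad_m = sorted(
            set(self.pairs["microbe_id"]) - set(self.microbe_features.index)
        )
        if bad_d or bad_m:
            raise KeyError(
                f"unresolvable ids - drugs: {bad_d[:5]}, microbes: {bad_m[:5]}"
            )

    def subset(self, mask) -> "InteractionDataset":
        return InteractionDataset(
            self.pairs.loc[mask].reset_index(drop=True),
            self.drug_features,
            self.microbe_features,
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(
            pd.util.hash_pandas_object(
                self.pairs[["drug_id", "microbe_id", "label"]], index=False
            ).values.tobytes()
        )
        h.update(np.ascontiguousarray(self.drug_features.to_numpy()).tobytes())
        h.update(np.ascontiguousarray(self.microbe_features.to_numpy()).tobytes())
        return h.hexdigest()[:16]


def assemble_pair_features(
    dataset: InteractionDataset, pairs: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix row_i = concat(microbe features, drug features)."""
    pairs = dataset.pairs if pairs is None else pairs
    m = dataset.microbe_features.loc[pairs["microbe_id"]].reset_index(drop=True)
    d = dataset.drug_features.loc[pairs["drug_id"]].reset_index(drop=True)
    X = pd.concat([m, d], axis=1)
    overlap = set(dataset.microbe_features.columns) & set(
        dataset.drug_features.columns
    )
    if overlap:
        raise ValueError(f"feature name collision: {sorted(overlap)[:5]}")
    y = pairs["label"].to_numpy() if "label" in pairs.columns else np.array([])
    return X, y


class InteractionForest(ClassifierMixin, BaseEstimator):
    """Random-forest classifier whose positive-class probability is the
    impact score.

    sklearn-compatible: ``fit(X, y)`` / ``predict_proba`` / ``get_params``.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features="sqrt",
        min_samples_leaf: int = 1,
        oob_score: bool = True,
        random_state=None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.oob_score = oob_score
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.feature_names_in_ = (
            list(X.columns) if hasattr(X, "columns") else None
        )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            oob_score=self.oob_score,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.forest_.classes_
        self.oob_score_ = getattr(self.forest_, "oob_score_", None)
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def impact_scores(self, X) -> np.ndarray:
        """Predicted probability of growth inhibition (label 1)."""
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]


@dataclass
class TrainedModel:
    """A fitted interaction forest with its feature contract and metadata."""

    estimator: InteractionForest
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing features at prediction time: {missing[:5]}")
        return X[self.feature_names]


def train(
    dataset: InteractionDataset, hyperparams: dict | None = None, seed: int = 0
) -> TrainedModel:
    """Fit the interaction forest on a screen; reproducible for fixed seed."""
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    X, y = assemble_pair_features(dataset)
    est = InteractionForest(random_state=seed, **hp)
    est.fit(X, y)
    meta = {
        "seed": seed,
        "hyperparams": hp,
        "dataset_hash": dataset.content_hash(),
        "n_pairs": len(y),
        "prevalence": float(np.mean(y)),
        "oob_score": est.oob_score_,
    }
    return TrainedModel(est, list(X.columns), meta)


def predict_impact(
    model: TrainedModel,
    drug_features: pd.DataFrame,
    microbe_features: pd.DataFrame,
) -> pd.DataFrame:
    """Impact-score catalog over the full drugs x microbes cross product.

    Returns a long DataFrame (drug_id, microbe_id, impact_score) with
    exactly len(drugs) * len(microbes) rows, scores in [0, 1].
    """
    drugs = list(drug_features.index)
    microbes = list(microbe_features.index)
    pairs = pd.DataFrame(
        [(d, m) for d in drugs for m in microbes],
        columns=["drug_id", "microbe_id"],
    )
    m = microbe_features.loc[pairs["microbe_id"]].reset_index(drop=True)
    d = drug_features.loc[pairs["drug_id"]].reset_index(drop=True)
    X = model.check_features(pd.concat([m, d], axis=1))
    pairs["impact_score"] = model.estimator.impact_scores(X)
    return pairs


class NullModel:
    """Naive baselines: constant majority vote or marginal inhibition rates."""

    MODES = ("majority", "per_drug_rate", "per_microbe_rate")

    def __init__(self, train_pairs: pd.DataFrame, mode: str):
        if mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}")
        self.mode = mode
        self.global_rate_ = float(train_pairs["label"].mean())
        self.majority_ = float(train_pairs["label"].mode().iloc[0])
        self.drug_rate_ = train_pairs.groupby("drug_id")["label"].mean()
        self.microbe_rate_ = train_pairs.groupby("microbe_id")["label"].mean()

    def predict(self, pairs: pd.DataFrame) -> np.ndarray:
        if self.mode == "majority":
            return np.full(len(pairs), self.majority_)
        if self.mode == "per_drug_rate":
            return (
                pairs["drug_id"]
                .map(self.drug_rate_)
                .fillna(self.global_rate_)
                .to_numpy()
            )
        return (
            pairs["microbe_id"]
            .map(self.microbe_rate_)
            .fillna(self.global_rate_)
            .to_numpy()
        )


def baseline_null(
    dataset: InteractionDataset,
    mode: str,
    train_mask=None,
    eval_pairs: pd.DataFrame | None = None,
) -> np.ndarray:
    """Baseline scores for ``eval_pairs`` fitted on the training split."""
    train_pairs = (
        dataset.pairs if train_mask is None else dataset.pairs.loc[train_mask]
    )
    null = NullModel(train_pairs, mode)
    return null.predict(dataset.pairs if eval_pairs is None else eval_pairs)


def save_model_metadata(model: TrainedModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.metadata, fh, indent=2, default=str)
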