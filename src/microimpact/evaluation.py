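"""Hold-out evaluation battery for the interaction model.

Four schemes of increasing difficulty:

* pair-level k-fold cross-validation (new drug-microbe *pairs*),
* leave-one-drug-out, optionally excluding training compounds whose
  Tanimoto similarity to the held-out drug reaches a cutoff (new drugs,
  with or without structurally related examples),
* leave-one-microbe-out, optionally correlating per-strain accuracy with
  phylogenetic distance to the nearest training strain (new strains),
* leave-phylum-out (new strains with the whole phylum withheld).

ROC AUC is the Mann-Whitney probability of correct ranking; PR AUC is
average precision (step-wise, no linear interpolation). Pooled (micro)
AUCs over all held-out predictions are the headline numbers; per-unit
(macro) AUCs are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold

from .chemspace import BitFingerprint, tanimoto
from .model import InteractionDataset, assemble_pair_features, train


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes and only one is present."""


def binary_metrics(scores, labels) -> tuple[float, float]:
    """(ROC AUC, PR AUC) for binary labels and continuous scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("both classes required for ROC/PR AUC")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


@dataclass
class EvaluationResult:
    """Pooled and per-unit held-out performance for one scheme."""

    scheme: str
    roc_auc: float
    pr_auc: float
    predictions: pd.DataFrame  # drug_id, microbe_id, label, score, unit
    per_unit: pd.DataFrame = field(default_factory=pd.DataFrame)
    params: dict = field(default_factory=dict)


def _fit_predict(dataset, train_mask, test_pairs, hyperparams, seed):
    model = train(dataset.subset(train_mask), hyperparams=hyperparams, seed=seed)
    X, _ = assemble_pair_features(dataset, test_pairs)
    return model.estimator.impact_scores(model.check_features(X))


def kfold_cv(
    dataset: InteractionDataset,
    k: int = 10,
    seed: int = 0,
    repeats: int = 1,
    hyperparams: dict | None = None,
) -> EvaluationResult:
    """Pair-level k-fold cross-validation, pooled over held-out folds.

    With ``repeats`` > 1 the whole CV is rerun on fresh shuffles and the
    mean +/- sd of the pooled AUCs is reported in ``params``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pooled_aucs, all_preds = [], None
    for rep in range(repeats):
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        preds = []
        for fold, (tr, te) in enumerate(splitter.split(dataset.pairs)):
            test_pairs = dataset.pairs.iloc[te]
            if len(np.unique(dataset.pairs.iloc[tr]["label"])) < 2:
                warnings.warn(f"fold {fold} has one training class; skipped")
                continue
            mask = np.zeros(len(dataset.pairs), dtype=bool)
            mask[tr] = True
            scores = _fit_predict(dataset, mask, test_pairs, hyperparams, seed + rep)
            chunk = test_pairs.copy()
            chunk["score"] = scores
            chunk["unit"] = fold
            preds.append(chunk)
        preds = pd.concat(preds, ignore_index=True)
        roc, pr = binary_metrics(preds["score"], preds["label"])
        pooled_aucs.append((roc, pr))
        if rep == 0:
            all_preds = preds
    rocs, prs = zip(*pooled_aucs)
    return EvaluationResult(
        scheme="cv",
        roc_auc=float(np.mean(rocs)),
        pr_auc=float(np.mean(prs)),
        predictions=all_preds,
        per_unit=pd.DataFrame(
            {"repeat": range(repeats), "roc_auc": rocs, "pr_auc": prs}
        ),
        params={
            "k": k,
            "seed": seed,
            "repeats": repeats,
            "roc_auc_sd": float(np.std(rocs)),
            "pr_auc_sd": float(np.std(prs)),
        },
    )


def leave_one_drug_out(
    dataset: InteractionDataset,
    tc_cutoff: float | None = None,
    fingerprints: dict[str, BitFingerprint] | None = None,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> EvaluationResult:
    """Hold out every pair of one drug at a time; train on the rest.

    With ``tc_cutoff`` set, training is further restricted to drugs whose
    Tanimoto similarity to the held-out drug is strictly below the cutoff
    (the held-out drug itself is always excluded). Per-drug diagnostics
    include the nearest-neighbour Tanimoto distance within the retained
    training compounds and the training-compound count.
    """
    drugs = sorted(dataset.pairs["drug_id"].unique())
    if tc_cutoff is not None and fingerprints is None:
        raise ValueError("tc_cutoff requires fingerprints for all drugs")
    preds, diagnostics = [], []
    for d in drugs:
        held = dataset.pairs["drug_id"] == d
        keep = ~held
        nn_tc = np.nan
        if tc_cutoff is not None:
            sims = {
                other: tanimoto(fingerprints[d], fingerprints[other])
                for other in drugs
                if other != d
            }
            allowed = {o for o, tc in sims.items() if tc < tc_cutoff}
            keep = keep & dataset.pairs["drug_id"].isin(allowed)
            if allowed:
                nn_tc = max(sims[o] for o in allowed)
        train_pairs = dataset.pairs.loc[keep]
        n_train_drugs = train_pairs["drug_id"].nunique()
        if n_train_drugs == 0 or train_pairs["label"].nunique() < 2:
            diagnostics.append(
                {"drug_id": d, "evaluable": False, "n_train_drugs": n_train_drugs}
            )
            continue
        scores = _fit_predict(
            dataset, keep.to_numpy(), dataset.pairs.loc[held], hyperparams, seed
        )
        chunk = dataset.pairs.loc[held].copy()
        chunk["score"] = scores
        chunk["unit"] = d
        preds.append(chunk)
        rec = {
            "drug_id": d,
            "evaluable": True,
            "n_train_drugs": n_train_drugs,
            "nn_tc_distance": 1.0 - nn_tc if np.isfinite(nn_tc) else np.nan,
        }
        if chunk["label"].nunique() == 2:
            rec["roc_auc"], rec["pr_auc"] = binary_metrics(
                chunk["score"], chunk["label"]
            )
        diagnostics.append(rec)
    if not preds:
        raise ValueError("no drug was evaluable under this cutoff")
    preds = pd.concat(preds, ignore_index=True)
    roc, pr = binary_metrics(preds["score"], preds["label"])
    return EvaluationResult(
        scheme="lodo",
        roc_auc=roc,
        pr_auc=pr,
        predictions=preds,
        per_unit=pd.DataFrame(diagnostics),
        params={"tc_cutoff": tc_cutoff, "seed": seed},
    )


def leave_one_microbe_out(
    dataset: InteractionDataset,
    phylo_distances: pd.DataFrame | None = None,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> EvaluationResult:
    """Hold out every strain at a time; optionally relate per-strain AUC to
    phylogenetic distance to its nearest training strain."""
    strains = sorted(dataset.pairs["microbe_id"].unique())
    if len(strains) < 3:
        raise ValueError("need at least 3 strains")
    preds, per_strain = [], []
    for s in strains:
        held = dataset.pairs["microbe_id"] == s
        if dataset.pairs.loc[~held, "label"].nunique() < 2:
            warnings.warn(f"strain {s}: training labels single-class; skipped")
            continue
        scores = _fit_predict(
            dataset, (~held).to_numpy(), dataset.pairs.loc[held], hyperparams, seed
        )
        chunk = dataset.pairs.loc[held].copy()
        chunk["score"] = scores
        chunk["unit"] = s
        preds.append(chunk)
        rec = {"microbe_id": s}
        if phylo_distances is not None:
            others = [o for o in strains if o != s]
            rec["nn_distance"] = float(phylo_distances.loc[s, others].min())
        if chunk["label"].nunique() == 2:
            rec["roc_auc"], rec["pr_auc"] = binary_metrics(
                chunk["score"], chunk["label"]
            )
        else:
            warnings.warn(f"strain {s}: held-out labels single-class; AUC undefined")
        per_strain.append(rec)
    preds = pd.concat(preds, ignore_index=True)
    roc, pr = binary_metrics(preds["score"], preds["label"])
    per_strain = pd.DataFrame(per_strain)
    params: dict = {"seed": seed}
    if phylo_distances is not None and "roc_auc" in per_strain:
        ok = per_strain.dropna(subset=["roc_auc", "nn_distance"])
        if ok["nn_distance"].nunique() > 1 and len(ok) > 2:
            r, p = stats.pearsonr(ok["nn_distance"], ok["roc_auc"])
            params["auc_distance_pearson"] = float(r)
            params["auc_distance_p"] = float(p)
        else:
            params["auc_distance_pearson"] = None
            params["auc_distance_note"] = "undefined (constant distances or n <= 2)"
    return EvaluationResult(
        scheme="lomo",
        roc_auc=roc,
        pr_auc=pr,
        predictions=preds,
        per_unit=per_strain,
        params=params,
    )


def leave_phylum_out(
    dataset: InteractionDataset,
    taxonomy: pd.Series,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> EvaluationResult:
    """Per strain: train with every same-phylum strain removed.

    Strains that are alone in their phylum are skipped (for them the
    scheme would collapse to plain leave-one-microbe-out).
    """
    strains = sorted(dataset.pairs["microbe_id"].unique())
    missing = [s for s in strains if s not in taxonomy.index]
    if missing:
        raise KeyError(f"taxonomy missing for strains: {missing[:5]}")
    phyla = taxonomy.loc[strains]
    if phyla.nunique() < 2:
        raise ValueError("all strains belong to one phylum; nothing evaluable")
    counts = phyla.value_counts()
    preds, per_strain = [], []
    for s in strains:
        ph = phyla[s]
        if counts[ph] < 2:
            per_strain.append({"microbe_id": s, "phylum": ph, "skipped": True})
            continue
        same_phylum = phyla.index[phyla == ph]
        keep = ~dataset.pairs["microbe_id"].isin(same_phylum)
        held = dataset.pairs["microbe_id"] == s
        if dataset.pairs.loc[keep, "label"].nunique() < 2:
            warnings.warn(f"strain {s}: training single-class after exclusion")
            continue
        scores = _fit_predict(
            dataset, keep.to_numpy(), dataset.pairs.loc[held], hyperparams, seed
        )
        chunk = dataset.pairs.loc[held].copy()
        chunk["score"] = scores
        chunk["unit"] = s
        preds.append(chunk)
        rec = {"microbe_id": s, "phylum": ph, "skipped": False}
        if chunk["label"].nunique() == 2:
            rec["roc_auc"], rec["pr_auc"] = binary_metrics(
                chunk["score"], chunk["label"]
            )
        per_strain.append(rec)
    preds = pd.concat(preds, ignore_index=True)
    roc, pr = binary_metrics(preds["score"], preds["label"])
    return EvaluationResult(
        scheme="lopho",
        roc_auc=roc,
        pr_auc=pr,
        predictions=preds,
        per_unit=pd.DataFrame(per_strain),
        params={"seed": seed},
    )
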