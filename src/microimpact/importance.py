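"""Permutation feature importance with significance, per-strain importance
profiles, and their ordination.

Significance follows the response-permutation scheme: the observed
importance of every feature comes from a forest fit on the true labels;
the null distribution comes from forests refit on label-permuted copies of
the data, giving a per-feature permutation p-value
p = (1 + #{null >= observed}) / (1 + n_perm), corrected across features by
Benjamini-Hochberg. Per-strain profiles (one forest per strain, only drug
features varying) are ordinated by PCA, and group separation (phylum, gram
stain) is tested by PERMANOVA on Euclidean distances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix, permanova
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .model import InteractionDataset, InteractionForest, assemble_pair_features
from .registries import descriptor_family, pathway_category


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _feature_category(name: str) -> str:
    if name.startswith(("ko", "map", "path")):
        return pathway_category(name)
    return descriptor_family(name)


def permutation_importance_report(
    dataset: InteractionDataset,
    n_perm: int = 100,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """Per-feature importance, permutation p-value and BH q-value.

    Columns: feature, importance, p_value, q_value, category. Constant
    features get importance 0 and p = 1 by construction of the forest.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for meaningful p-values")
    # low feature subsampling reduces impurity-importance masking among
    # correlated features, which would otherwise depress their p-values
    hp = {"n_estimators": 100, "max_features": "log2"}
    hp.update(hyperparams or {})
    X, y = assemble_pair_features(dataset)
    Xv = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)

    est = InteractionForest(random_state=seed, oob_score=False, **hp)
    est.fit(Xv, y)
    observed = est.feature_importances_

    exceed = np.zeros_like(observed)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        null_est = InteractionForest(
            random_state=seed + 1 + i, oob_score=False, **hp
        )
        null_est.fit(Xv, y_perm)
        exceed += null_est.feature_importances_ >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    constant = Xv.std(axis=0) == 0
    pvals[constant] = 1.0
    report = pd.DataFrame(
        {
            "feature": list(X.columns),
            "importance": observed,
            "p_value": pvals,
            "q_value": bh_fdr(pvals),
            "category": [_feature_category(c) for c in X.columns],
        }
    )
    return report


def compare_reports(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Compare two importance reports on their shared features.

    Returns Pearson r and p over importance values, plus a paired
    Wilcoxon signed-rank test of systematic shift.
    """
    merged = a.merge(b, on="feature", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared features")
    r, p = stats.pearsonr(merged["importance_a"], merged["importance_b"])
    diff = merged["importance_a"] - merged["importance_b"]
    if np.allclose(diff, 0):
        w_p = 1.0
    else:
        w_p = float(stats.wilcoxon(merged["importance_a"], merged["importance_b"]).pvalue)
    return {
        "n_features": len(merged),
        "pearson_r": float(r),
        "pearson_p": float(p),
        "paired_wilcoxon_p": w_p,
    }


def per_strain_importance(
    dataset: InteractionDataset,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """Strains x drug-feature importance matrix.

    One forest per strain, trained on that strain's pairs only. Within a
    strain the microbe features are constant, so only drug features enter
    the fit. Strains whose labels are single-class are excluded.
    """
    hp = {"n_estimators": 100, "max_features": "sqrt"}
    hp.update(hyperparams or {})
    rows = {}
    for s, grp in dataset.pairs.groupby("microbe_id"):
        y = grp["label"].to_numpy()
        if len(np.unique(y)) < 2:
            warnings.warn(f"strain {s}: single-class labels; excluded")
            continue
        Xd = dataset.drug_features.loc[grp["drug_id"]]
        est = InteractionForest(random_state=seed, oob_score=False, **hp)
        est.fit(np.asarray(Xd, dtype=float), y)
        rows[s] = est.feature_importances_
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(dataset.drug_features.columns)
    ).sort_index()


def strain_importance_ordination(
    dataset: InteractionDataset,
    annotations: pd.DataFrame,
    n_perm_permanova: int = 999,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """PCA of per-strain drug-importance profiles plus PERMANOVA per grouping.

    ``annotations`` is indexed by strain with one column per grouping
    (e.g. phylum, gram_stain). Each grouping needs >= 2 groups with >= 2
    strains each; others are reported as untestable.
    """
    imp = per_strain_importance(dataset, seed=seed, hyperparams=hyperparams)
    if len(imp) < 3:
        raise ValueError("need at least 3 strains with two-class labels")
    pca = PCA(n_components=min(5, len(imp) - 1, imp.shape[1]), random_state=seed)
    coords = pd.DataFrame(
        pca.fit_transform(imp.to_numpy()),
        index=imp.index,
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)],
    )
    coords.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()

    dm = DistanceMatrix(
        _euclidean_distances(imp.to_numpy()), ids=[str(i) for i in imp.index]
    )
    tests: dict[str, dict] = {}
    for grouping in annotations.columns:
        labels = annotations.loc[imp.index, grouping]
        sizes = labels.value_counts()
        if (sizes >= 2).sum() < 2:
            tests[grouping] = {"testable": False, "reason": "needs >=2 groups of >=2"}
            continue
        res = permanova(
            dm, labels.astype(str).tolist(), permutations=n_perm_permanova
        )
        tests[grouping] = {
            "testable": True,
            "pseudo_F": float(res["test statistic"]),
            "p_value": float(res["p-value"]),
            "n_permutations": n_perm_permanova,
        }
    return imp, coords, tests


def _euclidean_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def permanova_pseudo_f(distances: np.ndarray, groups) -> float:
    """Direct sum-of-squares PERMANOVA pseudo-F (reference computation)."""
    groups = np.asarray(groups)
    n = len(groups)
    d2 = np.asarray(distances) ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(groups))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))
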