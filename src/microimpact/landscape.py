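"""Interaction-landscape analytics over an impact-score catalog.

From a complete drugs x microbes catalog of impact scores this module
derives per-drug impact indices (mean score over taxa) and per-microbe
sensitivity indices (mean score over drugs), compares them across drug
groupings (target class, ATC level-1), classifies each drug's phylum
specificity between Firmicutes and Bacteroidetes, and screens putative
drug targets by comparing scores of taxa that do or do not carry a
homolog (KO) of a known target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .importance import bh_fdr


def _check_complete(catalog: pd.DataFrame) -> None:
    n_d = catalog["drug_id"].nunique()
    n_m = catalog["microbe_id"].nunique()
    if len(catalog) != n_d * n_m:
        raise ValueError(
            f"catalog is not a complete cross product: {len(catalog)} rows "
            f"for {n_d} drugs x {n_m} microbes"
        )


@dataclass
class LandscapeIndices:
    """Per-drug impact indices and per-microbe sensitivity indices."""

    drug: pd.DataFrame     # index drug_id: impact_index [, atc_level1, drug_class]
    microbe: pd.DataFrame  # index microbe_id: sensitivity_index [, phylum]
    params: dict = field(default_factory=dict)


def impact_indices(
    catalog: pd.DataFrame,
    drug_annotations: pd.DataFrame | None = None,
    microbe_annotations: pd.DataFrame | None = None,
) -> LandscapeIndices:
    """Mean impact per drug (impact index) and per microbe (sensitivity)."""
    _check_complete(catalog)
    drug = catalog.groupby("drug_id")["impact_score"].mean().to_frame("impact_index")
    microbe = (
        catalog.groupby("microbe_id")["impact_score"].mean().to_frame("sensitivity_index")
    )
    if drug_annotations is not None:
        drug = drug.join(drug_annotations)
    if microbe_annotations is not None:
        microbe = microbe.join(microbe_annotations)
    return LandscapeIndices(drug, microbe, {"n_pairs": len(catalog)})


def group_comparison(values: pd.Series, groups: pd.Series) -> dict:
    """Kruskal-Wallis across groups plus pairwise Wilcoxon rank-sum, BH-FDR.

    Effect size is epsilon squared, H / (n - 1). Groups with fewer than
    two members are dropped with a warning.
    """
    frame = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = frame["group"].value_counts()
    small = sizes.index[sizes < 2]
    if len(small):
        warnings.warn(f"dropping groups of size < 2: {sorted(small)}")
        frame = frame[~frame["group"].isin(small)]
    names = sorted(frame["group"].unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    samples = [frame.loc[frame["group"] == g, "value"].to_numpy() for g in names]
    h, p = stats.kruskal(*samples)
    n = len(frame)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            rows.append({"group_a": names[i], "group_b": names[j], "p_value": u.pvalue})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["q_value"] = bh_fdr(pairwise["p_value"])
    return {
        "H": float(h),
        "p_value": float(p),
        "epsilon_squared": float(h / (n - 1)),
        "n": n,
        "groups": names,
        "pairwise": pairwise,
    }


def phylum_specificity(
    catalog: pd.DataFrame,
    taxonomy: pd.Series,
    phylum_a: str = "Firmicutes",
    phylum_b: str = "Bacteroidetes",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-drug specificity between the two dominant gut phyla.

    delta = mean impact on ``phylum_a`` (Firmicutes) minus mean impact on
    ``phylum_b`` (Bacteroidetes); drugs in the top quartile of delta are
    classified ``firmicutes-specific``, the bottom quartile
    ``bacteroidetes-specific``, and the middle half ``non-specific``
    (type-7 quantiles, ties to the lower class). A per-drug two-sided
    Wilcoxon rank-sum across the two phyla's taxon score sets, BH-FDR
    corrected, flags significant specificity.
    """
    _check_complete(catalog)
    taxa_a = taxonomy.index[taxonomy == phylum_a]
    taxa_b = taxonomy.index[taxonomy == phylum_b]
    if len(taxa_a) < 2 or len(taxa_b) < 2:
        raise ValueError(f"need >= 2 taxa in each of {phylum_a} and {phylum_b}")
    wide = catalog.pivot(index="drug_id", columns="microbe_id", values="impact_score")
    a_scores = wide[list(taxa_a)]
    b_scores = wide[list(taxa_b)]
    delta = a_scores.mean(axis=1) - b_scores.mean(axis=1)
    pvals = []
    for d in wide.index:
        sa, sb = a_scores.loc[d].to_numpy(), b_scores.loc[d].to_numpy()
        if np.all(sa == sa[0]) and np.all(sb == sb[0]) and sa[0] == sb[0]:
            pvals.append(1.0)
        else:
            pvals.append(
                float(stats.mannwhitneyu(sa, sb, alternative="two-sided").pvalue)
            )
    q1, q3 = np.quantile(delta, [0.25, 0.75])  # type-7 (linear) quantiles
    cls = pd.Series("non-specific", index=wide.index)
    cls[delta > q3] = "firmicutes-specific"
    cls[delta <= q1] = "bacteroidetes-specific"
    out = pd.DataFrame(
        {
            "delta_firmicutes_minus_bacteroidetes": delta,
            "p_value": pvals,
            "q_value": bh_fdr(pvals),
            "specificity_class": cls,
        }
    )
    out["significant"] = out["q_value"] < fdr_threshold
    return out


def target_homolog_association(
    catalog: pd.DataFrame,
    drug_targets: pd.DataFrame,
    ko_presence: pd.DataFrame,
    min_per_side: int = 3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon screen of impact scores vs presence of a drug-target homolog.

    ``drug_targets`` is a long table (drug_id, ko_id); ``ko_presence`` a
    boolean microbes x KO matrix. For each (drug, KO) with at least
    ``min_per_side`` taxa on each side of the presence split, impact
    scores of carriers vs non-carriers are compared two-sided; BH-FDR is
    applied across all tested pairs. Direction is the sign of the median
    difference (carriers minus non-carriers).
    """
    _check_complete(catalog)
    wide = catalog.pivot(index="drug_id", columns="microbe_id", values="impact_score")
    taxa = [t for t in wide.columns if t in ko_presence.index]
    rows = []
    for _, rec in drug_targets.iterrows():
        d, ko = rec["drug_id"], rec["ko_id"]
        if d not in wide.index or ko not in ko_presence.columns:
            rows.append({"drug_id": d, "ko_id": ko, "tested": False,
                         "reason": "unmapped drug or KO"})
            continue
        present = [t for t in taxa if ko_presence.loc[t, ko]]
        absent = [t for t in taxa if not ko_presence.loc[t, ko]]
        if len(present) < min_per_side or len(absent) < min_per_side:
            rows.append({"drug_id": d, "ko_id": ko, "tested": False,
                         "reason": "one-sided presence split"})
            continue
        with_ko = wide.loc[d, present].to_numpy()
        without = wide.loc[d, absent].to_numpy()
        p = float(stats.mannwhitneyu(with_ko, without, alternative="two-sided").pvalue)
        rows.append(
            {
                "drug_id": d,
                "ko_id": ko,
                "tested": True,
                "p_value": p,
                "direction": int(np.sign(np.median(with_ko) - np.median(without))),
                "n_with": len(present),
                "n_without": len(absent),
            }
        )
    out = pd.DataFrame(rows)
    tested = out.get("tested", pd.Series(dtype=bool))
    if tested.any():
        out.loc[tested, "q_value"] = bh_fdr(out.loc[tested, "p_value"])
        out["significant"] = out.get("q_value", np.nan) < fdr_threshold
    return out
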