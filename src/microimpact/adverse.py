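"""Association of predicted anti-commensal activity with adverse drug
reaction frequencies.

Side-effect frequencies come in SIDER-like long form (drug, term, source
frequency, placebo flag). Per (drug, term) the adjusted frequency is the
mean across non-placebo sources minus the mean across placebo arms,
floored at zero; rare terms (reported for fewer than 50 drugs by default)
are discarded. Terms are grouped into broader categories (shipped
verbatim: gastrointestinal and infection lists), and drugs with a
category frequency above a threshold are compared with low-frequency
drugs on their mean microbiome impact (Wilcoxon rank-sum). A one-way
ANOVA relates a term's frequency to the drug's phylum-specificity class.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

GASTROINTESTINAL_TERMS = (
    "constipation",
    "abdominal pain",
    "diarrhea",
    "gastrointestinal disorder",
    "gastrointestinal pain",
    "vomiting",
    "nausea",
    "abdominal discomfort",
    "dyspepsia",
    "flatulence",
    "abdominal pain upper",
)

INFECTION_TERMS = (
    "infection",
    "urinary tract infection",
    "pneumonia",
    "stomatitis",
    "upper respiratory tract infection",
)

DEFAULT_CATEGORIES = {
    "gastrointestinal": list(GASTROINTESTINAL_TERMS),
    "infection": list(INFECTION_TERMS),
}


def effect_frequencies(
    raw: pd.DataFrame, min_drugs_per_term: int = 50
) -> pd.DataFrame:
    """Placebo-adjusted per (drug, term) frequencies.

    ``raw`` columns: drug_id, term, frequency, placebo (bool-like)
    [, source_id]. Malformed frequencies (outside [0, 1] or unparseable)
    are rejected row-wise with a warning. Terms reported for fewer than
    ``min_drugs_per_term`` drugs are dropped.
    """
    frame = raw.copy()
    frame["frequency"] = pd.to_numeric(frame["frequency"], errors="coerce")
    bad = frame["frequency"].isna() | (frame["frequency"] < 0) | (frame["frequency"] > 1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} row(s) with malformed frequency rejected")
        frame = frame.loc[~bad]
    frame["placebo"] = frame["placebo"].astype(bool)

    def adjust(grp: pd.DataFrame) -> float:
        active = grp.loc[~grp["placebo"], "frequency"]
        placebo = grp.loc[grp["placebo"], "frequency"]
        if active.empty:
            return 0.0
        adj = active.mean() - (placebo.mean() if not placebo.empty else 0.0)
        return max(0.0, float(adj))

    out = (
        frame.groupby(["drug_id", "term"])
        .apply(adjust, include_groups=False)
        .rename("frequency")
        .reset_index()
    )
    per_term = out.groupby("term")["drug_id"].nunique()
    keep = per_term.index[per_term >= min_drugs_per_term]
    return out[out["term"].isin(keep)].reset_index(drop=True)


def category_frequency(
    frequencies: pd.DataFrame,
    categories: dict[str, list[str]] | None = None,
    absent_as_zero: bool = True,
) -> pd.DataFrame:
    """Per (drug, category) mean frequency over member terms.

    Under ``absent_as_zero`` (default) the mean is over the full member
    list, with terms not reported for the drug contributing 0; otherwise
    the mean covers only the reported member terms.
    """
    categories = categories if categories is not None else DEFAULT_CATEGORIES
    for name, terms in categories.items():
        if not terms:
            raise ValueError(f"category {name!r} is empty")
    wide = frequencies.pivot_table(
        index="drug_id", columns="term", values="frequency", aggfunc="mean"
    )
    rows = {}
    for name, terms in categories.items():
        present = [t for t in terms if t in wide.columns]
        if not present:
            rows[name] = pd.Series(0.0, index=wide.index)
            continue
        block = wide[present]
        if absent_as_zero:
            rows[name] = block.fillna(0.0).sum(axis=1) / len(terms)
        else:
            rows[name] = block.mean(axis=1, skipna=True).fillna(0.0)
    return pd.DataFrame(rows)


def impact_vs_side_effect(
    impact_index: pd.Series,
    category_freq: pd.Series,
    threshold: float = 0.01,
) -> dict:
    """Wilcoxon rank-sum of mean impact: drugs above vs below a side-effect
    frequency threshold (default 1%)."""
    common = impact_index.index.intersection(category_freq.index)
    freq = category_freq.loc[common]
    high = impact_index.loc[common[freq > threshold]].to_numpy()
    low = impact_index.loc[common[freq <= threshold]].to_numpy()
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"empty group at threshold {threshold} "
            f"(high={len(high)}, low={len(low)})"
        )
    res = stats.mannwhitneyu(high, low, alternative="two-sided")
    return {
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "n_high": len(high),
        "n_low": len(low),
        "median_high": float(np.median(high)),
        "median_low": float(np.median(low)),
        "threshold": threshold,
    }


def specificity_vs_effect(
    specificity_class: pd.Series, term_frequency: pd.Series
) -> dict:
    """One-way ANOVA of a side-effect frequency across specificity classes.

    Classes are bacteroidetes-specific / firmicutes-specific /
    non-specific; each must hold >= 2 drugs. Reports F, p, group means
    and the percent difference between the two specific classes.
    """
    common = specificity_class.index.intersection(term_frequency.index)
    cls = specificity_class.loc[common]
    freq = term_frequency.loc[common]
    expected = {"bacteroidetes-specific", "firmicutes-specific", "non-specific"}
    missing = expected - set(cls.unique())
    if missing:
        raise ValueError(f"missing specificity class(es): {sorted(missing)}")
    groups = {g: freq[cls == g].to_numpy() for g in sorted(expected)}
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"class(es) with < 2 drugs: {small}")
    samples = list(groups.values())
    if all(np.var(s) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*samples)
    means = {g: float(v.mean()) for g, v in groups.items()}
    b, f = means["bacteroidetes-specific"], means["firmicutes-specific"]
    pct = (f - b) / b * 100.0 if b != 0 else np.nan
    return {
        "F": float(f_stat),
        "p_value": float(p),
        "group_means": means,
        "percent_difference_firmicutes_vs_bacteroidetes": float(pct)
        if np.isfinite(pct)
        else None,
    }
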