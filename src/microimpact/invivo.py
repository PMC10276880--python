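"""In-vivo dysbiosis pipeline on processed amplicon (ASV) tables, plus
cohort-summary agreement analysis.

Longitudinal before/after studies are filtered (read depth, prevalence,
abundance), renormalized to relative abundances, and collapsed to one
profile per subject and phase. Per-ASV abundance change is summarized by
a t-statistic (Welch unpaired by default; paired available), and drug-
induced dysbiosis is tested by comparing the model's predicted impact
scores between ASVs that decreased vs increased after treatment (two-
sided Wilcoxon rank-sum with rank-biserial effect size). A shuffled-
feature control re-runs the test after permuting microbe feature rows,
which should destroy the association.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

PHASES = ("before", "after")


@dataclass
class LongitudinalStudy:
    """Samples x ASVs relative abundances with per-sample metadata.

    metadata is indexed by sample id with columns subject_id, phase
    ("before"/"after"), timepoint, read_depth. taxonomy (per-ASV) and
    ko_profiles (ASVs x KOs) ride along untouched by filtering except for
    ASV subsetting.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    ko_profiles: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.abundance.index.equals(self.metadata.index):
            self.metadata = self.metadata.loc[self.abundance.index]


def preprocess_study(
    study: LongitudinalStudy,
    min_reads: int = 1000,
    prevalence: float = 0.005,
    abundance: float = 0.005,
) -> LongitudinalStudy:
    """Filter, renormalize and collapse a longitudinal study.

    Samples with read depth below ``min_reads`` are dropped. ASVs are kept
    iff their relative abundance exceeds ``abundance`` in at least
    ``prevalence`` of the retained samples (rounded up to >= 1 sample).
    Rows are renormalized to sum to 1, then multiple samples of the same
    subject and phase are averaged (and renormalized once more). The
    operation is idempotent.
    """
    meta = study.metadata
    deep = meta["read_depth"] >= min_reads
    if not deep.any():
        raise ValueError(f"no sample has read depth >= {min_reads}")
    ab = study.abundance.loc[deep.index[deep]]
    meta = meta.loc[ab.index]

    row_sums = ab.sum(axis=1)
    rel = ab.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    min_samples = max(1, math.ceil(prevalence * len(rel)))
    keep_asv = (rel > abundance).sum(axis=0) >= min_samples
    if not keep_asv.any():
        raise ValueError("no ASV passes the abundance/prevalence filter")
    rel = rel[keep_asv.index[keep_asv]]
    rel = rel.div(rel.sum(axis=1), axis=0)

    collapsed_rows, collapsed_meta = [], []
    for (subject, phase), grp in meta.groupby(["subject_id", "phase"], sort=True):
        prof = rel.loc[grp.index].mean(axis=0)
        prof = prof / prof.sum()
        sid = f"{subject}__{phase}"
        prof.name = sid
        collapsed_rows.append(prof)
        collapsed_meta.append(
            {
                "sample_id": sid,
                "subject_id": subject,
                "phase": phase,
                "timepoint": 0,
                "read_depth": float(meta.loc[grp.index, "read_depth"].mean()),
            }
        )
    new_ab = pd.DataFrame(collapsed_rows)
    new_meta = pd.DataFrame(collapsed_meta).set_index("sample_id")

    phases_per_subject = new_meta.groupby("subject_id")["phase"].nunique()
    partial = phases_per_subject.index[phases_per_subject < 2]
    if len(partial):
        warnings.warn(f"subjects with a single phase excluded: {sorted(partial)}")
        keep = ~new_meta["subject_id"].isin(partial)
        new_meta = new_meta.loc[keep]
        new_ab = new_ab.loc[new_meta.index]
    tax = study.taxonomy.loc[new_ab.columns] if study.taxonomy is not None else None
    kos = (
        study.ko_profiles.loc[study.ko_profiles.index.intersection(new_ab.columns)]
        if study.ko_profiles is not None
        else None
    )
    return LongitudinalStudy(new_ab, new_meta, tax, kos)


def abundance_change_tstats(
    study: LongitudinalStudy, paired: bool = False
) -> tuple[pd.Series, list[str]]:
    """Per-ASV t-statistic of the abundance change after treatment.

    Welch two-sample t (after vs before) by default; paired t on matched
    subjects when ``paired``. Negative t means the ASV decreased after
    treatment. Returns (t-statistics, ASVs excluded for zero variance).
    """
    meta = study.metadata
    before = study.abundance.loc[meta.index[meta["phase"] == "before"]]
    after = study.abundance.loc[meta.index[meta["phase"] == "after"]]
    if paired:
        subj_b = meta.loc[before.index, "subject_id"]
        subj_a = meta.loc[after.index, "subject_id"]
        common = sorted(set(subj_b) & set(subj_a))
        if len(common) < 2:
            raise ValueError("paired mode needs >= 2 matched subjects")
        before = before.set_index(subj_b).loc[common]
        after = after.set_index(subj_a).loc[common]
    elif len(before) < 2 or len(after) < 2:
        raise ValueError("need >= 2 samples in each phase")
    tstats, excluded = {}, []
    for asv in study.abundance.columns:
        b, a = before[asv].to_numpy(), after[asv].to_numpy()
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                tstats[asv] = 0.0
            else:
                excluded.append(asv)
            continue
        if paired:
            t = stats.ttest_rel(a, b).statistic
        else:
            t = stats.ttest_ind(a, b, equal_var=False).statistic
        if np.isfinite(t):
            tstats[asv] = float(t)
        else:
            excluded.append(asv)
    if excluded:
        warnings.warn(f"{len(excluded)} ASV(s) with undefined t excluded")
    return pd.Series(tstats, name="t"), excluded


@dataclass
class DysbiosisResult:
    """Wilcoxon comparison of impact scores: decreased vs increased ASVs."""

    statistic: float
    p_value: float
    rank_biserial: float
    n_decreased: int
    n_increased: int
    n_zero_t: int
    groups: dict = field(default_factory=dict)


def dysbiosis_test(impact: pd.Series, tstats: pd.Series) -> DysbiosisResult:
    """Two-sided Wilcoxon rank-sum of predicted impact scores between ASVs
    with negative vs positive abundance-change t-statistics.

    The expected direction under true drug impact is higher scores in the
    decreased group (positive rank-biserial r = 2U/(n1 n2) - 1, with U the
    Mann-Whitney statistic of the decreased group).
    """
    common = impact.index.intersection(tstats.index)
    t = tstats.loc[common]
    decreased = impact.loc[common[t < 0]].to_numpy()
    increased = impact.loc[common[t > 0]].to_numpy()
    n_zero = int((t == 0).sum())
    if len(decreased) == 0 or len(increased) == 0:
        raise ValueError(
            f"both groups must be non-empty (decreased={len(decreased)}, "
            f"increased={len(increased)})"
        )
    res = stats.mannwhitneyu(decreased, increased, alternative="two-sided")
    u1 = float(res.statistic)
    r = 2.0 * u1 / (len(decreased) * len(increased)) - 1.0
    return DysbiosisResult(
        statistic=u1,
        p_value=float(res.pvalue),
        rank_biserial=r,
        n_decreased=len(decreased),
        n_increased=len(increased),
        n_zero_t=n_zero,
        groups={
            "decreased_median": float(np.median(decreased)),
            "increased_median": float(np.median(increased)),
        },
    )


def shuffled_feature_control(
    model,
    drug_features_row: pd.Series,
    asv_features: pd.DataFrame,
    tstats: pd.Series,
    n_shuffles: int,
    seed: int = 0,
) -> np.ndarray:
    """Null p-value distribution from permuting microbe feature rows.

    Each shuffle reassigns the ASVs' feature vectors among the ASV ids
    before prediction, then repeats the dysbiosis test against the fixed
    t-statistics. With true signal the resulting p-values are ~uniform.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    microbe_cols = list(asv_features.columns)
    pvals = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(len(asv_features))
        shuffled = pd.DataFrame(
            asv_features.to_numpy()[perm],
            index=asv_features.index,
            columns=microbe_cols,
        )
        X = pd.concat(
            [
                shuffled,
                pd.DataFrame(
                    [drug_features_row] * len(shuffled), index=shuffled.index
                ),
            ],
            axis=1,
        )
        scores = pd.Series(
            model.estimator.impact_scores(model.check_features(X)),
            index=shuffled.index,
        )
        pvals[i] = dysbiosis_test(scores, tstats).p_value
    return pvals


def cohort_agreement(
    catalog: pd.DataFrame,
    associations: pd.DataFrame,
    drug_groups: dict[str, list[str]] | None = None,
    taxon_groups: dict[str, list[str]] | None = None,
    min_associations: int = 30,
) -> dict:
    """Agreement between predicted impact and cohort association summaries.

    ``associations`` is a long table (taxon, drug_group, effect_size) of
    signed regression effect sizes (negative = drug depletes the taxon).
    Observed drug impact = mean effect size over its associated taxa;
    observed taxon sensitivity = mean effect size over its associated
    drugs. Predictions are averaged over group members when a drug group
    or taxon maps to several catalog ids. Pearson and Spearman
    correlations are reported (expected negative), and for drug groups
    with strictly more than ``min_associations`` associations, a two-
    sided Wilcoxon compares predicted scores of negatively vs positively
    associated taxa.
    """
    drug_groups = drug_groups or {}
    taxon_groups = taxon_groups or {}
    wide = catalog.pivot(index="drug_id", columns="microbe_id", values="impact_score")

    def predicted(drug_group: str, taxon: str) -> float | None:
        d_ids = [d for d in drug_groups.get(drug_group, [drug_group]) if d in wide.index]
        m_ids = [m for m in taxon_groups.get(taxon, [taxon]) if m in wide.columns]
        if not d_ids or not m_ids:
            return None
        return float(wide.loc[d_ids, m_ids].to_numpy().mean())

    assoc = associations.copy()
    assoc["predicted"] = [
        predicted(r["drug_group"], r["taxon"]) for _, r in assoc.iterrows()
    ]
    dropped = assoc["predicted"].isna()
    if dropped.any():
        warnings.warn(
            f"{int(dropped.sum())} association(s) unmappable to the catalog; dropped"
        )
    assoc = assoc.loc[~dropped]

    per_drug = assoc.groupby("drug_group").agg(
        observed_impact=("effect_size", "mean"),
        predicted_impact=("predicted", "mean"),
        n_associations=("effect_size", "size"),
    )
    per_taxon = assoc.groupby("taxon").agg(
        observed_sensitivity=("effect_size", "mean"),
        predicted_sensitivity=("predicted", "mean"),
        n_associations=("effect_size", "size"),
    )

    def corr(frame: pd.DataFrame, obs: str, pred: str) -> dict:
        if len(frame) < 3 or frame[obs].nunique() < 2 or frame[pred].nunique() < 2:
            return {"pearson_r": None, "spearman_rho": None, "n": len(frame)}
        pr = stats.pearsonr(frame[pred], frame[obs])
        sr = stats.spearmanr(frame[pred], frame[obs])
        return {
            "pearson_r": float(pr.statistic),
            "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic),
            "spearman_p": float(sr.pvalue),
            "n": len(frame),
        }

    big: dict[str, dict] = {}
    for g, grp in assoc.groupby("drug_group"):
        if len(grp) <= min_associations:
            continue
        neg = grp.loc[grp["effect_size"] < 0, "predicted"].to_numpy()
        pos = grp.loc[grp["effect_size"] > 0, "predicted"].to_numpy()
        if len(neg) == 0 or len(pos) == 0:
            continue
        res = stats.mannwhitneyu(neg, pos, alternative="two-sided")
        big[g] = {
            "p_value": float(res.pvalue),
            "rank_biserial": 2.0 * float(res.statistic) / (len(neg) * len(pos)) - 1.0,
            "n_negative": len(neg),
            "n_positive": len(pos),
        }
    return {
        "per_drug": per_drug,
        "per_taxon": per_taxon,
        "drug_correlation": corr(per_drug, "observed_impact", "predicted_impact"),
        "taxon_correlation": corr(
            per_taxon, "observed_sensitivity", "predicted_sensitivity"
        ),
        "high_burden_drug_tests": big,
    }
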