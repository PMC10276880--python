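"""Microbe featurization: KO annotations to partitioned pathway scores.

A genome annotated with KEGG Orthology groups (KOs) is summarized as a
vector of pathway scores. The score of a pathway is the number of KO
copies the genome carries from that pathway, with KOs that belong to m
pathways contributing 1/m of each copy to every one of them (equal
partitioning). Total mass is therefore conserved: summed over pathways,
the scores equal the number of mapped KO copies in the genome. Fractional
counts are accepted so that predicted per-ASV KO profiles (e.g. PICRUSt2
output) can flow through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .registries import pathway_ids


@dataclass
class MicrobeRecord:
    """A genome (or ASV) with its KO content and optional annotations."""

    microbe_id: str
    ko_counts: Mapping[str, float] = field(default_factory=dict)
    taxonomy: Mapping[str, str] = field(default_factory=dict)
    gram_stain: str = "unknown"

    def __post_init__(self):
        bad = {k: v for k, v in self.ko_counts.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive KO counts for {self.microbe_id}: {bad}")


class PathwayMap:
    """pathway_id -> set of member KOs, with derived KO multiplicity."""

    def __init__(self, pathways: Mapping[str, set[str]]):
        self.pathways: dict[str, frozenset[str]] = {}
        for pid, kos in pathways.items():
            if not kos:
                raise ValueError(f"pathway {pid} is empty")
            self.pathways[pid] = frozenset(kos)
        mult: dict[str, int] = {}
        for kos in self.pathways.values():
            for k in kos:
                mult[k] = mult.get(k, 0) + 1
        self.ko_multiplicity = mult

    def __len__(self) -> int:
        return len(self.pathways)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayMap":
        """Build from a long table with columns pathway_id, ko_id."""
        grouped = frame.groupby("pathway_id")["ko_id"].agg(set)
        return cls(grouped.to_dict())


def pathway_scores(
    microbe: MicrobeRecord, pathway_map: PathwayMap, pathway_list=None
) -> pd.Series:
    """Partitioned pathway score vector for one genome.

    score(p) = sum over KOs k in the genome and in p of count(k) / m(k),
    where m(k) is the number of pathways containing k. Pathways in
    ``pathway_list`` absent from the map (or with no genome hits) score 0.
    """
    if len(pathway_map) == 0:
        raise ValueError("pathway map is empty")
    order = list(pathway_list) if pathway_list is not None else sorted(
        pathway_map.pathways
    )
    scores = pd.Series(0.0, index=order, name=microbe.microbe_id)
    mult = pathway_map.ko_multiplicity
    for pid in order:
        kos = pathway_map.pathways.get(pid)
        if kos is None:
            continue
        total = 0.0
        for k in kos:
            c = microbe.ko_counts.get(k)
            if c:
                total += c / mult[k]
        scores[pid] = total
    return scores


def build_feature_matrix(
    microbes, pathway_map: PathwayMap, pathway_list=None
) -> pd.DataFrame:
    """Microbes x pathways score matrix, rows in input order."""
    ids = [m.microbe_id for m in microbes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate microbe_id(s): {dupes}")
    rows = [pathway_scores(m, pathway_map, pathway_list) for m in microbes]
    return pd.DataFrame(rows)


class PathwayScorer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer over ``pathway_scores``.

    Parameters
    ----------
    pathway_map : PathwayMap
    pathways : sequence of str, optional
        Output column order; defaults to the packaged 148-pathway registry.
    """

    def __init__(self, pathway_map=None, pathways=None):
        self.pathway_map = pathway_map
        self.pathways = pathways

    def fit(self, X, y=None):
        if self.pathway_map is None or len(self.pathway_map) == 0:
            raise ValueError("a non-empty pathway_map is required")
        self.pathways_ = (
            list(self.pathways) if self.pathways is not None else list(pathway_ids())
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        return build_feature_matrix(X, self.pathway_map, self.pathways_)


def records_from_ko_table(frame: pd.DataFrame) -> list[MicrobeRecord]:
    """Build records from a long table: microbe_id, ko_id[, count]."""
    if "count" not in frame.columns:
        frame = frame.assign(count=1.0)
    records = []
    for mid, grp in frame.groupby("microbe_id", sort=False):
        counts = grp.groupby("ko_id")["count"].sum().to_dict()
        records.append(MicrobeRecord(str(mid), counts))
    return records
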