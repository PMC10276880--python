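"""Readers and writers for the plain-text table formats the tool consumes.

All tables are UTF-8 TSV with a header row; ``.gz`` paths are handled
transparently by pandas. Every written artifact can carry a JSON sidecar
recording the seed and a configuration hash for auditability.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .chemspace import DrugRecord
from .genomefeat import PathwayMap, records_from_ko_table
from .invivo import LongitudinalStudy


class SchemaError(ValueError):
    """An input table is missing required columns."""


def _require(frame: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_table(path) -> pd.DataFrame:
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_drug_table(path) -> list[DrugRecord]:
    """drug_id, smiles[, name, atc, class]; atc is ;-separated codes."""
    frame = read_table(path)
    _require(frame, ["drug_id", "smiles"], path)
    records = []
    for _, row in frame.iterrows():
        atc = row.get("atc")
        codes = str(atc).split(";") if isinstance(atc, str) and atc else []
        records.append(
            DrugRecord(
                str(row["drug_id"]),
                smiles=row["smiles"] if isinstance(row["smiles"], str) else None,
                name=row.get("name"),
                atc_codes=codes,
                drug_class=row.get("class"),
            )
        )
    return records


def read_ko_annotations(path):
    frame = read_table(path)
    _require(frame, ["microbe_id", "ko_id"], path)
    return records_from_ko_table(frame)


def read_pathway_map(path) -> PathwayMap:
    frame = read_table(path)
    _require(frame, ["pathway_id", "ko_id"], path)
    return PathwayMap.from_frame(frame)


def read_interactions(path) -> pd.DataFrame:
    frame = read_table(path)
    _require(frame, ["drug_id", "microbe_id", "label"], path)
    return frame


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_study(abundance_path, metadata_path, taxonomy_path=None, ko_path=None) -> LongitudinalStudy:
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    _require(metadata.reset_index(), ["subject_id", "phase", "read_depth"], metadata_path)
    taxonomy = (
        pd.read_csv(taxonomy_path, sep="\t", index_col=0) if taxonomy_path else None
    )
    kos = None
    if ko_path:
        long = read_table(ko_path)
        _require(long, ["asv_id", "ko_id", "abundance"], ko_path)
        kos = long.pivot_table(
            index="asv_id", columns="ko_id", values="abundance", fill_value=0.0
        )
    return LongitudinalStudy(abundance, metadata, taxonomy, kos)


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_with_sidecar(frame: pd.DataFrame, path, seed=None, config=None, index=True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
    sidecar = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "rows": len(frame),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
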