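"""Shared fixtures: one small planted screen reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from microimpact import synthetic_data as sd
from microimpact.genomefeat import build_feature_matrix

FAST_FOREST = {"n_estimators": 60}


@pytest.fixture(scope="session")
def small_screen():
    """30 drugs x 12 taxa SMILES-backed screen with a strong planted rule."""
    drugs = sd.gen_drugs(30, seed=5, mode="smiles-fixture")
    pmap = sd.gen_pathway_map(n_kos=300, seed=5)
    panel = sd.gen_genomes(12, pmap, seed=5, phylo_signal=0.8)
    microbe_features = build_feature_matrix(panel.records, pmap)
    rule = sd.default_rule(2.5)
    dataset = sd.plant_labels(
        drugs.features, microbe_features, rule, seed=6, families=drugs.families
    )
    return {
        "drugs": drugs,
        "pathway_map": pmap,
        "panel": panel,
        "microbe_features": microbe_features,
        "rule": rule,
        "dataset": dataset,
    }


@pytest.fixture(scope="session")
def tiny_catalog():
    """Deterministic 6 drugs x 6 microbes catalog with phylum structure."""
    rng = np.random.default_rng(42)
    drugs = [f"d{i}" for i in range(6)]
    microbes = [f"m{i}" for i in range(6)]
    rows = [
        {"drug_id": d, "microbe_id": m, "impact_score": rng.uniform()}
        for d in drugs
        for m in microbes
    ]
    catalog = pd.DataFrame(rows)
    taxonomy = pd.Series(
        ["Firmicutes"] * 3 + ["Bacteroidetes"] * 3, index=microbes, name="phylum"
    )
    return catalog, taxonomy
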