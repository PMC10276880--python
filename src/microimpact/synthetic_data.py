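"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here: drug libraries
(either abstract descriptor vectors with configured marginals, or small
real SMILES enumerated from scaffold/substituent combinations so the
actual RDKit code paths run), KO-annotated genomes with phylogenetic
structure (KO presence thresholded from a Brownian trait evolved on a
random birth-death tree), binary interaction screens labelled by a
planted logistic rule over chosen causal features, and longitudinal
before/after abundance studies in which taxa are depleted in proportion
to a supplied impact profile.

Defaults emulate the reference screen's conditions: an intercept of
-1.81 gives ~1:6.1 label imbalance under a null rule, and the default
planted rule uses one lipophilicity-like drug descriptor plus one
transporter-like pathway as causal features.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .chemspace import BitFingerprint, DrugRecord, compute_descriptors, compute_fingerprints
from .genomefeat import MicrobeRecord, PathwayMap
from .invivo import LongitudinalStudy
from .model import InteractionDataset
from .registries import drug_descriptor_names, pathway_ids

# Realistic marginals for a handful of named descriptors; everything else
# defaults to standard normal. (family, param1, param2)
DEFAULT_MARGINALS: dict[str, tuple[str, float, float]] = {
    "MolWt": ("lognormal", 5.8, 0.45),
    "MolLogP": ("normal", 2.5, 1.8),
    "TPSA": ("lognormal", 4.2, 0.6),
    "NumHDonors": ("lognormal", 0.7, 0.7),
    "NumHAcceptors": ("lognormal", 1.4, 0.5),
    "NumRotatableBonds": ("lognormal", 1.6, 0.6),
    "Kappa1": ("lognormal", 2.6, 0.4),
}


@dataclass
class PlantedRule:
    """Ground-truth logistic labelling rule for synthetic screens.

    label ~ Bernoulli(sigmoid(beta0 + beta_drug . z(x_d) + beta_microbe .
    z(x_m) + beta_interaction * z_d1 * z_m1 + family_effect + eps)), with
    z the library z-score of each causal feature, an optional per-
    scaffold-family random intercept (similar molecules share activity),
    and eps ~ Normal(0, noise_scale).
    """

    beta0: float = -1.81
    beta_drug: dict[str, float] = field(default_factory=dict)
    beta_microbe: dict[str, float] = field(default_factory=dict)
    beta_interaction: float = 0.0
    noise_scale: float = 0.0
    family_sd: float = 0.0
    realized_prevalence: float | None = None


def default_rule(strength: float = 2.0, **kw) -> PlantedRule:
    """The package's default planted rule: one lipophilicity-like drug
    descriptor and one transporter-like pathway as causal features."""
    return PlantedRule(
        beta_drug={"MolLogP": strength},
        beta_microbe={"ko02010": strength},
        **kw,
    )


@dataclass
class DrugLibrary:
    records: list[DrugRecord]
    features: pd.DataFrame
    fingerprints: dict[str, BitFingerprint] | None = None
    families: pd.Series | None = None  # drug_id -> scaffold family


_SCAFFOLDS = [
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCCCC1",        # cyclohexane
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccoc1",         # furan
    "c1ccsc1",         # thiophene
    "C1CCNCC1",        # piperidine
    "c1cnc2[nH]cnc2n1",  # purine
    "C1COCCN1",        # morpholine
]
_SUBSTITUENTS = ["", "C", "CC", "CCC", "CCCC", "O", "OC", "N", "NC", "Cl",
                 "Br", "F", "C(=O)O", "C(=O)N", "S", "OCC", "C(C)C", "CO",
                 "CN", "C=C"]


def gen_drugs(
    n: int,
    seed: int = 0,
    mode: str = "descriptor-space",
    marginals: dict | None = None,
    descriptor_list=None,
) -> DrugLibrary:
    """Generate a drug library of size ``n``.

    ``descriptor-space`` samples descriptor vectors directly from the
    configured marginal distributions (fast, no chemistry).
    ``smiles-fixture`` enumerates substituted variants of simple valid
    scaffolds, so descriptors and fingerprints come from the real
    featurization code; each drug carries its scaffold family id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "descriptor-space":
        names = list(descriptor_list or drug_descriptor_names())
        marg = dict(DEFAULT_MARGINALS)
        marg.update(marginals or {})
        cols = {}
        for name in names:
            fam, p1, p2 = marg.get(name, ("normal", 0.0, 1.0))
            if fam == "normal":
                cols[name] = rng.normal(p1, p2, size=n)
            elif fam == "lognormal":
                cols[name] = rng.lognormal(p1, p2, size=n)
            else:
                raise ValueError(f"unknown marginal family {fam!r} for {name}")
        ids = [f"d{i:04d}" for i in range(n)]
        feats = pd.DataFrame(cols, index=ids)
        records = [DrugRecord(i) for i in ids]
        return DrugLibrary(records, feats)
    if mode != "smiles-fixture":
        raise ValueError("mode must be 'descriptor-space' or 'smiles-fixture'")

    combos = [
        (si, f"{sub}{scaf}" if sub else scaf)
        for si, scaf in enumerate(_SCAFFOLDS)
        for sub in _SUBSTITUENTS
    ]
    # double substitution extends the library when n is large
    if n > len(combos):
        extra = [
            (si, f"{s1}{scaf.replace('1', '1', 1)}" )
            for si, scaf in enumerate(_SCAFFOLDS)
            for s1 in _SUBSTITUENTS
        ]
        combos = combos + [
            (si, f"{sub}C{scaf}")
            for si, scaf in enumerate(_SCAFFOLDS)
            for sub in _SUBSTITUENTS
        ]
        del extra
    if n > len(combos):
        raise ValueError(f"smiles-fixture mode supports at most {len(combos)} drugs")
    order = rng.permutation(len(combos))[:n]
    records, families = [], {}
    for k, idx in enumerate(sorted(order)):
        fam, smi = combos[idx]
        did = f"d{k:04d}"
        records.append(DrugRecord(did, smiles=smi))
        families[did] = fam
    feats, invalid = compute_descriptors(records, descriptor_list=descriptor_list)
    if invalid:  # defensive: scaffold enumeration should always parse
        records = [r for r in records if r.drug_id not in set(invalid)]
    fps = compute_fingerprints(records)
    return DrugLibrary(
        records, feats, fingerprints=fps,
        families=pd.Series(families, name="family").loc[feats.index],
    )


def gen_pathway_map(
    n_pathways: int = 148,
    n_kos: int = 600,
    seed: int = 0,
    mean_pathway_size: float = 8.0,
    max_multiplicity: int = 3,
) -> PathwayMap:
    """Random KO -> pathway map with realistic shared membership."""
    rng = np.random.default_rng(seed)
    pids = list(pathway_ids())[:n_pathways]
    if len(pids) < n_pathways:
        pids += [f"path{i:05d}" for i in range(len(pids), n_pathways)]
    kos = [f"K{i:05d}" for i in range(n_kos)]
    pathways: dict[str, set[str]] = {p: set() for p in pids}
    for ko in kos:
        mult = rng.integers(1, max_multiplicity + 1)
        for p in rng.choice(len(pids), size=mult, replace=False):
            pathways[pids[p]].add(ko)
    empty = [p for p, s in pathways.items() if not s]
    for p in empty:  # keep the invariant that every pathway is non-empty
        pathways[p].add(kos[int(rng.integers(0, n_kos))])
    del mean_pathway_size
    return PathwayMap(pathways)


@dataclass
class GenomePanel:
    records: list[MicrobeRecord]
    tree: dendropy.Tree
    distances: pd.DataFrame
    taxonomy: pd.DataFrame  # index microbe_id: phylum, gram_stain


def gen_genomes(
    n_taxa: int,
    pathway_map: PathwayMap,
    seed: int = 0,
    phylo_signal: float = 0.8,
) -> GenomePanel:
    """Simulate KO-annotated genomes on a random bifurcating tree.

    Per KO, a Brownian trait is evolved along the tree and mixed with an
    independent normal component: trait = sqrt(s) * z_BM + sqrt(1-s) *
    z_iid, where s = ``phylo_signal``. Presence is the trait exceeding a
    per-KO threshold drawn so that marginal carriage is ~25-75%. The two
    basal clades of the tree define two "phyla" (named Firmicutes and
    Bacteroidetes so downstream phylum analytics run unmodified), and
    each phylum's first internal split defines the gram-stain label.
    """
    if len(pathway_map) == 0:
        raise ValueError("pathway map is empty")
    if not 0.0 <= phylo_signal <= 1.0:
        raise ValueError("phylo_signal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    tips = tree.leaf_nodes()
    ids = [f"m{i:04d}" for i in range(len(tips))]
    for tip, mid in zip(tips, ids):
        tip.taxon.label = mid

    kos = sorted(pathway_map.ko_multiplicity)
    n_kos = len(kos)
    bm: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            bm[id(node)] = np.zeros(n_kos)
        else:
            el = node.edge.length or 0.0
            bm[id(node)] = bm[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(max(el, 1e-9)), size=n_kos
            )
    tip_bm = np.vstack([bm[id(t)] for t in tips])
    sd = tip_bm.std(axis=0)
    z_bm = (tip_bm - tip_bm.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    z_iid = rng.normal(size=(len(tips), n_kos))
    s = phylo_signal
    trait = np.sqrt(s) * z_bm + np.sqrt(1.0 - s) * z_iid
    from scipy.stats import norm

    carriage = rng.uniform(0.25, 0.75, size=n_kos)
    thresholds = norm.ppf(1.0 - carriage)
    presence = trait > thresholds

    # basal clades -> phyla; first split within each -> gram stain
    root_children = tree.seed_node.child_nodes()
    phylum_names = ["Firmicutes", "Bacteroidetes"]
    phylum: dict[str, str] = {}
    gram: dict[str, str] = {}
    for ci, child in enumerate(root_children):
        pname = phylum_names[min(ci, 1)]
        sub_children = child.child_nodes() or [child]
        for gi, sub in enumerate(sub_children):
            glabel = "positive" if gi % 2 == 0 else "negative"
            for leaf in sub.leaf_iter():
                phylum[leaf.taxon.label] = pname
                gram[leaf.taxon.label] = glabel
        if child.is_leaf():
            phylum[child.taxon.label] = pname
            gram[child.taxon.label] = "positive"

    records = []
    for i, mid in enumerate(ids):
        counts = {kos[j]: 1 for j in np.flatnonzero(presence[i])}
        records.append(
            MicrobeRecord(
                mid,
                counts,
                taxonomy={"phylum": phylum[mid]},
                gram_stain=gram[mid],
            )
        )
    pdm = tree.phylogenetic_distance_matrix()
    dist = pd.DataFrame(0.0, index=ids, columns=ids)
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d = pdm.patristic_distance(taxa[a], taxa[ids[j]])
            dist.iloc[i, j] = dist.iloc[j, i] = d
    taxonomy = pd.DataFrame(
        {"phylum": pd.Series(phylum), "gram_stain": pd.Series(gram)}
    ).loc[ids]
    return GenomePanel(records, tree, dist, taxonomy)


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    return (col - col.mean()) / (sd if sd > 0 else 1.0)


def plant_labels(
    drug_features: pd.DataFrame,
    microbe_features: pd.DataFrame,
    rule: PlantedRule,
    seed: int = 0,
    families: pd.Series | None = None,
) -> InteractionDataset:
    """Label the full drugs x microbes cross product with the planted rule."""
    for name in rule.beta_drug:
        if name not in drug_features.columns:
            raise KeyError(f"causal drug feature {name!r} not in features")
    for name in rule.beta_microbe:
        if name not in microbe_features.columns:
            raise KeyError(f"causal microbe feature {name!r} not in features")
    rng = np.random.default_rng(seed)
    drugs = list(drug_features.index)
    microbes = list(microbe_features.index)

    drug_term = pd.Series(0.0, index=drugs)
    for name, beta in rule.beta_drug.items():
        drug_term += beta * _zscore(drug_features[name])
    microbe_term = pd.Series(0.0, index=microbes)
    for name, beta in rule.beta_microbe.items():
        microbe_term += beta * _zscore(microbe_features[name])

    if rule.family_sd > 0:
        if families is None:
            raise ValueError("family_sd > 0 requires per-drug families")
        fam_levels = sorted(families.unique())
        effects = rng.normal(0.0, rule.family_sd, size=len(fam_levels))
        fam_effect = families.map(dict(zip(fam_levels, effects)))
        drug_term = drug_term + fam_effect.loc[drugs]

    z_d1 = (
        _zscore(drug_features[next(iter(rule.beta_drug))])
        if rule.beta_drug
        else pd.Series(0.0, index=drugs)
    )
    z_m1 = (
        _zscore(microbe_features[next(iter(rule.beta_microbe))])
        if rule.beta_microbe
        else pd.Series(0.0, index=microbes)
    )

    for attempt in range(2):
        logit = (
            rule.beta0
            + np.repeat(drug_term.to_numpy(), len(microbes))
            + np.tile(microbe_term.to_numpy(), len(drugs))
            + rule.beta_interaction
            * np.repeat(z_d1.to_numpy(), len(microbes))
            * np.tile(z_m1.to_numpy(), len(drugs))
        )
        if rule.noise_scale > 0:
            logit = logit + rng.normal(0.0, rule.noise_scale, size=len(logit))
        prob = 1.0 / (1.0 + np.exp(-logit))
        labels = (rng.random(len(prob)) < prob).astype(int)
        if 0 < labels.mean() < 1:
            break
        warnings.warn("degenerate label realization; resampling once")
    else:
        raise ValueError("planted rule produced all-0 or all-1 labels twice")
    rule.realized_prevalence = float(labels.mean())
    pairs = pd.DataFrame(
        {
            "drug_id": np.repeat(drugs, len(microbes)),
            "microbe_id": np.tile(microbes, len(drugs)),
            "label": labels,
        }
    )
    return InteractionDataset(pairs, drug_features, microbe_features)


def gen_longitudinal(
    impact: pd.Series,
    n_subjects: int = 20,
    effect_strength: float = 2.0,
    seed: int = 0,
    depth: int = 10000,
    samples_per_phase: int = 1,
    low_depth_samples: int = 0,
    low_depth: int = 800,
    concentration: float = 50.0,
) -> LongitudinalStudy:
    """Simulate a before/after treatment study driven by an impact profile.

    Baseline compositions are Dirichlet draws around a shared community
    profile; after treatment each taxon's abundance is multiplied by
    exp(-effect_strength * impact score) and the composition renormalized
    (a compositional depletion). Reads are multinomial at ``depth``;
    ``low_depth_samples`` extra shallow samples exercise the read-depth
    filter downstream.
    """
    taxa = list(impact.index)
    if len(taxa) < 5:
        raise ValueError("need >= 5 taxa")
    rng = np.random.default_rng(seed)
    base_profile = rng.dirichlet(np.ones(len(taxa)) * 2.0)
    depletion = np.exp(-effect_strength * impact.to_numpy())

    rows, meta = [], []
    for s in range(n_subjects):
        baseline = rng.dirichlet(base_profile * concentration)
        after_comp = baseline * depletion
        after_comp = after_comp / after_comp.sum()
        for phase, comp in (("before", baseline), ("after", after_comp)):
            for rep in range(samples_per_phase):
                counts = rng.multinomial(depth, comp)
                sid = f"s{s:03d}_{phase}_{rep}"
                rows.append(pd.Series(counts / depth, index=taxa, name=sid))
                meta.append(
                    {
                        "sample_id": sid,
                        "subject_id": f"s{s:03d}",
                        "phase": phase,
                        "timepoint": rep,
                        "read_depth": depth,
                    }
                )
    for k in range(low_depth_samples):
        comp = rng.dirichlet(base_profile * concentration)
        counts = rng.multinomial(low_depth, comp)
        sid = f"shallow{k:02d}_before_0"
        rows.append(pd.Series(counts / low_depth, index=taxa, name=sid))
        meta.append(
            {
                "sample_id": sid,
                "subject_id": f"shallow{k:02d}",
                "phase": "before",
                "timepoint": 0,
                "read_depth": low_depth,
            }
        )
    abundance = pd.DataFrame(rows)
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return LongitudinalStudy(abundance, metadata)
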