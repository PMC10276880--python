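"""Canonical feature registries.

The package ships a fixed, ordered registry of 92 molecular descriptors
(computable with RDKit from a SMILES string) and 148 KEGG-style pathway
identifiers. Registries fix feature identity and ordering across a run so
that trained models, catalogs and importance reports are comparable.
Both registries can be overridden with user-supplied lists.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache


@lru_cache(maxsize=None)
def drug_descriptor_names() -> tuple[str, ...]:
    """The canonical ordered list of 92 drug descriptor names."""
    text = (
        importlib.resources.files("microimpact.data")
        .joinpath("drug_descriptors.txt")
        .read_text()
    )
    names = tuple(line.strip() for line in text.splitlines() if line.strip())
    return names


@lru_cache(maxsize=None)
def pathway_registry() -> dict[str, str]:
    """The canonical ordered mapping of 148 pathway ids to display names."""
    text = (
        importlib.resources.files("microimpact.data")
        .joinpath("pathways.tsv")
        .read_text()
    )
    out: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        pid, name = line.split("\t", 1)
        out[pid] = name
    return out


def pathway_ids() -> tuple[str, ...]:
    return tuple(pathway_registry())


_FAMILY_PREFIXES = [
    ("PEOE_VSA", "partial charge surface (PEOE)"),
    ("SlogP_VSA", "lipophilicity surface (SlogP)"),
    ("SMR_VSA", "molar refractivity surface (SMR)"),
    ("VSA_EState", "electrotopological surface (EState)"),
    ("EState", "electrotopological state"),
    ("Chi", "chi connectivity"),
    ("Kappa", "kappa shape"),
    ("MolLogP", "lipophilicity"),
    ("MolMR", "molar refractivity"),
    ("TPSA", "polar surface area"),
    ("NumH", "hydrogen bonding"),
    ("NHOHCount", "hydrogen bonding"),
    ("NOCount", "hydrogen bonding"),
]

_CHARGE_NAMES = {
    "MaxPartialCharge",
    "MinPartialCharge",
    "MaxAbsPartialCharge",
    "MinAbsPartialCharge",
}
_SIZE_NAMES = {
    "MolWt",
    "HeavyAtomMolWt",
    "ExactMolWt",
    "HeavyAtomCount",
    "NumValenceElectrons",
    "LabuteASA",
}


def descriptor_family(name: str) -> str:
    """Coarse family label for a descriptor (used for grouped reporting)."""
    if name in _CHARGE_NAMES:
        return "partial charge"
    if name in _SIZE_NAMES:
        return "size"
    if "EStateIndex" in name:
        return "electrotopological state"
    for prefix, family in _FAMILY_PREFIXES:
        if name.startswith(prefix):
            return family
    if "Ring" in name or name in {"FractionCSP3", "BalabanJ", "BertzCT", "HallKierAlpha"}:
        return "topology"
    return "composition"


def pathway_category(pathway_id: str) -> str:
    """Coarse KEGG-style category from the numeric pathway id range."""
    try:
        num = int(pathway_id.lstrip("komap"))
    except ValueError:
        return "unknown"
    if num < 200:
        return "carbohydrate and energy metabolism"
    if num < 300:
        return "nucleotide metabolism"
    if num < 500:
        return "amino acid metabolism"
    if num < 600:
        return "glycan and lipid metabolism"
    if num < 700:
        return "carbohydrate and energy metabolism"
    if num < 900:
        return "cofactor and vitamin metabolism"
    if num < 1000:
        return "secondary metabolite and xenobiotic metabolism"
    if num < 2000:
        return "antibiotic biosynthesis and resistance"
    if num < 3000:
        return "membrane transport and signalling"
    return "genetic information processing"
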