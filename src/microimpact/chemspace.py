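"""Drug featurization from SMILES: physicochemical descriptors and
topological fingerprints.

Each compound is summarized by an ordered vector of molecular descriptors
(the canonical registry holds 92 of them: lipophilicity, partial-charge
surface terms, TPSA, hydrogen bonding counts, kappa shape and chi
connectivity indices, molecular weight, ...) and by a hashed topological
path fingerprint used for Tanimoto similarity. SMILES are canonicalized and
salts stripped to the largest organic fragment before featurization, since
drug-library SMILES frequently carry counter-ions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .registries import drug_descriptor_names

RDLogger.DisableLog("rdApp.*")

DRUG_CLASSES = (
    "human-targeted",
    "antibacterial",
    "antifungal",
    "antiviral",
    "antiparasitic",
)


@dataclass
class DrugRecord:
    """A compound in a drug library."""

    drug_id: str
    smiles: str | None = None
    name: str | None = None
    atc_codes: list[str] = field(default_factory=list)
    drug_class: str | None = None

    def atc_level1(self) -> list[str]:
        """Distinct ATC level-1 letters (first character of each code)."""
        return sorted({c[0].upper() for c in self.atc_codes if c})


@dataclass(frozen=True)
class BitFingerprint:
    """Hashed topological path fingerprint as a set of on-bit indices."""

    drug_id: str
    bits: frozenset[int]
    n_bits: int = 2048


class ConfigurationError(ValueError):
    """Raised for unknown descriptor names or unusable libraries."""


_DESCRIPTOR_FUNCS = dict(Descriptors._descList)


def _standardize(smiles: str) -> Chem.Mol | None:
    """Parse, keep the largest organic fragment, and canonicalize."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        def key(m: Chem.Mol) -> tuple[int, int]:
            has_c = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
            return (int(has_c), m.GetNumHeavyAtoms())

        mol = max(frags, key=key)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return None
    return mol


def canonical_smiles(smiles: str) -> str | None:
    mol = _standardize(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


class DrugFeaturizer(TransformerMixin, BaseEstimator):
    """Compute an ordered descriptor matrix for a drug library.

    sklearn-style transformer: ``fit`` learns per-descriptor imputation
    medians on a library; ``transform`` returns a drugs x descriptors
    DataFrame in fixed registry order. Descriptors that come back
    NaN/inf for a molecule (e.g. partial-charge terms on exotic atoms)
    are imputed per the policy and the affected drugs flagged.

    Parameters
    ----------
    descriptors : sequence of str, optional
        Descriptor registry; defaults to the packaged 92-name list. Every
        name must be a known RDKit descriptor.
    impute : {"median", "zero", "none"}
        Replacement for NaN/inf descriptor values.
    """

    def __init__(self, descriptors=None, impute: str = "median"):
        self.descriptors = descriptors
        self.impute = impute

    def _resolved(self) -> list[str]:
        names = list(self.descriptors) if self.descriptors is not None else list(
            drug_descriptor_names()
        )
        if not names:
            raise ConfigurationError("descriptor list is empty")
        unknown = [n for n in names if n not in _DESCRIPTOR_FUNCS]
        if unknown:
            raise ConfigurationError(f"unknown descriptor name(s): {unknown}")
        return names

    def _raw_matrix(self, records) -> tuple[pd.DataFrame, list[str]]:
        names = self._resolved()
        rows, index, invalid = [], [], []
        for rec in records:
            mol = _standardize(rec.smiles) if rec.smiles else None
            if mol is None:
                invalid.append(rec.drug_id)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = [_DESCRIPTOR_FUNCS[n](mol) for n in names]
            rows.append(vals)
            index.append(rec.drug_id)
        mat = pd.DataFrame(rows, index=index, columns=names, dtype=float)
        mat = mat.replace([np.inf, -np.inf], np.nan)
        return mat, invalid

    def fit(self, X, y=None):
        mat, invalid = self._raw_matrix(X)
        if mat.empty:
            raise ConfigurationError("no parseable SMILES in the library")
        self.feature_names_out_ = list(mat.columns)
        self.medians_ = mat.median(axis=0, skipna=True).fillna(0.0)
        self.invalid_ids_ = invalid
        return self

    def transform(self, X) -> pd.DataFrame:
        mat, invalid = self._raw_matrix(X)
        self.invalid_ids_ = invalid
        if invalid:
            warnings.warn(
                f"{len(invalid)} record(s) with unparseable SMILES: {invalid[:5]}...",
                stacklevel=2,
            )
        flagged = mat.index[mat.isna().any(axis=1)]
        self.imputed_ids_ = list(flagged)
        if self.impute == "median":
            mat = mat.fillna(self.medians_)
        elif self.impute == "zero":
            mat = mat.fillna(0.0)
        elif self.impute != "none":
            raise ConfigurationError(f"unknown impute policy {self.impute!r}")
        return mat


def compute_descriptors(
    records, descriptor_list=None, impute_policy: str = "median"
) -> tuple[pd.DataFrame, list[str]]:
    """Descriptor matrix (drugs x descriptors) plus the unparseable ids."""
    feat = DrugFeaturizer(descriptors=descriptor_list, impute=impute_policy)
    feat.fit(records)
    mat = feat.transform(records)
    return mat, feat.invalid_ids_


def compute_fingerprints(
    records, n_bits: int = 2048, min_path: int = 1, max_path: int = 7
) -> dict[str, BitFingerprint]:
    """Hashed topological path fingerprints (RDKit default chemistry)."""
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=min_path, maxPath=max_path, fpSize=n_bits
    )
    out: dict[str, BitFingerprint] = {}
    for rec in records:
        mol = _standardize(rec.smiles) if rec.smiles else None
        if mol is None:
            continue
        bv = gen.GetFingerprint(mol)
        out[rec.drug_id] = BitFingerprint(
            rec.drug_id, frozenset(bv.GetOnBits()), n_bits
        )
    return out


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different bit lengths")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0.0", stacklevel=2)
        return 0.0
    return len(a.bits & b.bits) / union


def nearest_similarity(
    query: BitFingerprint, library: list[BitFingerprint]
) -> tuple[float, str, float]:
    """(max Tanimoto, argmax drug_id, 1 - max Tanimoto) over a library.

    The query itself is excluded by id; ties broken by lexicographic id.
    """
    candidates = [fp for fp in library if fp.drug_id != query.drug_id]
    if not candidates:
        raise ValueError("library holds no fingerprint other than the query")
    best_tc, best_id = -1.0, ""
    for fp in sorted(candidates, key=lambda f: f.drug_id):
        tc = tanimoto(query, fp)
        if tc > best_tc:
            best_tc, best_id = tc, fp.drug_id
    return best_tc, best_id, 1.0 - best_tc


def pairwise_tanimoto(fps: dict[str, BitFingerprint]) -> pd.DataFrame:
    ids = sorted(fps)
    mat = np.eye(len(ids))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mat[i, j] = mat[j, i] = tanimoto(fps[a], fps[ids[j]])
    return pd.DataFrame(mat, index=ids, columns=ids)
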