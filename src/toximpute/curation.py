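"""Raw table -> clean LabelMatrix + FeatureMatrix.

The curation stages, in order: map raw label vocabulary to {0, 1,
equivocal, missing}; blank equivocal calls; standardise structures through
a pluggable chemistry backend (parse, disconnect metals, neutralise,
strip inorganic fragments/solvents, normalise chemotypes and tautomers,
canonical key via an InChI round-trip, discard multi-organic mixtures);
aggregate duplicate structures by per-assay majority vote (exact tie ->
data gap); drop assays below a minimum per-class label count; and compute
2048-bit Morgan radius-2 (ECFP4-like) fingerprints.

The chemistry backend is an interface so that unit tests can inject a mock
canonicaliser; the default backend wraps RDKit's MolStandardize.  Records
a backend rejects are discarded with a logged reason, never a crash.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Protocol

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EQUIVOCAL = "equivocal"

#: default raw-vocabulary mapping; the three public sources use different encodings
DEFAULT_LABEL_MAP = {
    "active": 1.0, "inactive": 0.0, "equivocal": EQUIVOCAL,
    "toxic": 1.0, "non-toxic": 0.0, "nontoxic": 0.0,
    "1": 1.0, "0": 0.0, 1: 1.0, 0: 0.0, 1.0: 1.0, 0.0: 0.0,
}


class ChemistryBackend(Protocol):
    """What curation needs from a chemistry toolkit."""

    def canonical_key(self, smiles: str) -> str | None:
        """Standardised canonical key, or None if the record must be discarded."""

    def fingerprint(self, smiles: str, n_bits: int = 2048) -> np.ndarray:
        """Binary Morgan radius-2 fingerprint of a standardised structure."""


class RDKitBackend:
    """RDKit/MolStandardize implementation of the chemistry backend.

    Standardisation order: parse; cleanup (metal disconnection, normalisation
    of chemotypes, reionisation); uncharge; keep the organic parent fragment
    (strips inorganic fragments and solvents); canonical tautomer; reject
    mixtures that still contain several organic components; canonical key by
    InChI -> molecule -> SMILES so that InChI-identical structures share one
    SMILES.
    """

    def __init__(self, radius: int = 2):
        from rdkit import Chem, RDLogger
        from rdkit.Chem import inchi, rdFingerprintGenerator
        from rdkit.Chem.MolStandardize import rdMolStandardize

        RDLogger.DisableLog("rdApp.*")
        self._chem = Chem
        self._inchi = inchi
        self._std = rdMolStandardize
        self._uncharger = rdMolStandardize.Uncharger()
        self._tautomers = rdMolStandardize.TautomerEnumerator()
        self._fpgen = rdFingerprintGenerator
        self.radius = radius

    def _organic_fragments(self, mol) -> list:
        frags = self._chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        return [f for f in frags
                if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]

    def canonical_key(self, smiles: str) -> str | None:
        Chem = self._chem
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        try:
            mol = self._std.Cleanup(mol)  # metal disconnect + normalize + reionize
            organics = self._organic_fragments(mol)
            if len(organics) > 1:
                # distinct organic components -> mixture -> discard
                if len({Chem.MolToSmiles(f) for f in organics}) > 1:
                    return None
                mol = organics[0]
            elif len(organics) == 1:
                mol = organics[0]
            else:
                mol = self._std.FragmentParent(mol)
            # uncharge after counterions are gone, so salts collapse onto
            # their neutral parent
            mol = self._uncharger.uncharge(mol)
            mol = self._tautomers.Canonicalize(mol)
            key = self._inchi.MolToInchi(mol)
            if not key:
                return None
            back = self._inchi.MolFromInchi(key)
            if back is None:
                return None
            return Chem.MolToSmiles(back)
        except Exception:  # a single bad record must never abort curation
            return None

    def fingerprint(self, smiles: str, n_bits: int = 2048) -> np.ndarray:
        mol = self._chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"cannot fingerprint structure: {smiles}")
        gen = self._fpgen.GetMorganGenerator(radius=self.radius, fpSize=n_bits)
        return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def map_raw_labels(raw: pd.DataFrame, label_map: dict | None = None,
                   smiles_col: str = "smiles") -> pd.DataFrame:
    """Translate raw vocabulary to {0.0, 1.0, 'equivocal', NaN} in place of values."""
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    out = raw.copy()
    assay_cols = [c for c in out.columns if c != smiles_col]

    def translate(v):
        if pd.isna(v):
            return np.nan
        if v in label_map:
            return label_map[v]
        if isinstance(v, str) and v.strip().lower() in label_map:
            return label_map[v.strip().lower()]
        raise ValueError(f"unknown raw label value: {v!r}")

    out[assay_cols] = out[assay_cols].map(translate)
    return out


def drop_equivocal(records: pd.DataFrame, smiles_col: str = "smiles") -> pd.DataFrame:
    """Equivocal calls become data gaps; every other cell is untouched."""
    out = records.copy()
    assay_cols = [c for c in out.columns if c != smiles_col]
    out[assay_cols] = out[assay_cols].map(
        lambda v: np.nan if isinstance(v, str) and v == EQUIVOCAL else v)
    return out


def standardize_structures(records: pd.DataFrame, backend: ChemistryBackend,
                           smiles_col: str = "smiles"
                           ) -> tuple[pd.DataFrame, dict]:
    """Attach a canonical structure key to each surviving record.

    Returns (records with a ``canonical_key`` column, discard-count dict).
    Records the backend rejects (unparseable, mixtures, failures) are
    dropped and counted; a stream with zero survivors yields an empty
    frame plus a warning.
    """
    counts = Counter(total=len(records))
    keys, keep = [], []
    for i, smi in enumerate(records[smiles_col]):
        key = backend.canonical_key(smi) if isinstance(smi, str) else None
        if key is None:
            counts["discarded"] += 1
            log.info("discarded record %d (%r): not standardisable", i, smi)
            continue
        keys.append(key)
        keep.append(i)
    out = records.iloc[keep].copy()
    out.insert(0, "canonical_key", keys)
    counts["kept"] = len(out)
    if len(out) == 0:
        log.warning("standardisation left zero surviving records")
    return out, dict(counts)


def aggregate_duplicates(keyed: pd.DataFrame, key_col: str = "canonical_key",
                         smiles_col: str = "smiles") -> pd.DataFrame:
    """One row per canonical structure; per assay, the majority label.

    An exact toxic/non-toxic tie leaves a data gap.  Idempotent: applied to
    its own output it changes nothing.
    """
    assay_cols = [c for c in keyed.columns if c not in (key_col, smiles_col)]
    vals = keyed[assay_cols].apply(pd.to_numeric, errors="coerce")
    grouped = vals.groupby(keyed[key_col].to_numpy())
    n_toxic = grouped.sum()
    n_obs = grouped.count()
    with np.errstate(invalid="ignore"):
        majority = np.where(n_obs == 0, np.nan,
                            np.where(n_toxic * 2 > n_obs, 1.0,
                                     np.where(n_toxic * 2 < n_obs, 0.0, np.nan)))
    out = pd.DataFrame(majority, index=n_obs.index, columns=assay_cols)
    out.index.name = "compound_id"
    return out.sort_index()


def filter_assays(matrix: pd.DataFrame, min_toxic: int = 50,
                  min_nontoxic: int = 50) -> pd.DataFrame:
    """Keep assays with at least ``min_toxic`` toxic and ``min_nontoxic``
    non-toxic labels; drop compounds left with no observed label."""
    if min_toxic < 0 or min_nontoxic < 0:
        raise ValueError("minimum counts must be non-negative")
    n_toxic = (matrix == 1.0).sum(axis=0)
    n_nontoxic = (matrix == 0.0).sum(axis=0)
    keep = matrix.columns[(n_toxic >= min_toxic) & (n_nontoxic >= min_nontoxic)]
    out = matrix[keep]
    return out[out.notna().any(axis=1)]


def compute_fingerprints(structures, backend: ChemistryBackend,
                         n_bits: int = 2048) -> pd.DataFrame:
    """Morgan fingerprints for an iterable/Series of standardised SMILES.

    Pass-through contract: an already-computed feature DataFrame is
    returned unchanged (synthetic mode).
    """
    if isinstance(structures, pd.DataFrame):
        return structures
    if isinstance(structures, pd.Series):
        index, smiles = structures.index, structures.to_list()
    else:
        smiles = list(structures)
        index = pd.Index(smiles, name="compound_id")
    rows = []
    for ident, smi in zip(index, smiles):
        try:
            rows.append(backend.fingerprint(smi, n_bits=n_bits))
        except Exception as err:
            raise ValueError(f"fingerprint failed for compound {ident}") from err
    return pd.DataFrame(np.vstack(rows), index=index,
                        columns=[f"bit_{b}" for b in range(n_bits)])


def matrix_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-assay and pooled completeness and prevalence.

    Completeness = observed cells / compounds; prevalence = toxic /
    observed.  The ``overall`` row pools all cells.
    """
    if matrix.size == 0:
        raise ValueError("empty label matrix")
    observed = matrix.notna()
    toxic = matrix == 1.0
    per_assay = pd.DataFrame({
        "n_labels": observed.sum(axis=0),
        "completeness": observed.mean(axis=0),
        "prevalence": toxic.sum(axis=0) / observed.sum(axis=0),
    })
    pooled = pd.DataFrame({
        "n_labels": [int(observed.to_numpy().sum())],
        "completeness": [observed.to_numpy().mean()],
        "prevalence": [toxic.to_numpy().sum() / observed.to_numpy().sum()],
    }, index=["overall"])
    return pd.concat([per_assay, pooled])


def curate(raw: pd.DataFrame, backend: ChemistryBackend | None = None,
           label_map: dict | None = None, min_toxic: int = 50,
           min_nontoxic: int = 50, n_bits: int = 2048,
           smiles_col: str = "smiles"
           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full curation pipeline: raw table -> (labels, features, report)."""
    backend = backend or RDKitBackend()
    mapped = map_raw_labels(raw, label_map, smiles_col)
    blanked = drop_equivocal(mapped, smiles_col)
    keyed, report = standardize_structures(blanked, backend, smiles_col)
    labels = aggregate_duplicates(keyed, smiles_col=smiles_col)
    before = labels.shape
    labels = filter_assays(labels, min_toxic, min_nontoxic)
    report["assays_dropped"] = before[1] - labels.shape[1]
    report["compounds_dropped_after_filter"] = before[0] - labels.shape[0]
    features = compute_fingerprints(pd.Series(labels.index, index=labels.index),
                                    backend, n_bits=n_bits)
    return labels, features, report
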