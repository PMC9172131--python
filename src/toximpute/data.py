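"""In-memory containers and CSV I/O conventions.

The package passes data around as plain pandas objects with fixed conventions:

* **label matrix** -- ``DataFrame`` of shape (n_compounds, n_assays), index =
  compound ids, columns = assay ids, values ``0.0`` (non-toxic), ``1.0``
  (toxic) or ``NaN`` (missing / untested).
* **feature matrix** -- ``DataFrame`` of binary fingerprint bits (uint8),
  row-aligned with the label matrix (identical index, identical order).
* **split mask** -- ``DataFrame`` with the label matrix's shape holding
  ``"train"``, ``"test"`` or ``NaN`` (unlabelled); a cell is ``NaN`` exactly
  where the label matrix is missing.

On disk everything is CSV: one row per compound with an optional ``smiles``
column and one column per assay (empty cell = missing); fingerprints as 0/1
columns ``bit_0 .. bit_{n-1}``; split masks as long-form
``(compound_id, assay_id, role)`` triples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAIN = "train"
TEST = "test"


class ValidationError(ValueError):
    """A container violated one of the package's data conventions."""


def validate_label_matrix(labels: pd.DataFrame, require_observed: bool = True) -> None:
    if labels.index.has_duplicates:
        raise ValidationError("duplicate compound ids in label matrix")
    if labels.columns.has_duplicates:
        raise ValidationError("duplicate assay ids in label matrix")
    values = labels.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    bad = observed & ~np.isin(values, (0.0, 1.0))
    if bad.any():
        raise ValidationError("label matrix cells must be 0, 1 or missing")
    if require_observed and observed.sum(axis=0).min(initial=1) == 0:
        empty = [a for a, n in zip(labels.columns, observed.sum(axis=0)) if n == 0]
        raise ValidationError(f"assays with zero observed labels: {empty}")


def validate_alignment(features: pd.DataFrame, labels: pd.DataFrame) -> None:
    if not features.index.equals(labels.index):
        raise ValidationError("feature matrix rows are not aligned with label matrix")


def validate_split_mask(mask: pd.DataFrame, labels: pd.DataFrame) -> None:
    if mask.shape != labels.shape:
        raise ValidationError("split mask shape differs from label matrix")
    observed = labels.notna().to_numpy()
    assigned = mask.notna().to_numpy()
    if (assigned & ~observed).any():
        raise ValidationError("split mask assigns a role to a missing cell")
    vals = mask.to_numpy(dtype=object)
    roles = set(vals[assigned].tolist())
    if not roles <= {TRAIN, TEST}:
        raise ValidationError(f"unknown split roles: {roles - {TRAIN, TEST}}")


def train_mask(mask: pd.DataFrame) -> pd.DataFrame:
    """Boolean frame of train cells."""
    return mask == TRAIN


def test_mask(mask: pd.DataFrame) -> pd.DataFrame:
    """Boolean frame of test cells."""
    return mask == TEST


def observed_mask(labels: pd.DataFrame) -> pd.DataFrame:
    return labels.notna()


def write_label_csv(labels: pd.DataFrame, path, smiles: pd.Series | None = None) -> None:
    out = labels.copy()
    if smiles is not None:
        out.insert(0, "smiles", smiles.reindex(labels.index))
    out.to_csv(path, index=True, index_label="compound_id")


def read_label_csv(path) -> tuple[pd.DataFrame, pd.Series | None]:
    raw = pd.read_csv(path, index_col="compound_id")
    smiles = None
    if "smiles" in raw.columns:
        smiles = raw.pop("smiles")
    labels = raw.astype(float)
    validate_label_matrix(labels, require_observed=False)
    return labels, smiles


def write_feature_csv(features: pd.DataFrame, path) -> None:
    features.astype(np.uint8).to_csv(path, index=True, index_label="compound_id")


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="compound_id").astype(np.uint8)


def write_split_csv(mask: pd.DataFrame, path) -> None:
    long = mask.stack().rename("role").rename_axis(["compound_id", "assay_id"]).reset_index()
    long.to_csv(path, index=False)


def read_split_csv(path, labels: pd.DataFrame) -> pd.DataFrame:
    long = pd.read_csv(path)
    mask = long.pivot(index="compound_id", columns="assay_id", values="role")
    mask = mask.reindex(index=labels.index, columns=labels.columns)
    validate_split_mask(mask, labels)
    return mask
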