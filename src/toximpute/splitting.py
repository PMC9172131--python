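"""Train/test assignment for sparse label matrices.

Two split geometries: *compound-based* (all of a compound's observed cells
fall on one side -- the conventional QSAR evaluation) and *assay-based*
(each assay's observed cells are split independently, so a compound can be
a training example for assay A and a test case for assay B -- the
imputation / repurposing scenario).  ``sparsify_training`` additionally
caps each assay's training cells to study the effect of sparsity.

Fractional test counts are rounded half-to-even with a minimum of one test
cell; all draws use ``numpy.random.default_rng`` (PCG64) seeded explicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import data as _data
from .data import TRAIN, TEST


def _round_count(fraction: float, n: int) -> int:
    return max(1, int(round(fraction * n)))


def compound_split(labels: pd.DataFrame, test_fraction: float = 0.2,
                   seed: int = 0) -> pd.DataFrame:
    """Assign whole compounds to train or test.

    ``round(test_fraction * n_compounds)`` compounds (at least one) are
    drawn uniformly for the test side; every observed cell of a compound
    gets that compound's role.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(labels.index)
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    rng = np.random.default_rng(seed)
    n_test = _round_count(test_fraction, n)
    test_rows = rng.choice(n, size=n_test, replace=False)
    is_test = np.zeros(n, dtype=bool)
    is_test[test_rows] = True
    roles = np.where(np.broadcast_to(is_test[:, None], labels.shape),
                     TEST, TRAIN).astype(object)
    mask = pd.DataFrame(roles, index=labels.index, columns=labels.columns)
    return mask.where(labels.notna())


def assay_split(labels: pd.DataFrame, test_fraction: float = 0.2,
                seed: int = 0, stratified: bool = False) -> pd.DataFrame:
    """Split each assay's observed cells independently.

    Per assay, ``round(test_fraction * n_observed)`` cells (minimum one) go
    to the test side.  In stratified mode the draw preserves the assay's
    class proportions: ``round(test_fraction * n_class)`` per class, at
    least one of each; a single-class assay is an error there.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    mask = pd.DataFrame(np.full(labels.shape, np.nan, dtype=object),
                        index=labels.index, columns=labels.columns)
    values = labels.to_numpy(dtype=float)
    for j, assay in enumerate(labels.columns):
        col = values[:, j]
        observed = np.flatnonzero(~np.isnan(col))
        if observed.size < 2:
            raise ValueError(f"assay {assay} has fewer than 2 observed labels")
        if stratified:
            test_idx = []
            classes = [observed[col[observed] == v] for v in (1.0, 0.0)]
            if any(c.size == 0 for c in classes):
                raise ValueError(f"assay {assay} is single-class; cannot stratify")
            for members in classes:
                n_test = _round_count(test_fraction, members.size)
                test_idx.append(rng.choice(members, size=n_test, replace=False))
            test_idx = np.concatenate(test_idx)
        else:
            n_test = _round_count(test_fraction, observed.size)
            test_idx = rng.choice(observed, size=n_test, replace=False)
        colmask = np.full(len(col), np.nan, dtype=object)
        colmask[observed] = TRAIN
        colmask[test_idx] = TEST
        mask.iloc[:, j] = colmask
    return mask


def sparsify_training(mask: pd.DataFrame, cap: int | None = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Cap each assay's train cells at ``cap`` by uniform subsampling.

    Assays at or below the cap keep all their training labels; dropped
    cells become unlabelled for training purposes; test cells are never
    touched.  ``cap=None`` is the identity.
    """
    if cap is None:
        return mask.copy()
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    out = mask.copy()
    arr = out.to_numpy(dtype=object)
    for j in range(arr.shape[1]):
        train_idx = np.flatnonzero(arr[:, j] == TRAIN)
        if train_idx.size > cap:
            keep = rng.choice(train_idx, size=cap, replace=False)
            drop = np.setdiff1d(train_idx, keep)
            arr[drop, j] = np.nan
    return pd.DataFrame(arr, index=mask.index, columns=mask.columns)


def split(labels: pd.DataFrame, kind: str, test_fraction: float = 0.2,
          seed: int = 0, stratified: bool = False,
          cap: int | None = None) -> pd.DataFrame:
    """Config-level entry point: kind in {'compound', 'assay'} plus optional cap."""
    if kind == "compound":
        mask = compound_split(labels, test_fraction, seed)
    elif kind == "assay":
        mask = assay_split(labels, test_fraction, seed, stratified)
    else:
        raise ValueError(f"unknown split kind: {kind}")
    if cap is not None:
        mask = sparsify_training(mask, cap=cap, seed=seed)
    _data.validate_split_mask(mask, labels)
    return mask
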