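"""Metrics, GHOST threshold optimisation, and binned / multi-seed analyses.

MCC is the primary metric (robust on imbalanced assays); F1 and ROC-AUC are
reported alongside.  GHOST picks a decision threshold from a candidate grid
using bootstrap resamples of the *training* scores only.  Binned analyses
slice test cells by chemical similarity to the training set (mean Tanimoto
to the 5 nearest neighbours) or by how many auxiliary training labels the
compound has.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from . import data as _data

GHOST_CANDIDATES = tuple(np.round(np.arange(0.05, 0.551, 0.05), 2))
SIMILARITY_EDGES = (0.4, 0.6)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        return cls(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                   tn=int((~t & ~p).sum()), fn=int((t & ~p).sum()))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when a denominator factor is zero.

    The zero-denominator case (a degenerate predictor or single-class truth)
    is conventionally scored 0; an empty count table is undefined (NaN).
    """
    if c.total == 0:
        return float("nan")
    tp, fp, tn, fn = (float(x) for x in (c.tp, c.fp, c.tn, c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def mcc_from_predictions(y_true, y_pred) -> float:
    return mcc(ConfusionCounts.from_predictions(y_true, y_pred))


def f1_and_auc(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """(F1, ROC-AUC); AUC is NaN when only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    preds = (scores >= threshold).astype(int)
    f1 = f1_score(labels, preds, zero_division=0)
    if len(np.unique(labels)) < 2:
        return float(f1), float("nan")
    return float(f1), float(roc_auc_score(labels, scores))


def _roc_point(scores, labels, threshold):
    preds = scores >= threshold
    pos = labels == 1
    tpr = preds[pos].mean() if pos.any() else 0.0
    fpr = preds[~pos].mean() if (~pos).any() else 0.0
    return fpr, tpr


def ghost_threshold(train_scores, train_labels,
                    candidates=GHOST_CANDIDATES, n_bootstrap: int = 100,
                    seed: int = 0, fallback: float = 0.5,
                    max_retries: int = 50) -> float:
    """GHOST decision threshold from training scores.

    For each bootstrap resample, every candidate's ROC point (FPR, TPR) is
    computed and the candidate closest (Euclidean) to the ideal corner
    (0, 1) wins, ties going to the lowest candidate; a resample where all
    candidates are equidistant (e.g. constant scores) contributes the
    fallback.  The returned threshold is the median of the per-resample
    optima.  Single-class resamples are redrawn.
    """
    scores = np.asarray(train_scores, dtype=float)
    labels = np.asarray(train_labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("GHOST needs both classes in the training labels")
    candidates = np.asarray(sorted(candidates), dtype=float)
    rng = np.random.default_rng(seed)
    n = scores.size
    optima = []
    for _ in range(n_bootstrap):
        for _retry in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        s, y = scores[idx], labels[idx]
        dists = np.array([np.hypot(fpr, 1.0 - tpr)
                          for fpr, tpr in (_roc_point(s, y, t) for t in candidates)])
        if dists.max() - dists.min() < 1e-12:
            optima.append(fallback)
        else:
            optima.append(float(candidates[int(np.argmin(dists))]))
    return float(np.median(optima))


def tanimoto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between two binary bit matrices."""
    a = np.asarray(a, dtype=np.int32)
    b = np.asarray(b, dtype=np.int32)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def nearest_neighbor_similarity(test_features, train_features,
                                n_neighbors: int = 5) -> np.ndarray:
    """Mean Tanimoto similarity of each test row to its n nearest training rows.

    With fewer than ``n_neighbors`` training compounds all of them are used.
    """
    train = np.asarray(train_features)
    if train.shape[0] == 0:
        raise ValueError("empty training set")
    k = min(n_neighbors, train.shape[0])
    sim = tanimoto(np.asarray(test_features), train)
    top = np.sort(sim, axis=1)[:, -k:]
    return top.mean(axis=1)


def bin_by_similarity(test_features, train_features,
                      edges: tuple[float, float] = SIMILARITY_EDGES,
                      n_neighbors: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Applicability-domain bins 1/2/3 from 5-NN Tanimoto similarity.

    Bins are [0, e1), [e1, e2), [e2, 1] (left-closed; the top bin closed on
    both sides).  Returns (bin indices, similarities).
    """
    sims = nearest_neighbor_similarity(test_features, train_features, n_neighbors)
    bins = np.digitize(sims, bins=list(edges), right=False) + 1
    return bins, sims


def bin_by_availability(split, target: str, compounds=None) -> pd.Series:
    """Bins by the number of *other-assay* train labels per compound.

    0-1 labels -> bin 1, 2-3 -> bin 2, >3 -> bin 3; counted over train cells
    of every assay except ``target``.
    """
    train = _data.train_mask(split)
    counts = train.drop(columns=[target]).sum(axis=1)
    if compounds is not None:
        counts = counts.loc[compounds]
    return pd.Series(np.digitize(counts, bins=[2, 4]) + 1, index=counts.index,
                     name="bin")


def binned_evaluation(scores: pd.Series, labels: pd.Series, bins: pd.Series,
                      threshold: float = 0.5, min_per_bin: int = 100,
                      n_bins: int = 3) -> tuple[pd.DataFrame, bool]:
    """Per-bin MCC/F1/AUC for one assay.

    Returns (table, included); ``included`` is False when any bin holds fewer
    than ``min_per_bin`` test cells, mirroring the reporting rule that every
    bin must be populated well enough for stable metrics.
    """
    rows = []
    sizes = [(bins == b).sum() for b in range(1, n_bins + 1)]
    included = all(s >= min_per_bin for s in sizes)
    for b in range(1, n_bins + 1):
        sel = bins == b
        if sel.sum() == 0:
            rows.append({"bin": b, "n": 0, "mcc": float("nan"),
                         "f1": float("nan"), "auc": float("nan")})
            continue
        s, y = scores[sel].to_numpy(), labels[sel].to_numpy().astype(int)
        preds = (s >= threshold).astype(int)
        f1, auc = f1_and_auc(s, y, threshold)
        rows.append({"bin": b, "n": int(sel.sum()),
                     "mcc": mcc_from_predictions(y, preds), "f1": f1, "auc": auc})
    return pd.DataFrame(rows), included


def multi_seed_summary(results: pd.DataFrame, metric: str = "mcc") -> pd.DataFrame:
    """Median and IQR across seeds of per-seed assay means, per method.

    ``results`` is tidy with columns (method, assay, seed, <metric>).  The
    mean over assays is taken within each seed first, then the median and
    the interquartile range (linear-interpolation quartiles) across seeds.
    """
    per_seed = (results.groupby(["method", "seed"])[metric]
                .mean().rename("seed_mean").reset_index())
    out = per_seed.groupby("method")["seed_mean"].agg(
        median="median",
        q1=lambda s: float(np.percentile(s, 25)),
        q3=lambda s: float(np.percentile(s, 75)),
        n_seeds="count",
    ).reset_index()
    out["iqr"] = out["q3"] - out["q1"]
    return out
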