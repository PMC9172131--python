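"""Information-theoretic relatedness between binary assays.

Relatedness between a target assay A and an auxiliary assay B is measured
on the compounds labelled in *both* assays: Shannon entropy of each margin,
mutual information MI(A,B) = H(A) + H(B) - H(A,B) from the four-cell joint,
and the MI-entropy ratio MI(A,B)/H(A) -- the fraction of the target's
information already contained in the auxiliary.  The ratio lies in [0, 1],
is asymmetric (the denominator is the target's entropy) and is the score
used to rank candidate auxiliary assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import data as _data

DEFAULT_MIN_OVERLAP = 20


def entropy(p_active: float) -> float:
    """Binary Shannon entropy in bits, with the 0*log2(0) := 0 convention."""
    p = float(p_active)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p}")
    out = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            out -= q * np.log2(q)
    return out


@dataclass
class AssayDistribution:
    """Joint label distribution of two assays over their co-labelled compounds.

    ``joint`` is the 2x2 proportion table with rows indexed by the first
    assay (row 0 = non-toxic, row 1 = toxic) and columns by the second.
    """

    joint: np.ndarray
    n_overlap: int

    @classmethod
    def from_counts(cls, counts) -> "AssayDistribution":
        c = np.asarray(counts, dtype=float)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("counts must be a non-negative 2x2 table")
        n = c.sum()
        joint = c / n if n > 0 else np.zeros((2, 2))
        return cls(joint=joint, n_overlap=int(round(n)))

    @classmethod
    def from_labels(cls, a: np.ndarray, b: np.ndarray) -> "AssayDistribution":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        both = ~np.isnan(a) & ~np.isnan(b)
        a, b = a[both].astype(int), b[both].astype(int)
        counts = np.zeros((2, 2))
        for i, j in zip(a, b):
            counts[i, j] += 1
        return cls.from_counts(counts)

    @property
    def p_a(self) -> float:
        return float(self.joint[1, :].sum())

    @property
    def p_b(self) -> float:
        return float(self.joint[:, 1].sum())

    def marginal_entropies(self) -> tuple[float, float]:
        return entropy(self.p_a), entropy(self.p_b)

    def joint_entropy(self) -> float:
        p = self.joint.ravel()
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())


def mutual_information(dist: AssayDistribution,
                       min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """MI(A,B) in bits; ``NaN`` when the overlap is below ``min_overlap``.

    Computed as H(A) + H(B) - H(A,B); tiny negative values from floating
    point are clamped to 0.
    """
    if dist.n_overlap < min_overlap:
        return float("nan")
    h_a, h_b = dist.marginal_entropies()
    mi = h_a + h_b - dist.joint_entropy()
    return max(mi, 0.0)


def mi_entropy_ratio(labels: pd.DataFrame, target: str, auxiliary: str,
                     split=None, label_scope: str = "train",
                     min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """MI(target, auxiliary) / H(target) on their co-labelled compounds.

    ``label_scope`` selects which labels enter: ``"train"`` (default;
    requires ``split``, avoids looking at held-out labels) or ``"all"``.
    ``NaN`` when the target has zero entropy on the overlap or the overlap
    is too small.
    """
    scoped = _scoped_labels(labels, split, label_scope)
    dist = AssayDistribution.from_labels(scoped[target].to_numpy(),
                                         scoped[auxiliary].to_numpy())
    mi = mutual_information(dist, min_overlap=min_overlap)
    if np.isnan(mi):
        return float("nan")
    h_target = entropy(dist.p_a)
    if h_target == 0.0:
        return float("nan")
    return mi / h_target


def relatedness_table(labels: pd.DataFrame, split=None, label_scope: str = "train",
                      min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Full ordered-pair table: H(target), MI, MI-entropy ratio, n_overlap."""
    scoped = _scoped_labels(labels, split, label_scope)
    assays = list(scoped.columns)
    rows = []
    for t in assays:
        for a in assays:
            if a == t:
                continue
            dist = AssayDistribution.from_labels(scoped[t].to_numpy(),
                                                 scoped[a].to_numpy())
            mi = mutual_information(dist, min_overlap=min_overlap)
            h_t = entropy(dist.p_a)
            ratio = mi / h_t if (not np.isnan(mi) and h_t > 0) else float("nan")
            rows.append({"target": t, "auxiliary": a, "h_target": h_t,
                         "mi": mi, "mi_entropy_ratio": ratio,
                         "n_overlap": dist.n_overlap})
    return pd.DataFrame(rows)


def rank_auxiliaries(labels: pd.DataFrame, target: str, k: int,
                     strategy: str = "mi_ratio", seed: int | None = None,
                     split=None, label_scope: str = "train",
                     min_overlap: int = DEFAULT_MIN_OVERLAP) -> list[str]:
    """Top-k auxiliary assays for ``target``.

    ``mi_ratio`` sorts descending by MI-entropy ratio (NaN last), ties broken
    by assay-id lexical order; ``random_additive`` draws a seeded permutation
    of the other assays and returns its prefix, so the set at k=3 contains
    the set at k=1.
    """
    others = [a for a in labels.columns if a != target]
    if k >= len(labels.columns):
        raise ValueError(f"k={k} must be below the number of assays")
    if strategy == "mi_ratio":
        ratios = {a: mi_entropy_ratio(labels, target, a, split=split,
                                      label_scope=label_scope,
                                      min_overlap=min_overlap)
                  for a in others}
        ordered = sorted(others, key=lambda a: (np.isnan(ratios[a]),
                                                -(ratios[a] if not np.isnan(ratios[a]) else 0.0),
                                                a))
        return ordered[:k]
    if strategy == "random_additive":
        rng = np.random.default_rng(seed)
        return list(rng.permutation(others))[:k]
    raise ValueError(f"unknown strategy: {strategy}")


def improvement_vs_relatedness(pairwise_results: pd.DataFrame,
                               relatedness: pd.DataFrame
                               ) -> tuple[float, pd.DataFrame]:
    """Pearson r between pairwise-model improvement and MI-entropy ratio.

    ``pairwise_results`` needs columns (target, auxiliary, delta_mcc) --
    pairwise Feature-Net MCC minus single-task MCC per ordered pair.
    Returns the correlation (NaN if fewer than 3 pairs or zero variance) and
    the merged scatter table.
    """
    merged = pairwise_results.merge(
        relatedness[["target", "auxiliary", "mi_entropy_ratio"]],
        on=["target", "auxiliary"], how="inner").dropna(
        subset=["delta_mcc", "mi_entropy_ratio"])
    if len(merged) < 3:
        return float("nan"), merged
    x = merged["mi_entropy_ratio"].to_numpy()
    y = merged["delta_mcc"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), merged
    r, _ = stats.pearsonr(x, y)
    return float(r), merged


def _scoped_labels(labels: pd.DataFrame, split, label_scope: str) -> pd.DataFrame:
    if label_scope == "all":
        return labels
    if label_scope == "train":
        if split is None:
            raise ValueError("label_scope='train' requires a split mask")
        return labels.where(_data.train_mask(split))
    raise ValueError(f"unknown label_scope: {label_scope}")
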