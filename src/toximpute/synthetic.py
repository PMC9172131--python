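"""Synthetic sparse toxicity panels with known ground truth.

The generator emulates the structure of public in-vitro toxicity panels
(Ames-strain batteries, Tox21-style receptor/stress panels, large
ToxCast-like screens): a sparse binary compound x assay matrix with
tunable per-assay completeness, prevalence and pairwise relatedness, plus
binary fingerprint-like feature vectors with scaffold-cluster structure.

Generative model
----------------
``n_mechanisms`` latent toxicity mechanisms drive everything.  Each assay
reports a subset of mechanisms (its *loading*); a compound is toxic in an
assay, pre-noise, iff it activates at least one mechanism the assay loads.
Two assays are related exactly to the extent that their loadings overlap,
which gives direct control over the mutual-information structure.

Compound fingerprints carry structural-alert bits for the mechanisms a
compound activates, cluster-specific scaffold bits, and sparse random
background bits.  The alert signal is deliberately imperfect (per-bit
dropout, occasional silent activations that leave no trace, and spurious
alerts without activation): chemistry alone under-determines the label,
which is the regime in which auxiliary assay labels carry information a
QSAR model cannot get from the fingerprint.

Observed labels are a masked (missing-completely-at-random per cell) and
bit-flipped view of the noise-free matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special


class ConfigurationError(ValueError):
    """Invalid synthetic panel configuration."""


def default_loadings(n_assays: int, n_mechanisms: int, per_assay: int = 2) -> np.ndarray:
    """Cyclic overlapping loadings: assay j loads mechanisms {j, .., j+per_assay-1} mod M.

    Neighbouring assays share mechanisms; assays a multiple of ``n_mechanisms``
    apart are exact duplicates, giving a spread of relatedness values.
    """
    per_assay = min(per_assay, n_mechanisms)
    out = np.zeros((n_assays, n_mechanisms), dtype=bool)
    for j in range(n_assays):
        for d in range(per_assay):
            out[j, (j + d) % n_mechanisms] = True
    return out


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic panel.

    Defaults emulate the published panels' ranges: completeness 0.5 (the
    real panels span roughly 1.4--92% filled), per-assay prevalence 0.2
    (real assays span roughly 3--32% toxic) and a 5% label-flip rate for
    experimental noise.
    """

    n_compounds: int = 2000
    n_assays: int = 6
    n_mechanisms: int = 4
    mechanism_loadings: np.ndarray | None = None
    bits_per_mechanism: int = 8
    n_clusters: int = 10
    label_flip_rate: float = 0.05
    completeness: float | Sequence[float] = 0.5
    target_prevalence: float | Sequence[float] = 0.2
    n_bits: int = 2048
    seed: int = 0
    # fingerprint imperfection
    bit_dropout: float = 0.25
    mech_silent_rate: float = 0.3
    spurious_alert_rate: float = 0.1
    cluster_bits: int = 20
    cluster_bit_rate: float = 0.8
    background_rate: float = 0.01
    # 0 = homogeneous MCAR; s>0 draws a per-compound tested-fraction weight
    # from U(max(0,1-s), 1+s), emulating panels where some compounds were
    # tested in most assays and others in few
    compound_completeness_spread: float = 0.0
    # give each (mechanism, cluster) pair its own alert-bit set: different
    # scaffolds ("chemotypes") express the same mechanism through different
    # substructures, so models cannot extrapolate to unseen clusters
    per_cluster_mechanism_bits: bool = False
    # fraction of compounds that are scaffold singletons (no cluster bits,
    # their own private chemotype), populating the low-similarity region
    singleton_fraction: float = 0.0

    def loadings(self) -> np.ndarray:
        if self.mechanism_loadings is not None:
            return np.asarray(self.mechanism_loadings, dtype=bool)
        return default_loadings(self.n_assays, self.n_mechanisms)

    def completeness_per_assay(self) -> np.ndarray:
        return _broadcast(self.completeness, self.n_assays, "completeness")

    def prevalence_per_assay(self) -> np.ndarray:
        return _broadcast(self.target_prevalence, self.n_assays, "target_prevalence")

    def validate(self) -> None:
        for name in ("n_compounds", "n_assays", "n_mechanisms", "bits_per_mechanism",
                     "n_clusters", "n_bits"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.label_flip_rate < 0.5:
            raise ConfigurationError("label_flip_rate must lie in [0, 0.5)")
        comp = self.completeness_per_assay()
        if np.any(comp <= 0) or np.any(comp > 1):
            raise ConfigurationError("completeness must lie in (0, 1]")
        prev = self.prevalence_per_assay()
        if np.any(prev <= 0) or np.any(prev >= 1):
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        load = self.loadings()
        if load.shape != (self.n_assays, self.n_mechanisms):
            raise ConfigurationError(
                f"mechanism_loadings must have shape ({self.n_assays}, {self.n_mechanisms})"
            )
        if load.sum(axis=1).min(initial=1) == 0:
            raise ConfigurationError("every assay needs at least one mechanism loading")
        if not 0 <= self.singleton_fraction <= 1:
            raise ConfigurationError("singleton_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated panel."""

    mechanism_bit_map: dict  # mechanism (or (mechanism, cluster)) -> bit indices
    activations: np.ndarray  # (n_compounds, n_mechanisms) bool
    clean_labels: pd.DataFrame  # noise-free labels, fully observed
    clusters: np.ndarray  # per-compound cluster index (-1 = singleton)
    activation_probs: np.ndarray  # calibrated per-mechanism P(activate)


def calibrate_activation_probs(loadings: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-mechanism activation probabilities hitting per-assay prevalence targets.

    Pre-noise prevalence of assay j is ``1 - prod_{m in S_j} (1 - q_m)``.
    Closed-form per-assay solutions (equal split across the assay's
    mechanisms) are averaged per mechanism, then refined by a deterministic
    bounded least-squares pass on logit(q) when loadings overlap.
    """
    load = np.asarray(loadings, dtype=bool)
    targets = np.asarray(targets, dtype=float)
    k = load.sum(axis=1)
    req = 1.0 - (1.0 - targets) ** (1.0 / k)
    q0 = np.array([req[load[:, m]].mean() if load[:, m].any() else 1e-6
                   for m in range(load.shape[1])])
    q0 = np.clip(q0, 1e-6, 1 - 1e-6)

    def residual(z):
        q = special.expit(z)
        prev = 1.0 - np.prod(np.where(load, 1.0 - q[None, :], 1.0), axis=1)
        return prev - targets

    if np.allclose(residual(special.logit(q0)), 0.0, atol=1e-12):
        return q0
    sol = optimize.least_squares(residual, special.logit(q0), method="lm", xtol=1e-12)
    return special.expit(sol.x)


def _broadcast(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ConfigurationError(f"{name} must be scalar or length {n}")
    return arr


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_panel(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (features, labels, truth) for a configured panel.

    Deterministic given ``config.seed``; all stages use independent child
    streams of the master seed.
    """
    config.validate()
    n, k_assays = config.n_compounds, config.n_assays
    load = config.loadings()
    prev = config.prevalence_per_assay()
    comp = config.completeness_per_assay()
    rng_act, rng_bits, rng_mask, rng_flip, rng_clust = _child_rngs(config.seed, 5)

    q = calibrate_activation_probs(load, prev)
    activations = rng_act.random((n, config.n_mechanisms)) < q[None, :]
    clean = (activations @ load.T.astype(int)) > 0  # toxic iff >=1 loaded mechanism active

    compound_ids = [f"C{i:05d}" for i in range(n)]
    assay_ids = [f"A{j}" for j in range(k_assays)]
    clean_df = pd.DataFrame(clean.astype(float), index=compound_ids, columns=assay_ids)

    clusters = rng_clust.integers(0, config.n_clusters, size=n)
    if config.singleton_fraction > 0:
        singles = rng_clust.random(n) < config.singleton_fraction
        clusters[singles] = -1

    features, bit_map = _make_fingerprints(config, activations, clusters,
                                           rng_bits, rng_clust)
    features_df = pd.DataFrame(features, index=compound_ids, columns=[
        f"bit_{b}" for b in range(config.n_bits)])

    observed = _observation_mask(config, comp, n, k_assays, rng_mask)
    flips = rng_flip.random((n, k_assays)) < config.label_flip_rate
    noisy = np.where(flips, 1.0 - clean, clean.astype(float))
    labels = np.where(observed, noisy, np.nan)
    labels_df = pd.DataFrame(labels, index=compound_ids, columns=assay_ids)

    truth = SyntheticTruth(mechanism_bit_map=bit_map, activations=activations,
                           clean_labels=clean_df, clusters=clusters,
                           activation_probs=q)
    return features_df, labels_df, truth


def _observation_mask(config, comp, n, k_assays, rng) -> np.ndarray:
    p = np.broadcast_to(comp[None, :], (n, k_assays)).copy()
    s = config.compound_completeness_spread
    if s > 0:
        w = rng.uniform(max(0.0, 1.0 - s), 1.0 + s, size=n)
        p = np.clip(p * w[:, None], 0.0, 1.0)
    return rng.random((n, k_assays)) < p


def _make_fingerprints(config, activations, clusters, rng_bits, rng_clust):
    n = config.n_compounds
    features = (rng_bits.random((n, config.n_bits)) < config.background_rate)

    # reserve alert bits; chemotype-specific mode keys them by (mechanism, cluster)
    if config.per_cluster_mechanism_bits:
        groups = [(m, c) for m in range(config.n_mechanisms)
                  for c in sorted(set(clusters.tolist())) if c >= 0]
    else:
        groups = list(range(config.n_mechanisms))
    needed = len(groups) * config.bits_per_mechanism + config.n_clusters * config.cluster_bits
    bit_map: dict = {}
    cluster_bits = {}
    if needed <= config.n_bits:
        perm = rng_bits.permutation(config.n_bits)
        pos = 0
        for g in groups:
            bit_map[g] = perm[pos:pos + config.bits_per_mechanism]
            pos += config.bits_per_mechanism
        for c in range(config.n_clusters):
            cluster_bits[c] = perm[pos:pos + config.cluster_bits]
            pos += config.cluster_bits
    else:
        # short fingerprints: draw bit sets independently, allowing the
        # collisions a hashed fingerprint would have anyway
        for g in groups:
            bit_map[g] = rng_bits.choice(config.n_bits,
                                         size=min(config.bits_per_mechanism,
                                                  config.n_bits), replace=False)
        for c in range(config.n_clusters):
            cluster_bits[c] = rng_bits.choice(config.n_bits,
                                              size=min(config.cluster_bits,
                                                       config.n_bits),
                                              replace=False)

    silent = rng_bits.random((n, config.n_mechanisms)) < config.mech_silent_rate
    spurious = rng_bits.random((n, config.n_mechanisms)) < config.spurious_alert_rate
    carries = (activations & ~silent) | (~activations & spurious)
    for m in range(config.n_mechanisms):
        carriers = np.flatnonzero(carries[:, m])
        if carriers.size == 0:
            continue
        for i in carriers:
            if config.per_cluster_mechanism_bits:
                if clusters[i] < 0:
                    # scaffold singleton: a private substructure no model has
                    # seen -- random bits, structurally uninformative
                    bits = rng_bits.choice(config.n_bits,
                                           size=config.bits_per_mechanism,
                                           replace=False)
                else:
                    bits = bit_map[(m, clusters[i])]
            else:
                bits = bit_map[m]
            keep = rng_bits.random(bits.size) >= config.bit_dropout
            features[i, bits[keep]] = True

    for c, bits in cluster_bits.items():
        members = np.flatnonzero(clusters == c)
        if members.size == 0:
            continue
        on = rng_clust.random((members.size, bits.size)) < config.cluster_bit_rate
        features[np.ix_(members, bits)] |= on

    return features.astype(np.uint8), bit_map


def make_related_pair(base_loading: np.ndarray, overlap: float,
                      config: SyntheticConfig, seed: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """A second assay loading sharing a fraction ``overlap`` of the base's mechanisms.

    ``overlap=1`` returns an identical loading, ``overlap=0`` a disjoint one of
    the same size; intermediate values share ``round(overlap * k)`` mechanisms.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ConfigurationError("overlap must lie in [0, 1]")
    base = np.asarray(base_loading, dtype=bool)
    if base.shape != (config.n_mechanisms,):
        raise ConfigurationError("base loading length must equal n_mechanisms")
    members = np.flatnonzero(base)
    k = members.size
    n_shared = int(round(overlap * k))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shared = rng.choice(members, size=n_shared, replace=False)
    outside = np.flatnonzero(~base)
    n_new = k - n_shared
    if n_new > outside.size:
        raise ConfigurationError(
            f"need {n_new} mechanisms outside the base loading, only {outside.size} exist")
    fresh = rng.choice(outside, size=n_new, replace=False)
    other = np.zeros_like(base)
    other[shared] = True
    other[fresh] = True
    return base.copy(), other


def write_panel_csvs(features: pd.DataFrame, labels: pd.DataFrame, prefix) -> None:
    """Write the curation-dialect CSVs (labels + fingerprint bits)."""
    from . import data

    data.write_label_csv(labels, f"{prefix}_labels.csv")
    data.write_feature_csv(features, f"{prefix}_features.csv")


def panel_with_duplicate_assay(config: SyntheticConfig) -> SyntheticConfig:
    """Convenience: append an exact duplicate of assay 0's loading."""
    load = config.loadings()
    new = np.vstack([load, load[:1]])
    return replace(config, n_assays=config.n_assays + 1, mechanism_loadings=new)
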