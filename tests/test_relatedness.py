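"""Entropy / mutual information / MI-entropy ratio and auxiliary ranking."""

import numpy as np
import pandas as pd
import pytest

from toximpute import SyntheticConfig, generate_panel
from toximpute.relatedness import (AssayDistribution, entropy,
                                   improvement_vs_relatedness,
                                   mi_entropy_ratio, mutual_information,
                                   rank_auxiliaries, relatedness_table)


def brute_force_mi(counts) -> float:
    """Independent oracle: sum over cells of p * log2(p / (p_row * p_col))."""
    c = np.asarray(counts, dtype=float)
    p = c / c.sum()
    rows, cols = p.sum(axis=1), p.sum(axis=0)
    out = 0.0
    for i in range(2):
        for j in range(2):
            if p[i, j] > 0:
                out += p[i, j] * np.log2(p[i, j] / (rows[i] * cols[j]))
    return out


class TestEntropy:
    def test_balanced_is_one_bit(self):
        assert entropy(0.5) == 1.0

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_is_zero(self, p):
        assert entropy(p) == 0.0

    def test_quarter_value(self):
        assert entropy(0.25) == pytest.approx(0.811278, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            entropy(1.2)


class TestMutualInformation:
    def test_identical_assays_give_target_entropy(self):
        d = AssayDistribution.from_counts([[70, 0], [0, 30]])
        assert mutual_information(d) == pytest.approx(entropy(0.3), abs=1e-9)

    def test_factorized_joint_gives_zero(self):
        # p(a,b) = p(a) p(b): counts 60/40 x 50/50
        d = AssayDistribution.from_counts([[30, 30], [20, 20]])
        assert mutual_information(d) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric(self):
        c = np.array([[40, 10], [5, 45]])
        d1 = AssayDistribution.from_counts(c)
        d2 = AssayDistribution.from_counts(c.T)
        assert mutual_information(d1) == pytest.approx(mutual_information(d2),
                                                       abs=1e-12)

    def test_matches_brute_force_cell_sum(self):
        counts = [[40, 10], [10, 40]]
        d = AssayDistribution.from_counts(counts)
        assert mutual_information(d) == pytest.approx(brute_force_mi(counts),
                                                      abs=1e-9)

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(1, 100, (2, 2))
            d = AssayDistribution.from_counts(counts)
            mi = mutual_information(d)
            assert -1e-9 <= mi <= min(entropy(d.p_a), entropy(d.p_b)) + 1e-9

    def test_small_overlap_flagged_undefined(self):
        d = AssayDistribution.from_counts([[5, 1], [1, 5]])
        assert np.isnan(mutual_information(d, min_overlap=20))

    def test_marginals_consistent(self):
        d = AssayDistribution.from_counts([[40, 10], [5, 45]])
        assert d.joint.sum() == pytest.approx(1.0)
        assert d.joint[1, :].sum() == pytest.approx(d.p_a)


class TestMiEntropyRatio:
    def frame_from_counts(self, counts):
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                rows += [[float(a), float(b)]] * counts[a][b]
        return pd.DataFrame(rows, columns=["T", "X"])

    def test_duplicate_assay_ratio_one(self):
        labels = self.frame_from_counts([[70, 0], [0, 30]])
        assert mi_entropy_ratio(labels, "T", "X", label_scope="all") == \
            pytest.approx(1.0, abs=1e-9)

    def test_independent_assay_ratio_zero(self):
        labels = self.frame_from_counts([[30, 30], [20, 20]])
        assert mi_entropy_ratio(labels, "T", "X", label_scope="all") == \
            pytest.approx(0.0, abs=1e-9)

    def test_intermediate_table_matches_oracle(self):
        counts = [[45, 5], [12, 38]]
        labels = self.frame_from_counts(counts)
        got = mi_entropy_ratio(labels, "T", "X", label_scope="all")
        expect = brute_force_mi(counts) / entropy(0.5)
        assert got == pytest.approx(expect, abs=1e-9)
        assert 0.3 < got < 0.45  # a mid-range relatedness, typical of selected pairs

    def test_zero_entropy_target_flagged(self):
        labels = pd.DataFrame({"T": [1.0] * 30, "X": [0.0, 1.0] * 15})
        assert np.isnan(mi_entropy_ratio(labels, "T", "X", label_scope="all"))

    def test_ratio_within_unit_interval_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            labels = self.frame_from_counts(rng.integers(5, 60, (2, 2)).tolist())
            r = mi_entropy_ratio(labels, "T", "X", label_scope="all")
            assert -1e-9 <= r <= 1 + 1e-9


class TestRankAuxiliaries:
    def panel(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, 300).astype(float)
        noise = lambda: rng.integers(0, 2, 300).astype(float)
        return pd.DataFrame({"T": t, "DUP": t, "N1": noise(), "N2": noise()})

    def test_duplicate_ranks_first(self):
        labels = self.panel()
        assert rank_auxiliaries(labels, "T", 1, label_scope="all") == ["DUP"]

    def test_random_additive_sets_are_nested(self):
        labels = self.panel()
        k1 = rank_auxiliaries(labels, "T", 1, strategy="random_additive", seed=5)
        k3 = rank_auxiliaries(labels, "T", 3, strategy="random_additive", seed=5)
        assert k3[:1] == k1

    def test_ratio_ties_break_lexically(self):
        t = pd.Series([0.0, 1.0] * 50)
        labels = pd.DataFrame({"T": t, "B": t, "A": t})
        assert rank_auxiliaries(labels, "T", 2, label_scope="all") == ["A", "B"]

    def test_k_must_be_below_assay_count(self):
        with pytest.raises(ValueError):
            rank_auxiliaries(self.panel(), "T", 4)


class TestImprovementCorrelation:
    def table(self, deltas, ratios):
        pairs = [("T", f"X{i}") for i in range(len(deltas))]
        res = pd.DataFrame({"target": [p[0] for p in pairs],
                            "auxiliary": [p[1] for p in pairs],
                            "delta_mcc": deltas})
        rel = pd.DataFrame({"target": [p[0] for p in pairs],
                            "auxiliary": [p[1] for p in pairs],
                            "mi_entropy_ratio": ratios})
        return res, rel

    def test_proportional_gives_r_one(self):
        res, rel = self.table([0.1, 0.2, 0.3, 0.4], [0.25, 0.5, 0.75, 1.0])
        r, _ = improvement_vs_relatedness(res, rel)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_constant_delta_is_undefined(self):
        res, rel = self.table([0.2, 0.2, 0.2], [0.1, 0.5, 0.9])
        r, _ = improvement_vs_relatedness(res, rel)
        assert np.isnan(r)

    def test_five_point_toy_matches_textbook_formula(self):
        deltas = [0.05, 0.12, -0.02, 0.30, 0.18]
        ratios = [0.10, 0.35, 0.05, 0.80, 0.50]
        res, rel = self.table(deltas, ratios)
        r, table = improvement_vs_relatedness(res, rel)
        x, y = np.array(ratios), np.array(deltas)
        expect = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(expect, abs=1e-12)
        assert len(table) == 5


def test_label_noise_never_raises_expected_mi():
    """Data-processing-inequality analogue, in expectation over seeds."""
    mis = {0.0: [], 0.2: []}
    for seed in range(50):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 400).astype(float)
        b = a.copy()
        for noise in mis:
            flips = rng.random(400) < noise
            bn = np.where(flips, 1 - b, b)
            d = AssayDistribution.from_labels(a, bn)
            mis[noise].append(mutual_information(d))
    assert np.mean(mis[0.2]) < np.mean(mis[0.0])


def test_ranked_selection_recovers_shared_mechanism_assays():
    """Top-k MI-ratio picks recover the truly related assays at low noise."""
    load = np.zeros((6, 6), dtype=bool)
    load[0, [0, 1]] = True
    load[1, [0, 1]] = True   # related to A0
    load[2, [1, 2]] = True   # related to A0
    for j in (3, 4, 5):
        load[j, j] = True    # unrelated
    hits = 0
    for seed in range(10):
        cfg = SyntheticConfig(n_compounds=3000, n_assays=6, n_mechanisms=6,
                              mechanism_loadings=load, label_flip_rate=0.02,
                              n_bits=32, seed=seed)
        _, labels, _ = generate_panel(cfg)
        top2 = rank_auxiliaries(labels, "A0", 2, label_scope="all")
        hits += len(set(top2) & {"A1", "A2"})
    assert hits / 20 >= 0.9


def test_relatedness_table_shape_and_symmetry(toy_labels):
    table = relatedness_table(toy_labels, label_scope="all", min_overlap=1)
    assert len(table) == 6  # 3 assays, ordered pairs
    ab = table.query("target=='A' and auxiliary=='B'")["mi"].iloc[0]
    ba = table.query("target=='B' and auxiliary=='A'")["mi"].iloc[0]
    assert ab == pytest.approx(ba, abs=1e-12)
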