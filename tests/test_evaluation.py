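"""Metrics, GHOST, bins, multi-seed aggregation."""

import numpy as np
import pandas as pd
import pytest

from toximpute.evaluation import (ConfusionCounts, bin_by_availability,
                                  bin_by_similarity, binned_evaluation,
                                  f1_and_auc, ghost_threshold, mcc,
                                  mcc_from_predictions, multi_seed_summary,
                                  nearest_neighbor_similarity, tanimoto)


class TestMcc:
    def test_perfect_classifier(self):
        assert mcc(ConfusionCounts(tp=50, fp=0, tn=50, fn=0)) == 1.0

    def test_hand_computed_value(self):
        # (40*40 - 10*10) / sqrt(50^4) = 1500/2500
        assert mcc(ConfusionCounts(tp=40, fp=10, tn=40, fn=10)) == \
            pytest.approx(0.6, abs=1e-12)

    def test_all_positive_predictions_scored_zero(self):
        assert mcc(ConfusionCounts(tp=30, fp=70, tn=0, fn=0)) == 0.0

    def test_empty_counts_undefined(self):
        assert np.isnan(mcc(ConfusionCounts(0, 0, 0, 0)))

    def test_equals_pearson_correlation_of_binary_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 200)
            p = np.where(rng.random(200) < 0.3, 1 - y, y)
            if len(np.unique(y)) < 2 or len(np.unique(p)) < 2:
                continue
            expect = np.corrcoef(y, p)[0, 1]
            assert mcc_from_predictions(y, p) == pytest.approx(expect, abs=1e-9)


class TestF1Auc:
    def test_perfect_separation(self):
        scores = np.array([0.9] * 5 + [0.1] * 5)
        labels = np.array([1] * 5 + [0] * 5)
        f1, auc = f1_and_auc(scores, labels)
        assert f1 == 1.0 and auc == 1.0

    def test_anticorrelated_scores_zero_auc(self):
        scores = np.array([0.1] * 5 + [0.9] * 5)
        labels = np.array([1] * 5 + [0] * 5)
        assert f1_and_auc(scores, labels)[1] == 0.0

    def test_tie_handling_matches_pair_counting(self):
        scores = np.array([0.8, 0.5, 0.5, 0.5, 0.3, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0])
        # brute force: over all pos/neg pairs, win=1, tie=0.5
        wins = 0.0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        expect = wins / (3 * 3)
        assert f1_and_auc(scores, labels)[1] == pytest.approx(expect, abs=1e-12)

    def test_single_class_auc_undefined(self):
        f1, auc = f1_and_auc([0.2, 0.8], [1, 1])
        assert np.isnan(auc)


class TestGhost:
    def test_perfectly_separated_picks_lowest_optimal_candidate(self):
        scores = np.array([0.9] * 30 + [0.1] * 70)
        labels = np.array([1] * 30 + [0] * 70)
        # every candidate in [0.15, 0.55] reaches (0,1); tie-break -> 0.15
        assert ghost_threshold(scores, labels, seed=0) == 0.15

    def test_constant_scores_fall_back(self):
        scores = np.full(60, 0.4)
        labels = np.array([0, 1] * 30)
        assert ghost_threshold(scores, labels, seed=1) == 0.5

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            ghost_threshold([0.2, 0.4], [1, 1])

    def test_output_always_in_candidate_set_or_fallback(self):
        rng = np.random.default_rng(2)
        cands = set(np.round(np.arange(0.05, 0.551, 0.05), 2)) | {0.5}
        for seed in range(5):
            y = rng.integers(0, 2, 150)
            s = np.clip(rng.normal(0.3 + 0.2 * y, 0.2), 0, 1)
            thr = ghost_threshold(s, y, seed=seed, n_bootstrap=20)
            # median of grid members can fall between two candidates
            doubled = {round((a + b) / 2, 3) for a in cands for b in cands}
            assert round(thr, 3) in doubled

    def test_miscalibrated_imbalanced_scores_get_lower_threshold(self):
        rng = np.random.default_rng(3)
        n = 2000
        y = (rng.random(n) < 0.05).astype(int)
        s = np.clip(np.where(y == 1, rng.normal(0.3, 0.05, n),
                             rng.normal(0.1, 0.05, n)), 0, 1)
        thr = ghost_threshold(s[:1000], y[:1000], seed=0)
        assert thr < 0.5
        m_ghost = mcc_from_predictions(y[1000:], s[1000:] >= thr)
        m_default = mcc_from_predictions(y[1000:], s[1000:] >= 0.5)
        assert m_ghost > m_default


class TestSimilarityBins:
    def test_identical_vectors_hit_top_bin(self):
        train = np.tile([1, 1, 0, 1, 0, 0, 1, 0], (6, 1))
        test = train[:1]
        bins, sims = bin_by_similarity(test, train)
        assert sims[0] == 1.0 and bins[0] == 3

    def test_disjoint_vectors_hit_bottom_bin(self):
        train = np.tile([1, 1, 0, 0], (5, 1))
        test = np.array([[0, 0, 1, 1]])
        bins, sims = bin_by_similarity(test, train)
        assert sims[0] == 0.0 and bins[0] == 1

    def test_left_closed_edges(self):
        sims = np.array([0.0, 0.4, 0.59, 0.6, 1.0])
        bins = np.digitize(sims, [0.4, 0.6]) + 1
        np.testing.assert_array_equal(bins, [1, 2, 2, 3, 3])

    def test_mean_of_five_nearest(self):
        rng = np.random.default_rng(0)
        train = (rng.random((20, 30)) < 0.4).astype(int)
        test = (rng.random((4, 30)) < 0.4).astype(int)
        sims = nearest_neighbor_similarity(test, train, n_neighbors=5)
        full = tanimoto(test, train)
        expect = np.sort(full, axis=1)[:, -5:].mean(axis=1)
        np.testing.assert_allclose(sims, expect)

    def test_fewer_than_five_training_compounds_uses_all(self):
        train = np.tile([1, 0, 1, 0], (3, 1))
        sims = nearest_neighbor_similarity(train[:1], train, n_neighbors=5)
        assert sims[0] == 1.0

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            nearest_neighbor_similarity(np.ones((1, 4)), np.ones((0, 4)))


class TestAvailabilityBins:
    def make_split(self, counts):
        # one test assay T plus 5 aux assays with given per-compound train counts
        rows = []
        for c in counts:
            rows.append(["test"] + ["train"] * c + [np.nan] * (5 - c))
        return pd.DataFrame(rows, columns=["T"] + [f"X{i}" for i in range(5)],
                            index=[f"c{i}" for i in range(len(counts))])

    @pytest.mark.parametrize("count,expected", [(0, 1), (1, 1), (2, 2),
                                                (3, 2), (4, 3), (5, 3)])
    def test_bin_edges(self, count, expected):
        split = self.make_split([count])
        assert bin_by_availability(split, "T").iloc[0] == expected


class TestBinnedEvaluation:
    def run(self, sizes, min_per_bin=100):
        rng = np.random.default_rng(0)
        bins = np.concatenate([[b + 1] * n for b, n in enumerate(sizes)])
        n = bins.size
        y = pd.Series(rng.integers(0, 2, n).astype(float))
        s = pd.Series(np.clip(0.5 * y + rng.normal(0.25, 0.2, n), 0, 1))
        return binned_evaluation(s, y, pd.Series(bins), min_per_bin=min_per_bin)

    def test_well_populated_assay_included(self):
        table, included = self.run([120, 130, 140])
        assert included and list(table["n"]) == [120, 130, 140]

    def test_boundary_bin_excluded(self):
        _, included = self.run([99, 130, 140])
        assert not included

    def test_zero_minimum_includes_all(self):
        _, included = self.run([1, 1, 1], min_per_bin=0)
        assert included

    def test_bin_counts_partition_the_test_set(self):
        table, _ = self.run([50, 60, 70], min_per_bin=0)
        assert table["n"].sum() == 180


class TestMultiSeedSummary:
    def tidy(self, values):
        # values: {(method, assay, seed): mcc}
        rows = [{"method": m, "assay": a, "seed": s, "mcc": v}
                for (m, a, s), v in values.items()]
        return pd.DataFrame(rows)

    def test_constant_values(self):
        vals = {("st", a, s): 0.5 for a in "AB" for s in range(4)}
        out = multi_seed_summary(self.tidy(vals))
        assert out["median"].iloc[0] == 0.5 and out["iqr"].iloc[0] == 0.0

    def test_three_seed_median(self):
        vals = {("st", "A", s): v for s, v in enumerate([0.4, 0.5, 0.6])}
        assert multi_seed_summary(self.tidy(vals))["median"].iloc[0] == 0.5

    def test_mean_then_median_ordering(self):
        # 4 seeds x 2 assays; the assay means per seed are 0.2,0.3,0.5,0.7
        table = {("st", "A", 0): 0.1, ("st", "B", 0): 0.3,
                 ("st", "A", 1): 0.2, ("st", "B", 1): 0.4,
                 ("st", "A", 2): 0.4, ("st", "B", 2): 0.6,
                 ("st", "A", 3): 0.6, ("st", "B", 3): 0.8}
        out = multi_seed_summary(self.tidy(table))
        assert out["median"].iloc[0] == pytest.approx(0.4)  # median of means
        assert out["q1"].iloc[0] == pytest.approx(np.percentile([0.2, 0.3, 0.5, 0.7], 25))


def test_raising_threshold_never_increases_positive_calls():
    rng = np.random.default_rng(1)
    scores = rng.random(500)
    n_pos = [(scores >= t).sum() for t in np.linspace(0, 1, 21)]
    assert all(a >= b for a, b in zip(n_pos, n_pos[1:]))
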