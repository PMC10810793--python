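"""Silhouette, SigClust cluster index and p-value, permutation tests, and
the full source-pair comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score as sk_silhouette

import mglkit as mk
from mglkit.datatypes import ExpressionMatrix
from mglkit.separability import (
    _within_ss,
    compare_sources,
    permutation_pvalue,
    sigclust_ci,
    sigclust_pvalue,
    silhouette_width,
)


class TestSilhouette:
    def test_hand_computed_1d_example(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        labels = ["A", "A", "B", "B"]
        assert silhouette_width(pts, labels) == pytest.approx(0.89975, abs=5e-6)

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 25))
            d = int(rng.integers(1, 5))
            pts = rng.normal(size=(n, d))
            labels = rng.permutation(["a"] * (n // 2) + ["b"] * (n - n // 2))
            ours = silhouette_width(pts, labels)
            theirs = sk_silhouette(pts, labels)
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_null_near_zero_and_monotone_in_separation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(100, 3))
        labels = ["a"] * 50 + ["b"] * 50
        assert abs(silhouette_width(pts, labels)) < 0.15
        means = []
        for delta in (0.0, 1.0, 2.0, 4.0):
            vals = []
            for r in range(10):
                g = np.random.default_rng(100 + r).normal(size=(40, 3))
                g[20:, 0] += delta
                vals.append(silhouette_width(g, ["a"] * 20 + ["b"] * 20))
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            silhouette_width(np.zeros((3, 2)), ["a", "b", "b"])


class TestClusterIndex:
    def test_perfect_split_and_two_points_give_zero(self):
        clumps = np.vstack([np.zeros((5, 2)), np.tile([10.0, 0.0], (5, 1))])
        assert sigclust_ci(clumps) == pytest.approx(0.0, abs=1e-12)
        assert sigclust_ci(np.array([[0.0, 0.0], [3.0, 1.0]])) == pytest.approx(0.0)

    def test_identical_points_guarded(self):
        with pytest.warns(UserWarning, match="identical"):
            assert sigclust_ci(np.ones((4, 2))) == 0.0

    def test_matches_exhaustive_partition_search(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            pts = rng.normal(size=(n, int(rng.integers(1, 4))))
            ci = sigclust_ci(pts, rng=int(rng.integers(2**31)))
            total = ((pts - pts.mean(0)) ** 2).sum()
            best = min(
                _within_ss(pts, np.array(assign))
                for assign in itertools.product([0, 1], repeat=n)
            ) / total
            assert ci == pytest.approx(best, abs=1e-12)

    def test_labeled_partition_mode(self):
        # within-SS = 0.5 + 0.5; total SS about the grand mean 5.5 is 101
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert sigclust_ci(pts, labels=["a", "a", "b", "b"]) == pytest.approx(
            1.0 / 101.0, abs=1e-12
        )


class TestSigclustPvalue:
    def test_p_always_a_proportion(self):
        rng = np.random.default_rng(0)
        for r in range(5):
            p = sigclust_pvalue(rng.normal(size=(12, 3)), n_null=150, rng=r)
            assert 0.0 <= p <= 1.0

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(size=(20, 3)), rng.normal(size=(20, 3)) + [10, 0, 0]])
        assert sigclust_pvalue(pts, n_null=1000, rng=1) <= 0.01

    def test_single_cloud_never_anticonservative(self):
        # estimated-spectrum nulls overdisperse at this n/d, so the test is
        # conservative: few small p-values, non-degenerate distribution
        ps = [
            sigclust_pvalue(np.random.default_rng(500 + r).standard_normal((40, 5)),
                            n_null=300, rng=r)
            for r in range(60)
        ]
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.12
        assert np.median(ps) > 0.2

    def test_coarse_null_warns(self):
        with pytest.warns(UserWarning, match="n_null"):
            sigclust_pvalue(np.random.default_rng(0).normal(size=(10, 2)), n_null=50, rng=0)


class TestPermutationPvalue:
    def test_counting_rule(self):
        # score function fed from a fixed queue: observed 0.9 then 4 permuted
        queue = iter([0.9, 0.95, 0.5, 0.2, 0.1])
        obs, p = permutation_pvalue(
            np.zeros((8, 2)), ["a"] * 4 + ["b"] * 4, score=lambda pts, lab: next(queue),
            n_perm=4, rng=0,
        )
        assert obs == 0.9
        assert p == pytest.approx(0.25)

    def test_all_ties_give_zero_under_strict_rule(self):
        obs, p = permutation_pvalue(
            np.zeros((8, 2)), ["a"] * 4 + ["b"] * 4, score=lambda pts, lab: 1.0,
            n_perm=10, rng=0,
        )
        assert p == 0.0
        _, p1 = permutation_pvalue(
            np.zeros((8, 2)), ["a"] * 4 + ["b"] * 4, score=lambda pts, lab: 1.0,
            n_perm=10, rng=0, correction="add_one",
        )
        assert p1 == pytest.approx(1.0 / 11.0)

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(16, 2))
        labels = np.array(["x"] * 8 + ["y"] * 8)
        flipped = np.where(labels == "x", "y", "x")
        for score in ("silhouette", "sigclust"):
            _, p_a = permutation_pvalue(pts, labels, score=score, n_perm=50, rng=11, n_null=200)
            _, p_b = permutation_pvalue(pts, flipped, score=score, n_perm=50, rng=11, n_null=200)
            assert p_a == p_b

    def test_null_calibration_of_silhouette_p(self):
        rejections = 0
        n_rep = 60
        for r in range(n_rep):
            pts = np.random.default_rng(800 + r).normal(size=(20, 2))
            _, p = permutation_pvalue(pts, ["a"] * 10 + ["b"] * 10, n_perm=100, rng=r)
            rejections += p <= 0.05
        assert 0.0 <= rejections / n_rep <= 0.15


class TestCompareSources:
    def _null_pair(self, seed):
        cfg = mk.BulkSimConfig(seed=seed, source_effect_size=0.0, batch_effect_sd=0.0,
                               n_batches=1, n_genes=800)
        matrix, meta, _ = mk.generate_bulk_dataset(cfg)
        pre = mk.preprocess_bulk(matrix, meta)
        return pre

    def test_one_row_per_pair_and_null_behavior(self):
        pre = self._null_pair(21)
        results = compare_sources(
            pre["log2"], pre["meta"], [("source_1", "source_2")], n_perm=50, rng=1,
            n_null=200,
        )
        assert len(results) == 1
        res = results[0]
        assert res.no_signal or (res.silhouette_p >= 0.2 or res.sigclust_p >= 0.2)

    def test_planted_shift_detected(self):
        cfg = mk.BulkSimConfig(seed=33, source_effect_size=2.0, n_batches=1,
                               batch_effect_sd=0.0, n_genes=800)
        matrix, meta, _ = mk.generate_bulk_dataset(cfg)
        pre = mk.preprocess_bulk(matrix, meta)
        res = compare_sources(
            pre["log2"], pre["meta"], [("source_1", "source_2")], n_perm=100, rng=2,
            n_null=300,
        )[0]
        assert res.n_meaningful >= 1
        assert res.silhouette_p <= 0.05
        assert res.sigclust_p <= 0.05

    def test_missing_source_skipped(self):
        pre = self._null_pair(5)
        results = compare_sources(
            pre["log2"], pre["meta"], [("source_1", "ghost")], n_perm=20, rng=0
        )
        assert results == []
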