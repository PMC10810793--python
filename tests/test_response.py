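"""Single-cell QC and DE, threshold calls, bulk normalization, overlaps,
deconvolution, concordance and panel summaries."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from mglkit.datatypes import ExpressionMatrix
from mglkit.response import (
    bh_adjust,
    bulk_contrast_de,
    call_bulk_degs,
    call_cluster_degs,
    call_cluster_markers,
    deconvolute_bulk_degs,
    deg_overlap,
    dose_concordance,
    exact_rank_sum_pvalue,
    filter_cells_qc,
    filter_genes_detection,
    median_of_ratios,
    normalize_cells,
    panel_medians,
    wilcoxon_de,
)


def _adata(counts, genes=None, **obs_cols):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[1])]
    obs = pd.DataFrame(obs_cols, index=[f"c{i}" for i in range(counts.shape[0])])
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=pd.Index(genes)))


class TestCellQC:
    @pytest.mark.parametrize(
        "genes,reads,mito,kept",
        [
            (1500, 50_000, 0.05, False),   # exactly 1500 genes -> removed
            (1501, 100_000, 0.05, False),  # exactly 100k reads -> removed
            (1600, 50_000, 0.19, True),    # inside all thresholds -> kept
            (1600, 50_000, 0.20, False),   # exactly 20% mito -> removed
        ],
    )
    def test_literal_thresholds(self, genes, reads, mito, kept):
        adata = _adata(
            np.zeros((2, 3)),
            n_genes_detected=[genes, 2000],
            total_counts=[reads, 50_000],
            mito_fraction=[mito, 0.01],
        )
        out, log = filter_cells_qc(adata)
        assert ("c0" in out.obs_names) is kept
        assert "c1" in out.obs_names

    def test_metadata_recomputed_when_missing(self):
        counts = np.array([[5, 0, 3], [1, 1, 1]])
        adata = _adata(counts, genes=["MT-X", "A", "B"])
        out, _ = filter_cells_qc(adata)
        # every toy cell fails the 1500-gene rule; the log must say so
        assert out.n_obs == 0

    def test_gene_detection_filter_boundary(self):
        counts = np.array(
            [[1, 1, 0], [1, 1, 0], [0, 1, 1], [0, 0, 0]]
        )  # detected in 2, 3, 2 cells... columns: G0=2, G1=3, G2=1
        adata = _adata(counts)
        out = filter_genes_detection(adata)
        assert list(out.var_names) == ["G1"]


class TestNormalization:
    def test_single_gene_cell_closed_form(self):
        adata = _adata(np.array([[5, 0], [2, 2]]))
        norm = normalize_cells(adata)
        x = np.asarray(norm.X.todense())
        assert x[0, 0] == pytest.approx(np.log(1 + 10_000.0))
        assert x[0, 1] == 0.0

    def test_column_sums_hit_target_before_log(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(10, 30))
        counts[:, 0] += 1
        adata = _adata(counts)
        norm = normalize_cells(adata)
        back = np.expm1(np.asarray(norm.X.todense()))
        np.testing.assert_allclose(back.sum(axis=1), 10_000.0, rtol=1e-9)

    def test_zero_total_cell_rejected(self):
        adata = _adata(np.array([[0, 0], [1, 2]]))
        with pytest.raises(ValueError, match="zero total"):
            normalize_cells(adata)


class TestWilcoxon:
    def test_identical_groups_are_null(self):
        x = np.log1p(np.arange(12, dtype=float).reshape(4, 3))
        de = wilcoxon_de(x, x, ["A", "B", "C"])
        assert (de["p_value"] == 1.0).all()
        assert np.allclose(de["log2_fc"], 0.0)

    def test_exact_branch_matches_itertools_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            na, nb = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            x = rng.integers(0, 5, na).astype(float)
            y = rng.integers(0, 5, nb).astype(float)
            p = exact_rank_sum_pvalue(x, y)
            ranks = stats.rankdata(np.concatenate([x, y]))
            n = na + nb
            mu = na * (n + 1) / 2
            obs = ranks[:na].sum()
            hits = total = 0
            for comb in itertools.combinations(range(n), na):
                s = ranks[list(comb)].sum()
                total += 1
                hits += abs(s - mu) >= abs(obs - mu) - 1e-9
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_exact_and_asymptotic_agree_at_crossover(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.normal(size=(10, 1))
            y = rng.normal(loc=0.5, size=(10, 1))
            p_exact = wilcoxon_de(x, y, ["G"], exact_max_group=10)["p_value"][0]
            p_asym = wilcoxon_de(x, y, ["G"], exact_max_group=5)["p_value"][0]
            assert abs(p_exact - p_asym) <= 0.02

    def test_planted_shift_recovered_in_lfc(self):
        # cells from NB means mu and mu * 2^1.5: lfc estimate near 1.5
        rng = np.random.default_rng(3)
        lfcs = []
        for r in range(10):
            mu = 8.0
            a = rng.poisson(mu * 2**1.5, size=(200, 1))
            b = rng.poisson(mu, size=(200, 1))
            # normalize both to the same library scale (single gene: identity)
            de = wilcoxon_de(np.log1p(a.astype(float)), np.log1p(b.astype(float)), ["G"])
            lfcs.append(de["log2_fc"][0])
        assert abs(np.mean(lfcs) - np.log2((mu * 2**1.5 + 1) / (mu + 1))) <= 0.1


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_p_unchanged_and_bonferroni(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_adjust([0.01, 0.4], method="bonferroni"), [0.02, 0.8])

    def test_matches_hand_rolled_step_up(self):
        def step_up(p):
            p = np.asarray(p, dtype=float)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank_i in range(n - 1, -1, -1):
                i = order[rank_i]
                running = min(running, p[i] * n / (rank_i + 1))
                adj[i] = running
            return adj

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), step_up(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestThresholdCalls:
    def _table(self, **kw):
        row = dict(gene="G", contrast="t_vs_c", cluster="C1", p_value=0.001,
                   log2_fc=0.7, adj_p=0.005, pct_group1=45.0, pct_group2=30.0)
        row.update(kw)
        return pd.DataFrame([row])

    @pytest.mark.parametrize(
        "kw,is_marker",
        [
            (dict(), True),
            (dict(pct_group1=40.0), False),       # strict >
            (dict(adj_p=0.02, pct_group1=60.0, log2_fc=1.0), False),
            (dict(log2_fc=-1.0), False),          # upregulated only
        ],
    )
    def test_marker_criteria(self, kw, is_marker):
        assert (len(call_cluster_markers(self._table(**kw))) == 1) is is_marker

    @pytest.mark.parametrize(
        "kw,is_deg,direction",
        [
            (dict(log2_fc=-0.8, adj_p=0.01, pct_group1=30.0), True, "down"),
            (dict(log2_fc=0.6, adj_p=0.01, pct_group1=30.0), False, None),  # boundary
            (dict(log2_fc=0.8, adj_p=0.01, pct_group1=5.0, pct_group2=12.0), True, "up"),
            (dict(log2_fc=0.8, adj_p=0.01, pct_group1=5.0, pct_group2=5.0), False, None),
        ],
    )
    def test_cluster_deg_criteria(self, kw, is_deg, direction):
        out = call_cluster_degs(self._table(**kw))
        assert (len(out) == 1) is is_deg
        if is_deg:
            assert out["direction"][0] == direction

    @pytest.mark.parametrize(
        "lfc,adj_p,tpms,is_deg",
        [
            (0.7, 0.04, [2.0, 0.5], True),
            (0.7, 0.04, [1.0, 0.5], False),  # max TPM exactly 1: strict >
            (2.0, 0.2, [5.0, 5.0], False),
        ],
    )
    def test_bulk_deg_criteria(self, lfc, adj_p, tpms, is_deg):
        stats_table = pd.DataFrame([dict(gene="G1", log2_fc=lfc, adj_p=adj_p)])
        tpm = ExpressionMatrix(
            pd.DataFrame([tpms], index=["G1"], columns=["s1", "s2"]), space="TPM"
        )
        assert (len(call_bulk_degs(stats_table, tpm)) == 1) is is_deg

    def test_threshold_calls_are_pure_filters(self):
        rng = np.random.default_rng(0)
        de = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(50)],
                "log2_fc": rng.normal(scale=1.0, size=50),
                "adj_p": rng.random(50),
                "pct_group1": rng.random(50) * 100,
                "pct_group2": rng.random(50) * 100,
            }
        )
        once = call_cluster_degs(de)
        twice = call_cluster_degs(once)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once["gene"]) <= set(de["gene"])


class TestMedianOfRatios:
    def test_hand_example(self):
        counts = pd.DataFrame({"s1": [2, 4, 8], "s2": [4, 8, 16]}, index=["A", "B", "C"])
        factors, norm = median_of_ratios(counts)
        np.testing.assert_allclose(factors, [0.70711, 1.41421], atol=1e-5)
        np.testing.assert_allclose(norm["s1"] * factors["s1"], counts["s1"])

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [3, 7, 2], "b": [3, 7, 2], "c": [3, 7, 2]})
        factors, _ = median_of_ratios(counts)
        np.testing.assert_allclose(factors, 1.0)

    def test_scaling_equivariance(self):
        # against a fixed reference, scaling one sample by c scales its size
        # factor by exactly c; refitting shifts the reference, so the factor
        # ratio to any other sample scales by c instead
        from mglkit.response import MedianOfRatiosNormalizer

        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 4)), columns=list("abcd"))
        est = MedianOfRatiosNormalizer().fit(counts.T.to_numpy())
        f0 = est._factors(counts.T.to_numpy())
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        f_fixed = est._factors(scaled.T.to_numpy())
        assert f_fixed[1] / f0[1] == pytest.approx(3.0, rel=1e-9)
        f1, _ = median_of_ratios(scaled)
        f0_series, _ = median_of_ratios(counts)
        assert (f1["b"] / f1["a"]) / (f0_series["b"] / f0_series["a"]) == pytest.approx(
            3.0, rel=1e-9
        )

    def test_all_zero_rows_only_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="reference"):
            median_of_ratios(counts)


class TestOverlapDeconvolutionConcordance:
    def test_overlap_partitions(self):
        assert deg_overlap({"A", "B", "C"}, {"B", "C", "D"}) == (1, 2, 1)
        assert deg_overlap({"A", "B"}, {"A", "B"}) == (0, 2, 0)
        assert deg_overlap({"A"}, {"B", "C"}) == (1, 0, 2)

    def test_deconvolution_set_logic(self):
        bulk = pd.DataFrame(
            {"gene": ["A", "B", "C"], "direction": ["up", "up", "up"]}
        )
        sc = pd.DataFrame(
            {"gene": ["A", "A", "C"], "cluster": ["C1", "C4", "C4"],
             "direction": ["up", "up", "up"]}
        )
        out = deconvolute_bulk_degs(bulk, sc).set_index("gene")
        assert out.loc["A", "clusters"] == ["C1", "C4"]
        assert out.loc["B", "bulk_only"]
        assert out.loc["C", "clusters"] == ["C4"]

    def test_deconvolution_partitions_and_flags_discordance(self):
        bulk = pd.DataFrame({"gene": ["A", "B"], "direction": ["up", "down"]})
        sc = pd.DataFrame(
            {"gene": ["A", "B"], "cluster": ["C1", "C2"], "direction": ["down", "down"]}
        )
        out = deconvolute_bulk_degs(bulk, sc).set_index("gene")
        assert out.loc["A", "bulk_only"] and out.loc["A", "discordant_clusters"] == ["C1"]
        assert out.loc["B", "clusters"] == ["C2"]
        # every bulk DEG appears exactly once
        assert sorted(out.index) == ["A", "B"]

    def test_empty_cluster_tables_all_bulk_only(self):
        bulk = pd.DataFrame({"gene": ["A"], "direction": ["up"]})
        out = deconvolute_bulk_degs(bulk, pd.DataFrame(columns=["gene", "cluster", "direction"]))
        assert out["bulk_only"].all()

    def test_concordance_closed_forms_and_hand_example(self):
        fc = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("ABCD"))
        r, n, genes = dose_concordance(fc, fc)
        assert r == pytest.approx(1.0)
        r_neg, _, _ = dose_concordance(fc, -fc)
        assert r_neg == pytest.approx(-1.0)
        a = pd.Series([0.2, 1.0, -0.5, 2.0, 0.0], index=list("ABCDE"))
        b = pd.Series([0.1, 0.8, -0.2, 1.5, 0.3], index=list("ABCDE"))
        cov = np.cov(a, b, ddof=1)[0, 1]
        expected = cov / (a.std(ddof=1) * b.std(ddof=1))
        r_h, n_h, _ = dose_concordance(a, b)
        assert r_h == pytest.approx(expected, abs=1e-12)
        assert n_h == 5
        with pytest.raises(ValueError, match="3 shared"):
            dose_concordance(fc.iloc[:2], fc.iloc[:2])


class TestPanelMedians:
    def test_group_medians_and_missing_flags(self):
        tpm = ExpressionMatrix(
            pd.DataFrame(
                {"s1": [1.0, 4.0], "s2": [2.0, 5.0], "s3": [9.0, 6.0]},
                index=["A", "B"],
            ),
            space="TPM",
        )
        meta = pd.DataFrame(
            {"source": ["g1", "g1", "g1"]}, index=["s1", "s2", "s3"]
        )
        out = panel_medians(tpm, meta, {"p": ["A", "GHOST"]})
        a_row = out[(out.gene == "A")].iloc[0]
        assert a_row["median_tpm"] == 2.0 and not a_row["missing"]
        ghost = out[(out.gene == "GHOST")].iloc[0]
        assert ghost["missing"] and np.isnan(ghost["median_tpm"])


class TestBulkContrastDE:
    def test_recovers_planted_counts_shift(self):
        rng = np.random.default_rng(4)
        n_genes = 300
        mu = rng.uniform(20, 200, n_genes)
        planted = np.zeros(n_genes, dtype=bool)
        planted[:20] = True
        a = rng.poisson(np.where(planted, mu * 2.5, mu), size=(6, n_genes))
        b = rng.poisson(mu, size=(6, n_genes))
        counts = pd.DataFrame(
            np.vstack([a, b]).T,
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"t{i}" for i in range(6)] + [f"c{i}" for i in range(6)],
        )
        cond = pd.Series(["T"] * 6 + ["C"] * 6, index=counts.columns)
        de = bulk_contrast_de(counts, cond, "T", "C").set_index("gene")
        planted_genes = [f"G{i}" for i in range(20)]
        assert (de.loc[planted_genes, "log2_fc"] > 0.6).mean() > 0.8
        assert de.loc[planted_genes, "adj_p"].median() < 0.05
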