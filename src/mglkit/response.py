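"""Stimulus-response analysis: single-cell QC and per-cluster differential
expression, bulk count normalization and DEG calling, overlaps, dose
concordance, and bulk→cluster deconvolution.

DEG thresholds are applied with literal strict inequalities.  The default
multiple-testing adjustment is Benjamini–Hochberg within each contrast x
cluster; Bonferroni is available via ``method="bonferroni"``.  The bulk test
statistic is a two-sided Wilcoxon rank-sum on median-of-ratios-normalized
counts — a deliberately simple substitute for a negative-binomial GLM, which
is out of scope here; the threshold logic is agnostic to how the per-gene
statistics were produced.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_GENES_DETECTED = 1500       # cells kept with strictly more genes than this
MAX_READS_PER_CELL = 100_000    # cells kept with strictly fewer reads
MAX_MITO_FRACTION = 0.20        # cells kept strictly below this mito fraction
MIN_CELLS_DETECTED = 3          # genes kept when detected in >= this many cells
NORM_TOTAL = 10_000.0           # per-cell normalization target before log1p

MARKER_ADJ_P = 0.01
MARKER_MIN_PCT = 40.0
MARKER_MIN_LFC = 0.6
DEG_ADJ_P = 0.05
DEG_MIN_ABS_LFC = 0.6
DEG_MIN_PCT = 10.0
BULK_MIN_MAX_TPM = 1.0

_EXACT_MAX_GROUP = 10  # exact rank-sum enumeration when both groups <= this


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# single-cell QC
# ---------------------------------------------------------------------------

def annotate_cell_qc(adata: ad.AnnData) -> ad.AnnData:
    """(Re)compute per-cell QC columns from the count matrix."""
    counts = adata.X
    total = np.asarray(counts.sum(axis=1)).ravel()
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.upper().str.startswith("MT-")
    mito = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    adata.obs["n_genes_detected"] = detected.astype(int)
    adata.obs["total_counts"] = total
    adata.obs["mito_fraction"] = np.divide(mito, np.maximum(total, 1))
    return adata


def filter_cells_qc(adata: ad.AnnData) -> tuple[ad.AnnData, pd.DataFrame]:
    """Keep cells with >1500 genes detected, <100,000 reads, <20% mito RNA.

    Returns the filtered AnnData and a removal log (barcode, rule).
    """
    need = {"n_genes_detected", "total_counts", "mito_fraction"}
    if not need <= set(adata.obs.columns):
        adata = annotate_cell_qc(adata.copy())
    obs = adata.obs
    records = []
    for barcode, row in obs.iterrows():
        if not row["n_genes_detected"] > MIN_GENES_DETECTED:
            records.append((barcode, "genes_detected_le_1500"))
        if not row["total_counts"] < MAX_READS_PER_CELL:
            records.append((barcode, "reads_ge_100k"))
        if not row["mito_fraction"] < MAX_MITO_FRACTION:
            records.append((barcode, "mito_fraction_ge_20pct"))
    removal_log = pd.DataFrame(records, columns=["barcode", "rule"])
    keep = ~obs.index.isin(set(removal_log["barcode"]))
    return adata[keep].copy(), removal_log


def filter_genes_detection(adata: ad.AnnData, min_cells: int = MIN_CELLS_DETECTED) -> ad.AnnData:
    """Drop genes detected (count > 0) in fewer than ``min_cells`` cells."""
    detected_in = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    return adata[:, detected_in >= min_cells].copy()


class CellNormalizer(TransformerMixin, BaseEstimator):
    """Library-size normalization to a fixed total, then natural-log log1p.

    Stateless (``fit`` is a no-op); matches the common single-cell default
    of counts-per-10k followed by ln(1 + x).
    """

    def __init__(self, target_sum: float = NORM_TOTAL):
        self.target_sum = target_sum

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        if np.any(totals == 0):
            raise ValueError("cell(s) with zero total counts cannot be normalized")
        if sp.issparse(X):
            Xn = sp.csr_matrix(X, dtype=float)
            scale = self.target_sum / totals
            Xn = sp.diags(scale) @ Xn
            Xn.data = np.log1p(Xn.data)
            return Xn
        return np.log1p(np.asarray(X, dtype=float) / totals[:, None] * self.target_sum)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def normalize_cells(adata: ad.AnnData, target_sum: float = NORM_TOTAL) -> ad.AnnData:
    """Return a copy with X replaced by log1p(counts-per-``target_sum``)."""
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = CellNormalizer(target_sum=target_sum).fit_transform(adata.X)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------

def exact_rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by subset-sum dynamic programming.

    Handles ties through midranks.  p = P(|S - mu| >= |S_obs - mu|) where S
    is the group-x rank sum over all equally likely assignments of the
    observed (mid)ranks to the two groups and mu = n_x (n + 1) / 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    ranks = stats.rankdata(np.concatenate([x, y]))
    r2 = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integers
    obs = int(r2[:n_x].sum())
    mu2 = n_x * (n + 1)

    max_sum = int(r2.sum())
    # dp[k, s] = number of k-subsets of the doubled ranks with sum s
    dp = np.zeros((n_x + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in r2:
        dp[1:, r:] += dp[:-1, : max_sum + 1 - r]
    dist = dp[n_x]
    total = dist.sum()
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mu2) >= abs(obs - mu2) - 1e-9
    return float(dist[extreme].sum() / total)


def wilcoxon_de(
    norm_a: np.ndarray,
    norm_b: np.ndarray,
    gene_ids: pd.Index | list[str],
    exact_max_group: int = _EXACT_MAX_GROUP,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test between two cell groups.

    ``norm_a``/``norm_b`` are cells x genes matrices of log1p-normalized
    expression.  The p-value uses exact enumeration when both groups have at
    most ``exact_max_group`` members, else the tie-corrected normal
    approximation (with continuity correction).  The fold change is the
    ratio of mean back-transformed expression with a pseudocount of 1:
    log2((mean(expm1 a) + 1) / (mean(expm1 b) + 1)).  ``pct_*`` is the
    percentage of cells with nonzero expression.
    """
    A, B = _dense(norm_a), _dense(norm_b)
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("both groups need >= 3 cells")
    if A.shape[1] != B.shape[1] or A.shape[1] != len(gene_ids):
        raise ValueError("gene dimension mismatch")
    if A.shape[0] <= exact_max_group and B.shape[0] <= exact_max_group:
        pvals = np.array(
            [exact_rank_sum_pvalue(A[:, j], B[:, j]) for j in range(A.shape[1])]
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided", method="asymptotic")
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals[~np.isfinite(pvals)] = 1.0  # all-tied genes: no evidence either way
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "p_value": pvals,
            "log2_fc": lfc,
            "pct_group1": (A > 0).mean(axis=0) * 100.0,
            "pct_group2": (B > 0).mean(axis=0) * 100.0,
        }
    )


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini–Hochberg step-up (default) or
    Bonferroni.  Adjusted values are capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError("method must be 'bh' or 'bonferroni'")
    return multipletests(p, method=key)[1]


def cluster_contrast_de(
    adata_norm: ad.AnnData,
    group1: str,
    group2: str,
    condition_col: str = "condition",
    cluster_col: str = "cluster",
    adjust_method: str = "bh",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-cluster DE of ``group1`` vs ``group2`` cells (e.g. treated vs DMSO).

    Returns one row per (gene, cluster) with adjusted p-values computed
    within each contrast x cluster.
    """
    frames = []
    contrast = f"{group1}_vs_{group2}"
    for cluster in sorted(adata_norm.obs[cluster_col].unique()):
        in_cluster = adata_norm.obs[cluster_col] == cluster
        m1 = in_cluster & (adata_norm.obs[condition_col] == group1)
        m2 = in_cluster & (adata_norm.obs[condition_col] == group2)
        if m1.sum() < min_cells or m2.sum() < min_cells:
            logger.warning("cluster %s skipped: fewer than %d cells per side", cluster, min_cells)
            continue
        de = wilcoxon_de(
            adata_norm.X[np.flatnonzero(m1)], adata_norm.X[np.flatnonzero(m2)],
            adata_norm.var_names,
        )
        de["adj_p"] = bh_adjust(de["p_value"].to_numpy(), method=adjust_method)
        de.insert(1, "contrast", contrast)
        de.insert(2, "cluster", cluster)
        frames.append(de)
    if not frames:
        return pd.DataFrame(
            columns=["gene", "contrast", "cluster", "p_value", "log2_fc",
                     "pct_group1", "pct_group2", "adj_p"]
        )
    return pd.concat(frames, ignore_index=True)


def cluster_marker_de(
    adata_norm: ad.AnnData,
    cluster_col: str = "cluster",
    adjust_method: str = "bh",
) -> pd.DataFrame:
    """Cluster-vs-rest DE for marker identification."""
    frames = []
    for cluster in sorted(adata_norm.obs[cluster_col].unique()):
        m = (adata_norm.obs[cluster_col] == cluster).to_numpy()
        if m.sum() < 3 or (~m).sum() < 3:
            continue
        de = wilcoxon_de(
            adata_norm.X[np.flatnonzero(m)], adata_norm.X[np.flatnonzero(~m)],
            adata_norm.var_names,
        )
        de["adj_p"] = bh_adjust(de["p_value"].to_numpy(), method=adjust_method)
        de.insert(1, "contrast", "cluster_vs_rest")
        de.insert(2, "cluster", cluster)
        frames.append(de)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# threshold calls
# ---------------------------------------------------------------------------

def call_cluster_markers(
    de: pd.DataFrame,
    adj_p: float = MARKER_ADJ_P,
    min_pct: float = MARKER_MIN_PCT,
    min_lfc: float = MARKER_MIN_LFC,
) -> pd.DataFrame:
    """Markers: adjusted p < 0.01, detected percentage > 40%, log2FC > 0.6
    (upregulated in the cluster only)."""
    keep = (
        (de["adj_p"] < adj_p)
        & (de["pct_group1"] > min_pct)
        & (de["log2_fc"] > min_lfc)
    )
    return de.loc[keep].reset_index(drop=True)


def call_cluster_degs(
    de: pd.DataFrame,
    adj_p: float = DEG_ADJ_P,
    min_abs_lfc: float = DEG_MIN_ABS_LFC,
    min_pct: float = DEG_MIN_PCT,
) -> pd.DataFrame:
    """Cluster DEGs: |log2FC| > 0.6, adjusted p < 0.05, and detection
    percentage > 10% in at least one of the two groups."""
    keep = (
        (de["log2_fc"].abs() > min_abs_lfc)
        & (de["adj_p"] < adj_p)
        & (de[["pct_group1", "pct_group2"]].max(axis=1) > min_pct)
    )
    out = de.loc[keep].reset_index(drop=True)
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out


def call_bulk_degs(
    stats_table: pd.DataFrame,
    tpm: ExpressionMatrix,
    adj_p: float = DEG_ADJ_P,
    min_abs_lfc: float = DEG_MIN_ABS_LFC,
    min_max_tpm: float = BULK_MIN_MAX_TPM,
) -> pd.DataFrame:
    """Bulk DEGs: |log2FC| > 0.6, adjusted p < 0.05, max TPM across samples > 1.

    ``stats_table`` needs gene, log2_fc and adj_p columns; how the p-values
    were produced is pluggable.  Genes missing from the TPM matrix are
    excluded with a log entry.
    """
    tpm.require_space("TPM")
    table = stats_table.copy()
    table["gene"] = table["gene"].astype(str).str.upper()
    missing = ~table["gene"].isin(tpm.genes)
    if missing.any():
        logger.warning("%d gene(s) missing from the TPM matrix; excluded", int(missing.sum()))
        table = table.loc[~missing]
    max_tpm = tpm.values.max(axis=1)
    table = table.assign(max_tpm=max_tpm.loc[table["gene"]].to_numpy())
    keep = (
        (table["log2_fc"].abs() > min_abs_lfc)
        & (table["adj_p"] < adj_p)
        & (table["max_tpm"] > min_max_tpm)
    )
    out = table.loc[keep].reset_index(drop=True)
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# bulk normalization and DE
# ---------------------------------------------------------------------------

class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios size-factor normalization for bulk counts.

    The reference is the per-gene geometric mean over the fitted samples,
    restricted to genes with all-nonzero counts; each sample's size factor
    is the median over those genes of count/reference.  Input orientation is
    samples x genes.  ``size_factors_`` is set on the samples seen by
    ``fit_transform``.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        all_nonzero = (X > 0).all(axis=0)
        if not all_nonzero.any():
            raise ValueError("no gene with nonzero counts in every sample; cannot form reference")
        self.reference_mask_ = all_nonzero
        self.log_reference_ = np.log(X[:, all_nonzero]).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def _factors(self, X) -> np.ndarray:
        ratios = np.log(np.maximum(X[:, self.reference_mask_], np.finfo(float).tiny)) - self.log_reference_
        return np.exp(np.median(ratios, axis=1))

    def transform(self, X):
        check_is_fitted(self, "log_reference_")
        X = check_array(X)
        factors = self._factors(X)
        return X / factors[:, None]

    def fit_transform(self, X, y=None):
        self.fit(X)
        self.size_factors_ = self._factors(check_array(X))
        return X / self.size_factors_[:, None]


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors and normalized counts for a gene x sample count matrix."""
    est = MedianOfRatiosNormalizer()
    normalized = est.fit_transform(counts.T.to_numpy())
    factors = pd.Series(est.size_factors_, index=counts.columns, name="size_factor")
    return factors, pd.DataFrame(normalized.T, index=counts.index, columns=counts.columns)


def bulk_contrast_de(
    counts: pd.DataFrame,
    conditions: pd.Series,
    group1: str,
    group2: str,
    adjust_method: str = "bh",
) -> pd.DataFrame:
    """Bulk DE statistics: Wilcoxon on median-of-ratios-normalized counts.

    The fold change is log2((mean1 + 1)/(mean2 + 1)) of normalized counts
    (no shrinkage).
    """
    conditions = conditions.loc[counts.columns]
    _, norm = median_of_ratios(counts)
    a = norm.loc[:, conditions == group1].to_numpy()
    b = norm.loc[:, conditions == group2].to_numpy()
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("need >= 3 replicates per condition")
    de = wilcoxon_de(np.log1p(a.T), np.log1p(b.T), counts.index)
    # fold change on normalized counts, not log1p back-transform
    lfc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
    de["log2_fc"] = lfc
    de["adj_p"] = bh_adjust(de["p_value"].to_numpy(), method=adjust_method)
    de.insert(1, "contrast", f"{group1}_vs_{group2}")
    return de


# ---------------------------------------------------------------------------
# overlaps, deconvolution, concordance, panels
# ---------------------------------------------------------------------------

def deg_overlap(set_a, set_b) -> tuple[int, int, int]:
    """(|a only|, |shared|, |b only|) partition counts of two DEG sets."""
    a, b = set(set_a), set(set_b)
    return (len(a - b), len(a & b), len(b - a))


def deconvolute_bulk_degs(
    bulk_degs: pd.DataFrame, cluster_degs: pd.DataFrame
) -> pd.DataFrame:
    """Assign each bulk DEG to the clusters where it is a same-direction DEG.

    Returns one row per bulk DEG with its cluster set, a ``bulk_only`` flag
    (no same-direction cluster hit), and ``discordant_clusters`` where the
    gene is a DEG of the opposite direction (recorded, never merged).
    """
    for col in ("gene", "direction"):
        if col not in bulk_degs.columns:
            raise ValueError(f"bulk DEG table missing column {col!r}")
    rows = []
    cd = cluster_degs[["gene", "cluster", "direction"]] if len(cluster_degs) else None
    for _, rec in bulk_degs.iterrows():
        gene, direction = rec["gene"], rec["direction"]
        same, opposite = [], []
        if cd is not None:
            hits = cd[cd["gene"] == gene]
            same = sorted(hits.loc[hits["direction"] == direction, "cluster"].unique())
            opposite = sorted(hits.loc[hits["direction"] != direction, "cluster"].unique())
        rows.append(
            {
                "gene": gene,
                "direction": direction,
                "clusters": same,
                "bulk_only": len(same) == 0,
                "discordant_clusters": opposite,
            }
        )
    columns = ["gene", "direction", "clusters", "bulk_only", "discordant_clusters"]
    return pd.DataFrame(rows, columns=columns)


def dose_concordance(fc_a: pd.Series, fc_b: pd.Series) -> tuple[float, int, list[str]]:
    """Pearson correlation of log2 fold changes over the shared finite genes.

    Returns (r, n_genes, gene_list).  Fewer than 3 shared genes is an error.
    """
    shared = fc_a.index.intersection(fc_b.index)
    x = fc_a.loc[shared].astype(float)
    y = fc_b.loc[shared].astype(float)
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if len(x) < 3:
        raise ValueError("need >= 3 shared genes with finite fold changes")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(len(x)), list(x.index)


def panel_medians(
    tpm: ExpressionMatrix, meta: pd.DataFrame, panels: dict[str, list[str]],
    source_col: str = "source",
) -> pd.DataFrame:
    """Median TPM per (panel, gene, source group); absent genes are flagged."""
    tpm.require_space("TPM")
    meta = meta.loc[list(tpm.samples)]
    rows = []
    for panel, genes in panels.items():
        for gene in genes:
            gene = str(gene).upper()
            present = gene in tpm.genes
            for group in pd.unique(meta[source_col]):
                cols = meta.index[meta[source_col] == group]
                rows.append(
                    {
                        "panel": panel,
                        "gene": gene,
                        "group": group,
                        "median_tpm": float(tpm.values.loc[gene, cols].median()) if present else np.nan,
                        "missing": not present,
                    }
                )
    return pd.DataFrame(rows)
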