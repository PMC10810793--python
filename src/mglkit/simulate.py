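"""Synthetic bulk and single-cell datasets with planted, recorded structure.

The generators emulate the statistical structure the downstream analyses
assume rather than any particular real dataset:

* bulk expression is log-normal on the log2 scale — a per-gene baseline plus
  a per-source mean shift on a chosen gene subset, a per-batch additive
  offset, and Gaussian residual noise — exponentiated to a TPM-scale matrix;
* single-cell counts are negative binomial with planted cluster markers,
  a treatment fold change confined to chosen clusters, and cells forced to
  fail quality control (low library or high mitochondrial load);
* pseudobulk replicate counts share the single-cell config's planted truth,
  so the bulk and per-cluster response arms can be cross-referenced.

Every generator is deterministic given its config and seed; all randomness
derives from one top-level seed through fixed sub-streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import ExpressionMatrix, new_rng, validate_sample_table
from . import io as mio

# fractions of the gene panel given ribosomal-/mitochondrial-style names so
# the literal prefix filters are exercised on bulk data
_BULK_MT_FRACTION = 0.02
_BULK_RP_FRACTION = 0.03


@dataclass(frozen=True)
class BulkSimConfig:
    """Configuration of the bulk expression generator.

    All effect sizes are on the log2 scale.  ``source_effect_size`` is the
    mean shift between consecutive source groups on the planted gene subset;
    ``qc_fail_fraction`` of samples receive sequencing-depth metadata below
    the 10M-read QC threshold.
    """

    n_sources: int = 2
    samples_per_source: int = 10
    n_genes: int = 2000
    n_batches: int = 2
    source_effect_genes: float = 0.05
    source_effect_size: float = 2.0
    batch_effect_sd: float = 0.5
    noise_sd: float = 1.0
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sources", "samples_per_source", "n_genes", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.samples_per_source < 2:
            raise ValueError("samples_per_source must be >= 2 (separability needs >=2 per group)")
        for name in ("source_effect_genes", "qc_fail_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("batch_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.source_effect_size) > 0 and self.source_effect_genes > 0:
            n_eligible = self.n_genes - self._n_named_prefix_genes()
            if round(self.source_effect_genes * self.n_genes) > n_eligible:
                raise ValueError("source_effect_genes exceeds the eligible (non RP/MT) gene pool")

    def _n_named_prefix_genes(self) -> int:
        return math.ceil(_BULK_MT_FRACTION * self.n_genes) + math.ceil(
            _BULK_RP_FRACTION * self.n_genes
        )


def _bulk_gene_names(n_genes: int) -> list[str]:
    n_mt = math.ceil(_BULK_MT_FRACTION * n_genes)
    n_rp = math.ceil(_BULK_RP_FRACTION * n_genes)
    names = [f"MT-SYN{i:04d}" for i in range(n_mt)]
    names += [f"RPSYN{i:04d}" for i in range(n_rp)]
    names += [f"G{i:05d}" for i in range(n_genes - n_mt - n_rp)]
    return names


def generate_bulk_dataset(
    config: BulkSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Generate a TPM-scale matrix, its sample table, and the planted truth.

    Sources are labeled ``source_1 .. source_K``; source ``k`` carries a mean
    shift of ``(k-1) * source_effect_size * sign_g`` on the planted genes
    (signs alternate by gene), so consecutive source pairs differ by exactly
    the configured effect size in expectation.
    """
    cfg = config
    rng_base = new_rng(cfg.seed, stream=0)
    rng_batch = new_rng(cfg.seed, stream=1)
    rng_noise = new_rng(cfg.seed, stream=2)
    rng_qc = new_rng(cfg.seed, stream=3)

    genes = _bulk_gene_names(cfg.n_genes)
    n_samples = cfg.n_sources * cfg.samples_per_source
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    sources = np.repeat([f"source_{k + 1}" for k in range(cfg.n_sources)], cfg.samples_per_source)
    # balanced round-robin batch assignment within each source
    batches = np.array(
        [f"batch_{(i % cfg.n_batches) + 1}" for i in range(cfg.samples_per_source)]
        * cfg.n_sources
    )

    baseline = rng_base.normal(loc=3.0, scale=2.0, size=cfg.n_genes)

    # planted source-effect genes: chosen from well-expressed, non-prefix genes
    # so they survive the RP/MT and median-TPM filters
    n_shift = round(cfg.source_effect_genes * cfg.n_genes)
    n_named = cfg._n_named_prefix_genes()
    eligible = np.arange(n_named, cfg.n_genes)
    eligible = eligible[baseline[eligible] >= 1.0]
    if n_shift > len(eligible):
        n_shift = len(eligible)
    shifted_idx = np.sort(rng_base.choice(eligible, size=n_shift, replace=False))
    signs = np.where(np.arange(n_shift) % 2 == 0, 1.0, -1.0)

    # per-source x gene shift matrix on the log2 scale
    shift = np.zeros((cfg.n_sources, cfg.n_genes))
    for k in range(cfg.n_sources):
        shift[k, shifted_idx] = k * cfg.source_effect_size * signs

    # per-batch x gene additive offsets
    batch_names = [f"batch_{b + 1}" for b in range(cfg.n_batches)]
    batch_offsets = rng_batch.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_batches, cfg.n_genes))

    source_idx = np.repeat(np.arange(cfg.n_sources), cfg.samples_per_source)
    batch_idx = np.array([batch_names.index(b) for b in batches])
    log2_expr = (
        baseline[None, :]
        + shift[source_idx, :]
        + batch_offsets[batch_idx, :]
        + rng_noise.normal(0.0, cfg.noise_sd, size=(n_samples, cfg.n_genes))
    )
    tpm = pd.DataFrame(np.power(2.0, log2_expr).T, index=genes, columns=sample_ids)

    # QC metadata; failing samples get depths below the 10M-read threshold
    n_fail = round(cfg.qc_fail_fraction * n_samples)
    fail_mask = np.zeros(n_samples, dtype=bool)
    if n_fail:
        fail_mask[rng_qc.choice(n_samples, size=n_fail, replace=False)] = True
    total_reads = np.where(
        fail_mask,
        rng_qc.integers(1_000_000, 9_990_000, size=n_samples),
        rng_qc.integers(12_000_000, 50_000_000, size=n_samples),
    )
    meta = pd.DataFrame(
        {
            "source": sources,
            "batch": batches,
            "total_reads": total_reads,
            "alignment_rate": rng_qc.uniform(0.70, 0.95, size=n_samples).round(4),
            "duplicate_fraction": rng_qc.uniform(0.05, 0.35, size=n_samples).round(4),
            "paired_end": True,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = {
        "shifted_genes": [genes[i] for i in shifted_idx],
        "shift_signs": {genes[i]: float(s) for i, s in zip(shifted_idx, signs)},
        "source_effect_size": cfg.source_effect_size,
        "per_source_shift": {
            f"source_{k + 1}": {genes[i]: float(shift[k, i]) for i in shifted_idx}
            for k in range(cfg.n_sources)
        },
        "batch_offsets": {b: batch_offsets[j].tolist() for j, b in enumerate(batch_names)},
        "qc_fail_samples": [s for s, f in zip(sample_ids, fail_mask) if f],
    }
    return ExpressionMatrix(tpm, space="TPM"), validate_sample_table(meta), truth


@dataclass(frozen=True)
class ScSimConfig:
    """Configuration of the single-cell count generator.

    Counts are negative binomial with variance ``mu + dispersion * mu**2``.
    ``treatment_lfc`` (log2) is planted on ``n_response_genes`` genes in the
    treated condition, confined to ``responsive_clusters`` (1-based labels).
    Response genes get a ``response_enrichment``-fold elevated baseline in
    responsive clusters in both conditions, mirroring stimulus-response
    programs concentrated in the responding subpopulation.  Per-gene mean
    scales are set high enough that healthy cells detect well over 1500 of
    the (deliberately small) gene panel, keeping the absolute QC thresholds
    meaningful at reduced dimension.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 150
    n_genes: int = 2000
    baseline_mean: float = 5.0
    dispersion: float = 0.3
    responsive_clusters: frozenset[int] = field(default_factory=lambda: frozenset({4}))
    treatment_lfc: float = 1.5
    n_response_genes: int = 100
    response_enrichment: float = 4.0
    marker_genes_per_cluster: int = 40
    marker_log2fc: float = 2.0
    mito_gene_fraction: float = 0.05
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1 or self.n_genes < 1:
            raise ValueError("counts must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.mito_gene_fraction <= 1.0 or not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        bad = set(self.responsive_clusters) - set(range(1, self.n_clusters + 1))
        if bad:
            raise ValueError(f"responsive_clusters outside 1..{self.n_clusters}: {sorted(bad)}")
        if self.treatment_lfc != 0 and self.n_response_genes == 0:
            raise ValueError("nonzero treatment_lfc requires a non-empty response gene set")


def _sc_gene_names(cfg: ScSimConfig) -> list[str]:
    n_mt = math.ceil(cfg.mito_gene_fraction * cfg.n_genes)
    return [f"MT-SYN{i:04d}" for i in range(n_mt)] + [
        f"G{i:05d}" for i in range(cfg.n_genes - n_mt)
    ]


def _sc_cluster_means(cfg: ScSimConfig, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Per-(cluster, gene) mean matrix for the control condition + truth sets."""
    genes = _sc_gene_names(cfg)
    n_mt = math.ceil(cfg.mito_gene_fraction * cfg.n_genes)
    base = np.exp(rng.normal(np.log(cfg.baseline_mean), 0.6, size=cfg.n_genes))

    non_mito = np.arange(n_mt, cfg.n_genes)
    perm = rng.permutation(non_mito)
    marker_sets: dict[int, np.ndarray] = {}
    pos = 0
    for c in range(1, cfg.n_clusters + 1):
        take = min(cfg.marker_genes_per_cluster, max(0, len(perm) - pos))
        marker_sets[c] = np.sort(perm[pos : pos + take])
        pos += take
    n_resp = min(cfg.n_response_genes, max(0, len(perm) - pos))
    response_idx = np.sort(perm[pos : pos + n_resp])

    means = np.tile(base, (cfg.n_clusters, 1))
    for c, idx in marker_sets.items():
        means[c - 1, idx] *= 2.0**cfg.marker_log2fc
    for c in cfg.responsive_clusters:
        means[c - 1, response_idx] *= cfg.response_enrichment
    truth = {
        "genes": genes,
        "marker_genes": {f"C{c}": [genes[i] for i in idx] for c, idx in marker_sets.items()},
        "response_genes": [genes[i] for i in response_idx],
        "response_idx": response_idx,
        "responsive_clusters": sorted(f"C{c}" for c in cfg.responsive_clusters),
    }
    return means, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int32)


def _assemble_adata(
    counts: np.ndarray, genes: list[str], clusters: np.ndarray, condition: str, prefix: str,
    forced_fail: np.ndarray,
) -> ad.AnnData:
    n_mt = sum(1 for g in genes if g.startswith("MT-"))
    total = counts.sum(axis=1)
    mito = counts[:, :n_mt].sum(axis=1)
    obs = pd.DataFrame(
        {
            "cluster": [f"C{c}" for c in clusters],
            "condition": condition,
            "n_genes_detected": (counts > 0).sum(axis=1),
            "total_counts": total,
            "mito_fraction": np.divide(mito, np.maximum(total, 1)),
            "qc_fail_forced": forced_fail,
        },
        index=pd.Index([f"{prefix}{i:05d}" for i in range(counts.shape[0])], name="barcode"),
    )
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=pd.Index(genes)))


def generate_singlecell_dataset(
    config: ScSimConfig,
    control_name: str = "DMSO",
    treated_name: str = "treated",
) -> tuple[ad.AnnData, ad.AnnData, dict]:
    """Generate control and treated single-cell count datasets plus truth.

    Exactly ``round(qc_fail_fraction * n_cells)`` cells per condition are
    forced to fail QC, alternating between a collapsed library (few genes
    detected) and an inflated mitochondrial load.
    """
    cfg = config
    rng_struct = new_rng(cfg.seed, stream=10)
    rng_control = new_rng(cfg.seed, stream=11)
    rng_treated = new_rng(cfg.seed, stream=12)
    rng_qc = new_rng(cfg.seed, stream=13)

    means, truth = _sc_cluster_means(cfg, rng_struct)
    genes = truth["genes"]
    n_mt = sum(1 for g in genes if g.startswith("MT-"))
    n_cells = cfg.n_clusters * cfg.cells_per_cluster
    clusters = np.repeat(np.arange(1, cfg.n_clusters + 1), cfg.cells_per_cluster)

    treated_means = means.copy()
    for c in cfg.responsive_clusters:
        treated_means[c - 1, truth["response_idx"]] *= 2.0**cfg.treatment_lfc

    out = []
    n_fail = round(cfg.qc_fail_fraction * n_cells)
    for cond, mean_matrix, rng in (
        (control_name, means, rng_control),
        (treated_name, treated_means, rng_treated),
    ):
        cell_means = mean_matrix[clusters - 1, :].astype(float)
        forced = np.zeros(n_cells, dtype=bool)
        if n_fail:
            fail_cells = np.sort(rng_qc.choice(n_cells, size=n_fail, replace=False))
            forced[fail_cells] = True
            for j, cell in enumerate(fail_cells):
                if j % 2 == 0:  # collapsed library -> genes detected <= 1500
                    cell_means[cell, :] *= 0.02
                else:  # inflated mitochondrial load -> mito fraction >= 0.20
                    cell_means[cell, :n_mt] *= 30.0
        counts = _nb_draw(rng, cell_means, cfg.dispersion)
        out.append(
            _assemble_adata(counts, genes, clusters, cond, f"{cond}_", forced)
        )

    truth = dict(truth)
    truth.pop("response_idx")
    truth["qc_fail_barcodes"] = {
        a.obs["condition"].iloc[0] if len(a.obs) else "": a.obs_names[a.obs["qc_fail_forced"]].tolist()
        for a in out
    }
    truth["treatment_lfc"] = cfg.treatment_lfc
    return out[0], out[1], truth


def generate_bulk_response_counts(
    config: ScSimConfig,
    n_reps: int = 8,
    depth_factor: float = 30.0,
    bulk_dispersion: float = 0.05,
    control_name: str = "DMSO",
    treated_name: str = "treated",
) -> tuple[pd.DataFrame, ExpressionMatrix, pd.Series, dict]:
    """Pseudobulk replicate counts matched to a single-cell response config.

    Each replicate's per-gene mean is the equal-weight mixture of the
    cluster means from ``config`` (times ``depth_factor``), so a treatment
    response confined to a subset of clusters appears in bulk diluted by the
    clusters' mixture weights — the regime the bulk→cluster deconvolution is
    designed for.

    The default of 8 replicates per condition reflects the granularity of a
    rank-based test: with n vs n replicates the smallest attainable two-sided
    Wilcoxon p is 2/C(2n, n), and the replicate count must leave that minimum
    clear of the multiple-testing threshold across the gene panel.

    Returns the counts matrix (genes x samples), a CPM-scale abundance
    matrix standing in for TPM, a sample→condition series, and the truth
    record with the expected bulk log2 fold change per response gene.
    """
    cfg = config
    rng_struct = new_rng(cfg.seed, stream=10)  # same structure stream as the sc generator
    rng_counts = new_rng(cfg.seed, stream=20)
    means, truth = _sc_cluster_means(cfg, rng_struct)
    genes = truth["genes"]
    treated_means = means.copy()
    for c in cfg.responsive_clusters:
        treated_means[c - 1, truth["response_idx"]] *= 2.0**cfg.treatment_lfc

    mix_control = means.mean(axis=0) * depth_factor
    mix_treated = treated_means.mean(axis=0) * depth_factor

    cols, conds, mats = [], [], []
    for cond, mu in ((control_name, mix_control), (treated_name, mix_treated)):
        for r in range(n_reps):
            cols.append(f"{cond}_rep{r + 1}")
            conds.append(cond)
            mats.append(_nb_draw(rng_counts, mu, bulk_dispersion))
    counts = pd.DataFrame(np.column_stack(mats), index=genes, columns=cols)
    cpm = counts / counts.sum(axis=0) * 1e6
    conditions = pd.Series(conds, index=cols, name="condition")
    expected_lfc = np.log2(mix_treated[truth["response_idx"]] / mix_control[truth["response_idx"]])
    truth_out = {
        "response_genes": truth["response_genes"],
        "expected_bulk_log2fc": {
            g: float(l) for g, l in zip(truth["response_genes"], expected_lfc)
        },
        "responsive_clusters": truth["responsive_clusters"],
    }
    return counts, ExpressionMatrix(cpm, space="TPM"), conditions, truth_out


def generate_marker_panels(
    n_panels: int,
    genes_per_panel: int,
    gene_universe: list[str] | tuple[str, ...] | set[str],
    seed: int = 0,
) -> dict[str, list[str]]:
    """Sample named gene panels (without replacement within a panel)."""
    universe = sorted(str(g).upper() for g in gene_universe)
    if not universe:
        raise ValueError("gene universe is empty")
    if genes_per_panel > len(universe):
        raise ValueError("genes_per_panel exceeds the gene universe size")
    rng = new_rng(seed, stream=30)
    return {
        f"panel_{i + 1}": sorted(rng.choice(universe, size=genes_per_panel, replace=False))
        for i in range(n_panels)
    }


def write_bulk_dataset(
    matrix: ExpressionMatrix, meta: pd.DataFrame, truth: dict, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_expression_tsv(matrix, out / "bulk_tpm.tsv")
    mio.write_sample_table(meta, out / "bulk_samples.tsv")
    mio.write_json(truth, out / "bulk_truth.json")


def write_singlecell_dataset(
    control: ad.AnnData, treated: ad.AnnData, truth: dict, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_cell_counts(control, out, prefix="control_")
    mio.write_cell_counts(treated, out, prefix="treated_")
    mio.write_json(truth, out / "sc_truth.json")
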