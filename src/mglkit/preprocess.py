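"""Uniform bulk preprocessing: sample QC, gene filters, transform, scaling,
and a location-scale batch adjustment.

All threshold rules are applied with literal strict inequalities — a sample
with exactly 10,000,000 reads or a gene with median TPM exactly 1 survives.
The canonical stage order is: sample QC -> RP/MT gene removal -> (branch a:
median-TPM filter -> log2(TPM + 0.01) -> per-gene z-scoring for PCA;
branch b: raw TPM retained for marker-panel medians).

The transform-shaped steps are scikit-learn style estimators operating on
sample x gene arrays; the module-level functions wrap them for the
gene x sample :class:`~mglkit.datatypes.ExpressionMatrix` convention.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import ExpressionMatrix, validate_sample_table

logger = logging.getLogger(__name__)

MIN_TOTAL_READS = 10_000_000
MIN_ALIGNMENT_RATE = 0.60
MAX_DUPLICATE_FRACTION = 0.50
LOG_PSEUDO_TPM = 0.01
MIN_MEDIAN_TPM = 1.0


# ---------------------------------------------------------------------------
# sample- and gene-level filters
# ---------------------------------------------------------------------------

def filter_samples_by_qc(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    apply_duplicate_rule: bool = True,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Drop samples failing any sequencing QC rule.

    A sample is removed if total reads < 10,000,000, alignment rate < 60%,
    or — for paired-end samples only — duplicate-read fraction > 50%.  The
    duplicate rule can be disabled (``apply_duplicate_rule=False``) for runs
    where it should not apply to in-house libraries.

    Returns the filtered matrix, filtered metadata, and a removal log with
    one row per (sample, rule-that-fired).
    """
    meta = validate_sample_table(meta)
    missing = [s for s in matrix.samples if s not in meta.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    meta = meta.loc[list(matrix.samples)]

    records = []
    for sid, row in meta.iterrows():
        if row["total_reads"] < MIN_TOTAL_READS:
            records.append((sid, "total_reads_lt_10M"))
        if row["alignment_rate"] < MIN_ALIGNMENT_RATE:
            records.append((sid, "alignment_rate_lt_60pct"))
        if (
            apply_duplicate_rule
            and row["paired_end"]
            and row["duplicate_fraction"] > MAX_DUPLICATE_FRACTION
        ):
            records.append((sid, "duplicate_fraction_gt_50pct_paired"))
    removal_log = pd.DataFrame(records, columns=["sample_id", "rule"])
    removed = set(removal_log["sample_id"])
    keep = [s for s in matrix.samples if s not in removed]
    return matrix.subset_samples(keep), meta.loc[keep], removal_log


def remove_rp_mt_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop ribosomal/mitochondrial genes: any symbol starting "RP" or "MT".

    The rule is the literal uppercase prefix match, so e.g. MTOR and RPA1
    are also removed.  Survivor order is preserved.
    """
    keep = ~(matrix.genes.str.startswith("RP") | matrix.genes.str.startswith("MT"))
    return matrix.with_values(matrix.values.loc[keep])


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 0.01) variance-stabilizing transform."""
    matrix.require_space("TPM")
    vals = matrix.values.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative TPM values")
    return matrix.with_values(np.log2(matrix.values + LOG_PSEUDO_TPM), space="log2TPM")


def filter_low_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop lowly expressed genes with median TPM (across samples) < 1."""
    matrix.require_space("TPM")
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    medians = matrix.values.median(axis=1)
    return matrix.with_values(matrix.values.loc[medians >= MIN_MEDIAN_TPM])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class GeneScaler(TransformerMixin, BaseEstimator):
    """Per-feature z-scoring with the n-1 (sample) standard deviation.

    Zero-variance features cannot be scaled and are dropped at transform
    time with a warning (``dropped_features_`` records which).  Operates on
    sample x gene arrays, the scikit-learn orientation.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.keep_mask_ = self.scale_ > 0
        self.n_features_in_ = X.shape[1]
        self.dropped_features_ = np.flatnonzero(~self.keep_mask_)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X)
        if len(self.dropped_features_):
            warnings.warn(
                f"dropping {len(self.dropped_features_)} zero-variance gene(s)",
                UserWarning,
                stacklevel=2,
            )
        Xs = (X[:, self.keep_mask_] - self.mean_[self.keep_mask_]) / self.scale_[self.keep_mask_]
        return Xs


class BatchAdjuster(TransformerMixin, BaseEstimator):
    """Location-scale batch adjustment with grand-moment restoration.

    Per feature: each batch's values are standardized by the batch mean and
    (n-1) SD, then rescaled to the feature's grand mean and pooled SD
    (classic pooled variance, weighted by batch degrees of freedom).  After
    adjustment every batch has the same per-feature mean and the feature's
    grand mean and pooled variance are preserved.  This is a deliberately
    simple alternative to empirical-Bayes batch correction: batch removal is
    treated as preprocessing, not inference.
    """

    def fit(self, X, y=None, *, batch=None):
        X = check_array(X)
        if batch is None:
            raise ValueError("batch labels are required")
        batch = np.asarray(batch)
        if batch.shape[0] != X.shape[0]:
            raise ValueError("batch labels must match the number of samples")
        self.batches_ = [str(b) for b in pd.unique(batch)]
        counts = {b: int((batch == b).sum()) for b in self.batches_}
        singletons = [b for b, n in counts.items() if n < 2]
        if singletons:
            raise ValueError(
                f"batch(es) with a single sample: {singletons}; merge them into "
                "another batch or exclude those samples before adjustment"
            )
        self.grand_mean_ = X.mean(axis=0)
        self.batch_mean_ = {}
        self.batch_scale_ = {}
        sq = np.zeros(X.shape[1])
        dof = 0
        for b in self.batches_:
            Xb = X[batch == b]
            self.batch_mean_[b] = Xb.mean(axis=0)
            self.batch_scale_[b] = Xb.std(axis=0, ddof=1)
            sq += (Xb.shape[0] - 1) * self.batch_scale_[b] ** 2
            dof += Xb.shape[0] - 1
        self.pooled_scale_ = np.sqrt(sq / dof)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, batch=None):
        check_is_fitted(self, "grand_mean_")
        X = check_array(X)
        if batch is None:
            raise ValueError("batch labels are required")
        batch = np.asarray(batch)
        out = np.empty_like(X, dtype=float)
        for b in self.batches_:
            mask = batch == b
            if not mask.any():
                continue
            centered = X[mask] - self.batch_mean_[b]
            scale = self.batch_scale_[b]
            z = np.where(scale > 0, centered / np.where(scale > 0, scale, 1.0), 0.0)
            out[mask] = z * self.pooled_scale_ + self.grand_mean_
        unknown = set(str(b) for b in pd.unique(batch)) - set(self.batches_)
        if unknown:
            raise ValueError(f"unseen batch label(s): {sorted(unknown)}")
        return out

    def fit_transform(self, X, y=None, *, batch=None):
        return self.fit(X, batch=batch).transform(X, batch=batch)


# ---------------------------------------------------------------------------
# matrix-level wrappers
# ---------------------------------------------------------------------------

def scale_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene across samples (mean 0, SD 1 with n-1 denominator).

    Zero-variance genes are dropped with a warning.
    """
    matrix.require_space("log2TPM", "scaled")
    scaler = GeneScaler().fit(matrix.values.T.to_numpy())
    scaled = scaler.transform(matrix.values.T.to_numpy())
    genes = matrix.genes[scaler.keep_mask_]
    return matrix.with_values(
        pd.DataFrame(scaled.T, index=genes, columns=matrix.samples), space="scaled"
    )


def batch_adjust(matrix: ExpressionMatrix, meta: pd.DataFrame) -> ExpressionMatrix:
    """Equalize per-batch means/SDs per gene, preserving grand moments."""
    matrix.require_space("log2TPM", "scaled")
    meta = validate_sample_table(meta)
    batch = meta.loc[list(matrix.samples), "batch"].to_numpy()
    adj = BatchAdjuster().fit_transform(matrix.values.T.to_numpy(), batch=batch)
    return matrix.with_values(
        pd.DataFrame(adj.T, index=matrix.genes, columns=matrix.samples), space=matrix.space
    )


def preprocess_bulk(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    apply_duplicate_rule: bool = True,
    adjust_batches: bool = True,
) -> dict:
    """Run the full bulk preprocessing chain.

    Returns a dict with the QC'd TPM matrix (``tpm``, for marker-panel
    medians), the analysis-ready log2 matrix (``log2``, median-filtered and
    batch-adjusted), the scaled matrix for PCA (``scaled``), filtered
    metadata (``meta``), and the sample removal log (``removal_log``).
    """
    qc_matrix, meta_kept, removal_log = filter_samples_by_qc(
        matrix, meta, apply_duplicate_rule=apply_duplicate_rule
    )
    qc_matrix = remove_rp_mt_genes(qc_matrix)
    expressed = filter_low_expression(qc_matrix)
    logged = log_transform(expressed)
    if adjust_batches and meta_kept["batch"].nunique() > 1:
        logged = batch_adjust(logged, meta_kept)
    scaled = scale_genes(logged)
    return {
        "tpm": qc_matrix,
        "log2": logged,
        "scaled": scaled,
        "meta": meta_kept,
        "removal_log": removal_log,
    }
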