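"""Core in-memory containers shared by all analysis stages.

Bulk expression lives in :class:`ExpressionMatrix`, a thin wrapper around a
gene x sample :class:`pandas.DataFrame` that carries a ``space`` tag so stages
can refuse inputs on the wrong scale (TPM vs log2-transformed vs per-gene
z-scored).  Single-cell counts use :class:`anndata.AnnData` (cells as ``obs``,
genes as ``var``) throughout; see :mod:`mglkit.response`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: allowed values of ``ExpressionMatrix.space``
SPACES = ("TPM", "log2TPM", "scaled", "counts", "normalized")

#: columns a sample-metadata table must provide
SAMPLE_TABLE_COLUMNS = (
    "source",
    "batch",
    "total_reads",
    "alignment_rate",
    "duplicate_fraction",
    "paired_end",
)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with an explicit value-space tag.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and sample identifiers as
        columns.  Gene symbols are uppercased on construction so the literal
        "RP"/"MT" prefix rules behave case-insensitively on lowercase input.
    space
        One of ``TPM``, ``log2TPM``, ``scaled``, ``counts``, ``normalized``.
    """

    values: pd.DataFrame
    space: str = "TPM"

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown space {self.space!r}; expected one of {SPACES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if self.space in ("TPM", "counts") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.space} matrix must be non-negative")

    # -- convenience views ------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, space: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, space=space or self.space)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return self.with_values(self.values.loc[:, ids])

    def require_space(self, *spaces: str) -> None:
        if self.space not in spaces:
            raise ValueError(
                f"operation requires matrix in {'/'.join(spaces)} space, got {self.space!r}"
            )


def validate_sample_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a per-sample metadata table.

    The table must be indexed by (or contain a ``sample_id`` column of)
    unique sample identifiers and provide the QC covariates used by sample
    filtering: source group, batch of origin, total reads, alignment rate,
    duplicate-read fraction and a paired-end flag.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample_id rows in sample table")
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    for col in ("alignment_rate", "duplicate_fraction"):
        vals = meta[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"{col} must lie in [0, 1]")
    meta["paired_end"] = meta["paired_end"].astype(bool)
    meta["total_reads"] = meta["total_reads"].astype(np.int64)
    return meta


@dataclass
class PCAResult:
    """Result of a PCA over samples.

    ``scores`` holds per-sample projections (samples x PCs), ``varexp`` the
    fraction of total variance captured by each PC, and ``loadings`` the
    per-gene weights (genes x PCs).
    """

    scores: pd.DataFrame
    varexp: np.ndarray
    loadings: pd.DataFrame
    n_pcs: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_pcs == 0:
            self.n_pcs = self.scores.shape[1]
        if np.any(self.varexp < -1e-12) or np.any(self.varexp > 1 + 1e-12):
            raise ValueError("variance-explained fractions must lie in [0, 1]")


@dataclass
class MeaningfulPCReport:
    """Permutation-based count of PCs explaining more variance than noise."""

    threshold: float
    perm_top_varexp: np.ndarray
    n_meaningful: int
    varexp_observed: np.ndarray

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "n_meaningful": int(self.n_meaningful),
            "perm_top_varexp": [float(v) for v in self.perm_top_varexp],
            "varexp_observed": [float(v) for v in self.varexp_observed],
        }


@dataclass
class SeparabilityResult:
    """Separability of one source pair on its meaningful-PC scores."""

    source_pair: tuple[str, str]
    n_meaningful: int
    silhouette: float | None
    silhouette_p: float | None
    sigclust_score: float | None
    sigclust_p: float | None
    cluster_index: float | None
    n_perm: int
    no_signal: bool = False

    def to_dict(self) -> dict:
        return {
            "source_a": self.source_pair[0],
            "source_b": self.source_pair[1],
            "n_meaningful": int(self.n_meaningful),
            "silhouette": None if self.silhouette is None else float(self.silhouette),
            "silhouette_p": None if self.silhouette_p is None else float(self.silhouette_p),
            "sigclust_score": None if self.sigclust_score is None else float(self.sigclust_score),
            "sigclust_p": None if self.sigclust_p is None else float(self.sigclust_p),
            "cluster_index": None if self.cluster_index is None else float(self.cluster_index),
            "n_perm": int(self.n_perm),
            "no_signal": bool(self.no_signal),
        }


def new_rng(seed: int | np.random.Generator | None, stream: int = 0) -> np.random.Generator:
    """Derive a reproducible generator from a top-level seed.

    Sub-streams are derived by a fixed offset scheme so each module can be
    re-run independently with identical randomness.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))
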