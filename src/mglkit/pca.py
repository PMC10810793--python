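"""PCA over scaled expression, PC-space distances, and permutation-based
detection of meaningful components.

A "meaningful" PC is one whose variance-explained fraction exceeds a noise
threshold derived from 100 datasets in which every gene's values are
independently shuffled across samples (destroying gene-gene correlation but
preserving each gene's marginal): threshold = mean + 2 SD of the top-PC
variance explained over the permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import ExpressionMatrix, MeaningfulPCReport, PCAResult, new_rng


class ExpressionPCA(TransformerMixin, BaseEstimator):
    """Centered-SVD principal components with a deterministic sign convention.

    Each component's score vector is flipped so its largest-magnitude entry
    is positive, making results reproducible across BLAS backends.  Input is
    sample x gene (scikit-learn orientation); per-gene scaling is expected
    to have been done upstream.

    Attributes (after fit): ``scores_`` (n_samples x n_pcs),
    ``explained_variance_ratio_``, ``components_`` (n_pcs x n_genes).
    """

    def __init__(self, n_pcs: int | None = None):
        self.n_pcs = n_pcs

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        n, p = X.shape
        max_pcs = min(n - 1, p)
        k = self.n_pcs if self.n_pcs is not None else max_pcs
        if k > max_pcs:
            warnings.warn(
                f"n_pcs={k} exceeds min(n_samples-1, n_genes)={max_pcs}; clipping",
                UserWarning,
                stacklevel=2,
            )
            k = max_pcs
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-|score| entry of each PC made positive
        scores = U * S
        for j in range(scores.shape[1]):
            i = np.argmax(np.abs(scores[:, j]))
            if scores[i, j] < 0:
                scores[:, j] *= -1
                Vt[j] *= -1
        var = S**2
        total = var.sum()
        self.n_components_ = k
        self.scores_ = scores[:, :k]
        self.explained_variance_ratio_ = (var / total if total > 0 else var)[:k]
        self.components_ = Vt[:k]
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X)
        return (X - self.mean_) @ self.components_.T


def run_pca(matrix: ExpressionMatrix, n_pcs: int | None = None) -> PCAResult:
    """PCA of a scaled gene x sample matrix; samples are the observations."""
    matrix.require_space("scaled")
    est = ExpressionPCA(n_pcs=n_pcs).fit(matrix.values.T.to_numpy())
    pc_names = [f"PC{i + 1}" for i in range(est.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(est.scores_, index=matrix.samples, columns=pc_names),
        varexp=est.explained_variance_ratio_,
        loadings=pd.DataFrame(est.components_.T, index=matrix.genes, columns=pc_names),
    )


def pc_distance(
    pca: PCAResult,
    meta: pd.DataFrame,
    reference_source: str,
    other_source: str,
    source_col: str = "source",
) -> np.ndarray:
    """All cross-group Euclidean distances on (PC1, PC2) score coordinates."""
    meta = meta.loc[list(pca.scores.index)]
    for src in (reference_source, other_source):
        if not (meta[source_col] == src).any():
            raise KeyError(f"unknown source label {src!r}")
    a = pca.scores.loc[meta[source_col] == reference_source, ["PC1", "PC2"]].to_numpy()
    b = pca.scores.loc[meta[source_col] == other_source, ["PC1", "PC2"]].to_numpy()
    return cdist(a, b).ravel()


def _top_varexp(X: np.ndarray) -> float:
    """Variance-explained fraction of the top PC of a gene x sample matrix.

    Assumes rows (genes) are centered across samples, which gene scaling
    guarantees and gene-wise permutation preserves.  Uses the n x n dual
    Gram matrix, cheap when samples are few.
    """
    gram = X.T @ X
    ev = np.linalg.eigvalsh(gram)
    total = ev.sum()
    return float(ev[-1] / total) if total > 0 else 0.0


def meaningful_pcs(
    matrix: ExpressionMatrix,
    n_perm: int = 100,
    rng: int | np.random.Generator | None = 0,
    mode: str = "contiguous",
) -> MeaningfulPCReport:
    """Count PCs whose variance explained exceeds the permutation threshold.

    ``mode="contiguous"`` (default) counts the leading run of PCs above the
    threshold — PCs are variance-ordered, so the first sub-threshold PC ends
    the signal block.  ``mode="any"`` counts every PC above the threshold.
    """
    matrix.require_space("scaled")
    if matrix.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if n_perm < 10:
        raise ValueError("n_perm < 10 gives an unstable threshold")
    if mode not in ("contiguous", "any"):
        raise ValueError("mode must be 'contiguous' or 'any'")
    rng = new_rng(rng, stream=40)

    X = matrix.values.to_numpy()
    # observed varexp spectrum (gene-centered by construction of scaling)
    Xc = X - X.mean(axis=1, keepdims=True)
    ev = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
    total = ev.sum()
    varexp = ev / total if total > 0 else ev

    perm_top = np.empty(n_perm)
    for i in range(n_perm):
        # independently permute each gene across samples, in fixed gene order
        order = np.argsort(rng.random(X.shape), axis=1)
        Xp = np.take_along_axis(Xc, order, axis=1)
        perm_top[i] = _top_varexp(Xp)
    threshold = float(perm_top.mean() + 2.0 * perm_top.std(ddof=1))

    above = varexp > threshold
    if mode == "contiguous":
        n_meaningful = int(np.argmin(above)) if not above.all() else int(above.size)
    else:
        n_meaningful = int(above.sum())
    return MeaningfulPCReport(
        threshold=threshold,
        perm_top_varexp=perm_top,
        n_meaningful=n_meaningful,
        varexp_observed=np.asarray(varexp),
    )
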