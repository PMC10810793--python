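"""Pairwise cell-source separability on meaningful-PC scores.

Two separability statistics are computed on the sample scores:

* **Silhouette width** — mean over samples of (b - a)/max(a, b), where a is
  the mean distance to the sample's own source and b to the other source;
  higher means better separated.
* **SigClust score** — the SigClust p-value: the observed 2-group cluster
  index (within-group sum of squares of the labeled partition divided by
  total sum of squares about the grand mean) compared against cluster
  indices of the best 2-means split on Gaussian null datasets whose diagonal
  covariance spectrum is the sample spectrum floored at a background noise
  variance (hard-threshold variant); lower means more separable.

Empirical significance for both comes from shuffling the source labels over
the fixed score matrix and recomputing each score; p is the fraction of
permutations scoring more separable than observed (strict inequalities, so
p = 0 is representable; an add-one-corrected mode is available).  The
Gaussian null CI distribution depends only on the point cloud, never the
labels, so it is simulated once and reused across permutations.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import ExpressionMatrix, SeparabilityResult, new_rng
from .pca import meaningful_pcs, run_pca
from .preprocess import scale_genes

logger = logging.getLogger(__name__)

_MAD_TO_SD = 1.4826022185056018  # 1 / Phi^{-1}(3/4): MAD -> SD for a Gaussian


def _as_points(points) -> np.ndarray:
    """Coerce to an (n_points, n_dims) float array; 1-D input = 1-D points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise ValueError("points must be 1-D or 2-D")
    return pts


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def silhouette_width(points: np.ndarray, labels: Sequence) -> float:
    """Mean silhouette width for a two-group labeling (Euclidean metric)."""
    points = _as_points(points)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 label values, got {len(uniq)}")
    mask = labels == uniq[0]
    n0, n1 = int(mask.sum()), int((~mask).sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs >= 2 members (intra-group distance undefined)")
    D = cdist(points, points)
    s = np.empty(points.shape[0])
    for i in range(points.shape[0]):
        own = mask if mask[i] else ~mask
        a = D[i, own].sum() / (own.sum() - 1)  # excludes self (D[i,i] = 0)
        b = D[i, ~own].mean()
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


# ---------------------------------------------------------------------------
# 2-means cluster index
# ---------------------------------------------------------------------------

def _within_ss(points: np.ndarray, assign: np.ndarray) -> float:
    ss = 0.0
    for g in (0, 1):
        pts = points[assign == g]
        if len(pts):
            ss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return ss


_EXACT_PARTITION_MAX_N = 10  # exhaustive 2-partition search up to this size


def _exact_two_partition_within_ss(points: np.ndarray) -> float:
    """Global minimum within-SS over all 2-partitions, by enumeration.

    The optimal within-SS split need not be a Voronoi partition of its own
    centroids (cluster-size factors enter the assignment condition), so
    Lloyd iteration cannot guarantee it; for small n the minimum is found
    exactly.  Uses within-SS = sum||x||^2 - |S1|^2/k - |S2|^2/(n-k) over all
    bitmask splits.
    """
    n = points.shape[0]
    sq_total = float((points**2).sum())
    total_sum = points.sum(axis=0)
    masks = np.arange(1, 2 ** (n - 1), dtype=np.uint32)
    bits = ((masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(float)
    k = bits.sum(axis=1)
    s1 = bits @ points
    s2 = total_sum[None, :] - s1
    within = sq_total - (s1**2).sum(axis=1) / k - (s2**2).sum(axis=1) / (n - k)
    return float(within.min())


def best_two_partition_within_ss(
    points: np.ndarray, n_restarts: int, rng: np.random.Generator
) -> float:
    if points.shape[0] <= _EXACT_PARTITION_MAX_N:
        return _exact_two_partition_within_ss(points)
    return _two_means_within_ss(points, n_restarts, rng)


def _two_means_within_ss(
    points: np.ndarray, n_restarts: int, rng: np.random.Generator, max_iter: int = 100
) -> float:
    """Best within-cluster SS over seeded Lloyd restarts, vectorized.

    Restarts initialize from random distinct point pairs and iterate in
    parallel; ties in within-SS resolve to the minimum, which is all the
    cluster index needs.
    """
    n, d = points.shape
    if n == 2:
        return 0.0
    idx = np.array([rng.choice(n, size=2, replace=False) for _ in range(n_restarts)])
    centers = points[idx]  # (r, 2, d)
    assign = np.zeros((n_restarts, n), dtype=np.int8)
    for _ in range(max_iter):
        d2 = ((points[None, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)  # (r, n, 2)
        new_assign = np.argmin(d2, axis=2).astype(np.int8)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for g in (0, 1):
            m = assign == g
            cnt = m.sum(axis=1)
            # empty cluster: reseed its center at the farthest point
            empty = cnt == 0
            sums = m.astype(float) @ points
            centers[:, g, :] = np.where(
                empty[:, None], centers[:, g, :], sums / np.maximum(cnt, 1)[:, None]
            )
            if empty.any():
                far = np.argmax(d2[empty, :, 1 - g], axis=1)
                centers[empty, g, :] = points[far]
    d2 = ((points[None, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)
    within = np.minimum(d2[:, :, 0], d2[:, :, 1]).sum(axis=1)
    best = int(np.argmin(within))
    # Lloyd's final assignment is the nearest-center one; recompute exactly
    return _within_ss(points, np.argmin(d2[best], axis=1))


def sigclust_ci(
    points: np.ndarray,
    labels: Sequence | None = None,
    n_restarts: int = 20,
    rng: int | np.random.Generator | None = 0,
) -> float:
    """2-cluster index: within-cluster SS / total SS about the grand mean.

    With ``labels`` the partition is the given one; otherwise the best
    2-means partition over ``n_restarts`` seeded initializations.  All
    points identical yields CI = 0 with a warning (0/0 guarded).
    """
    points = _as_points(points)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    total = float(((points - points.mean(axis=0)) ** 2).sum())
    if total == 0.0:
        warnings.warn("all points identical; cluster index defined as 0", UserWarning)
        return 0.0
    if labels is not None:
        labels = np.asarray(labels)
        uniq = pd.unique(labels)
        if len(uniq) != 2:
            raise ValueError("labels must define exactly 2 groups")
        within = _within_ss(points, (labels == uniq[1]).astype(int))
    else:
        within = best_two_partition_within_ss(points, n_restarts, new_rng(rng, stream=50))
    return within / total


def _null_ci_distribution(
    points: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
    n_restarts: int = 20,
) -> np.ndarray:
    """Cluster indices of 2-means splits on Gaussian null datasets.

    Null model: independent Gaussians whose diagonal covariance is the
    eigenvalue spectrum of the sample covariance, hard-floored at a
    background noise variance estimated from the MAD of the mean-centered
    entries (scaled to SD under normality).
    """
    n, d = points.shape
    centered = points - points.mean(axis=0)
    mad = np.median(np.abs(centered - np.median(centered)))
    bg_var = (mad * _MAD_TO_SD) ** 2
    cov = np.cov(points, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    eig = np.maximum(eig, bg_var)
    sd = np.sqrt(eig)
    out = np.empty(n_null)
    for i in range(n_null):
        Z = rng.standard_normal((n, d)) * sd
        total = float(((Z - Z.mean(axis=0)) ** 2).sum())
        out[i] = best_two_partition_within_ss(Z, n_restarts, rng) / total if total > 0 else 0.0
    return out


def sigclust_pvalue(
    points: np.ndarray,
    labels: Sequence | None = None,
    n_null: int = 1000,
    rng: int | np.random.Generator | None = 0,
    n_restarts: int = 20,
    null_cis: np.ndarray | None = None,
) -> float:
    """SigClust p-value: fraction of null cluster indices <= the observed CI.

    The observed CI comes from the given two-group labels when provided
    (the labeled-partition mode used for source comparisons), else from the
    best 2-means split.  ``null_cis`` lets callers reuse a precomputed null
    distribution — it depends only on the point cloud.
    """
    points = _as_points(points)
    if points.shape[0] < 4:
        raise ValueError("need at least 4 points")
    if n_null < 100:
        warnings.warn("n_null < 100 gives a coarse p-value resolution", UserWarning)
    rng = new_rng(rng, stream=51)
    if null_cis is None:
        null_cis = _null_ci_distribution(points, n_null, rng, n_restarts)
    obs = sigclust_ci(points, labels=labels, n_restarts=n_restarts, rng=rng)
    return float(np.mean(null_cis <= obs))


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------

def permutation_pvalue(
    points: np.ndarray,
    labels: Sequence,
    score: str | Callable[[np.ndarray, np.ndarray], float] = "silhouette",
    n_perm: int = 100,
    rng: int | np.random.Generator | None = 0,
    correction: str = "none",
    n_null: int = 1000,
) -> tuple[float, float]:
    """Empirical p-value from label shuffling on a fixed score matrix.

    Returns ``(observed_score, p)``.  For silhouette, p is the fraction of
    permutations scoring strictly *higher*; for sigclust, strictly *lower*
    (both directions mean "more separable than observed").
    ``correction="add_one"`` uses (b + 1)/(n_perm + 1) instead of b/n_perm.
    """
    points = _as_points(points)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2 or min((labels == uniq[0]).sum(), (labels == uniq[1]).sum()) < 2:
        raise ValueError("need two groups with >= 2 members each")
    if correction not in ("none", "add_one"):
        raise ValueError("correction must be 'none' or 'add_one'")
    rng = new_rng(rng, stream=52)

    if score == "silhouette":
        score_fn = lambda pts, lab: silhouette_width(pts, lab)
        more_separable = np.greater
    elif score == "sigclust":
        # The SigClust p-value is a monotone nondecreasing step function of
        # the labeled cluster index, so ranking permutations by the CI is the
        # same test with the Gaussian-null discretization ties broken by the
        # underlying continuous statistic.
        score_fn = lambda pts, lab: sigclust_ci(pts, labels=lab)
        more_separable = np.less
    elif callable(score):
        score_fn = score
        more_separable = np.greater
    else:
        raise ValueError("score must be 'silhouette', 'sigclust', or a callable")

    observed = score_fn(points, labels)
    perm_scores = np.empty(n_perm)
    for i in range(n_perm):
        perm_scores[i] = score_fn(points, rng.permutation(labels))
    b = int(more_separable(perm_scores, observed).sum())
    p = (b + 1) / (n_perm + 1) if correction == "add_one" else b / n_perm
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# full source-pair comparison
# ---------------------------------------------------------------------------

def compare_sources(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    n_perm: int = 100,
    rng: int | np.random.Generator | None = 0,
    n_null: int = 1000,
    on_no_signal: str = "flag",
    source_col: str = "source",
    correction: str = "none",
) -> list[SeparabilityResult]:
    """Separability statistics + permutation p-values for each source pair.

    For each pair: subset samples -> per-gene scaling -> PCA -> meaningful-PC
    detection -> scores restricted to the meaningful PCs -> silhouette and
    SigClust scores with label-permutation p-values.  With no PC above the
    noise threshold the pair is flagged "no signal above noise" and scores
    are omitted (``on_no_signal="flag"``), or the first two PCs are used
    instead (``on_no_signal="top2"``).
    """
    if on_no_signal not in ("flag", "top2"):
        raise ValueError("on_no_signal must be 'flag' or 'top2'")
    matrix.require_space("log2TPM", "scaled")
    rng = new_rng(rng, stream=53)
    meta = meta.loc[list(matrix.samples)]
    results: list[SeparabilityResult] = []
    for pair in pairs:
        src_a, src_b = pair
        sel = meta.index[meta[source_col].isin([src_a, src_b])]
        present = set(meta.loc[sel, source_col])
        if {src_a, src_b} - present:
            logger.warning("skipping pair %s: missing source(s) %s", pair, {src_a, src_b} - present)
            continue
        sub = matrix.subset_samples(sel)
        labels = meta.loc[sel, source_col].to_numpy()
        if min((labels == src_a).sum(), (labels == src_b).sum()) < 2:
            logger.warning("skipping pair %s: a source has < 2 samples", pair)
            continue
        # drop genes with no variance in this subset, then scale + PCA
        sub_vals = sub.values.loc[sub.values.std(axis=1, ddof=1) > 0]
        sub = ExpressionMatrix(sub_vals, space="log2TPM")
        scaled = scale_genes(sub)
        pca = run_pca(scaled)
        report = meaningful_pcs(scaled, n_perm=n_perm, rng=rng)
        k = report.n_meaningful
        if k == 0 and on_no_signal == "flag":
            results.append(
                SeparabilityResult(
                    source_pair=(src_a, src_b),
                    n_meaningful=0,
                    silhouette=None,
                    silhouette_p=None,
                    sigclust_score=None,
                    sigclust_p=None,
                    cluster_index=None,
                    n_perm=n_perm,
                    no_signal=True,
                )
            )
            continue
        use_k = k if k > 0 else min(2, pca.scores.shape[1])
        pts = pca.scores.iloc[:, :use_k].to_numpy()
        sil_obs, sil_p = permutation_pvalue(
            pts, labels, score="silhouette", n_perm=n_perm, rng=rng, correction=correction
        )
        ci_obs, sig_p = permutation_pvalue(
            pts, labels, score="sigclust", n_perm=n_perm, rng=rng,
            correction=correction, n_null=n_null,
        )
        null_cis = _null_ci_distribution(pts, n_null, new_rng(rng, stream=54))
        sig_score = sigclust_pvalue(pts, labels=labels, rng=rng, null_cis=null_cis)
        results.append(
            SeparabilityResult(
                source_pair=(src_a, src_b),
                n_meaningful=k,
                silhouette=sil_obs,
                silhouette_p=sil_p,
                sigclust_score=sig_score,
                sigclust_p=sig_p,
                cluster_index=ci_obs,
                n_perm=n_perm,
                no_signal=(k == 0),
            )
        )
    return results


def separability_table(results: list[SeparabilityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
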