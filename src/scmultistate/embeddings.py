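"""RNA and ATAC dimension reduction.

RNA: library-size log-normalization, highly-variable-gene selection by
standardized variance, per-gene scaling with cell-cycle regression, PCA
(60 components by default).

ATAC: iterative LSI — binarize, TF-IDF weight, truncated SVD, drop
depth-correlated components, cluster, reselect the most variable features
across cluster pseudobulks, repeat (3 iterations, resolution 0.2,
50,000 variable features, 30 dimensions by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "Embedding",
    "normalize_log1p",
    "select_hvg",
    "cell_cycle_scores",
    "scale_genes",
    "regress_out",
    "pca",
    "tfidf",
    "iterative_lsi",
]


@dataclass
class Embedding:
    """A cells x dims real embedding plus its provenance."""

    coords: np.ndarray
    method: str                      # "pca" | "lsi"
    params: dict = field(default_factory=dict)
    features: np.ndarray | None = None
    depth_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite values")


# ---------------------------------------------------------------------------
# RNA normalization and feature selection
# ---------------------------------------------------------------------------

def normalize_log1p(counts, scale: float = 1e4) -> sp.csr_matrix:
    """x -> log(1 + scale * x / cell_total); all-zero cells map to zero rows."""
    counts = sp.csr_matrix(counts, dtype=np.float64, copy=True)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    inv = np.divide(scale, totals, out=np.zeros_like(totals, dtype=float),
                    where=totals > 0)
    counts = sp.diags(inv) @ counts
    counts.data = np.log1p(counts.data)
    return counts.tocsr()


def _sparse_mean_var(normed: sp.csr_matrix):
    n = normed.shape[0]
    mean = np.asarray(normed.mean(axis=0)).ravel()
    sq = normed.copy()
    sq.data = sq.data ** 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean ** 2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(normed, n: int = 2000, n_bins: int = 20,
               gene_ids=None) -> np.ndarray:
    """Rank genes by standardized variance; return indices of the top ``n``.

    The mean-variance trend is a rolling median of per-bin median variances
    over ``n_bins`` equal-count mean bins; per-gene z-scores are clipped at
    sqrt(n_cells) before the variance-of-z statistic is taken.  Constant
    genes are never selected.  Ties break by gene id (lexicographic when ids
    are given, by index otherwise).
    """
    normed = sp.csr_matrix(normed)
    n_cells, n_genes = normed.shape
    mean, var = _sparse_mean_var(normed)

    order = np.argsort(mean, kind="stable")
    bins = np.zeros(n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)
    bin_median = np.array([
        np.median(var[bins == b]) if (bins == b).any() else 0.0
        for b in range(n_bins)
    ])
    smoothed = np.array([
        np.median(bin_median[max(0, b - 1): b + 2]) for b in range(n_bins)
    ])
    expected_sd = np.sqrt(np.maximum(smoothed[bins], 1e-12))

    clip = np.sqrt(n_cells)
    std_var = np.zeros(n_genes)
    csc = normed.tocsc()
    # relative tolerance: catches genes constant up to float cancellation
    const = var <= 1e-10 * np.maximum(1.0, mean ** 2)
    for g in range(n_genes):
        if const[g]:
            continue
        col = csc.data[csc.indptr[g]: csc.indptr[g + 1]]
        z_nz = np.clip((col - mean[g]) / expected_sd[g], -clip, clip)
        z_zero = np.clip(-mean[g] / expected_sd[g], -clip, clip)
        n_zero = n_cells - col.size
        s = z_nz.sum() + n_zero * z_zero
        s2 = (z_nz ** 2).sum() + n_zero * z_zero ** 2
        std_var[g] = (s2 - s ** 2 / n_cells) / max(n_cells - 1, 1)

    if gene_ids is not None:
        tie = np.argsort(np.asarray(gene_ids, dtype=object), kind="stable")
        rank_of = np.empty(n_genes, dtype=int)
        rank_of[tie] = np.arange(n_genes)
    else:
        rank_of = np.arange(n_genes)
    order = np.lexsort((rank_of, -std_var))
    order = order[std_var[order] > 0]
    return order[:n]


# ---------------------------------------------------------------------------
# scaling, cell-cycle regression, PCA
# ---------------------------------------------------------------------------

def cell_cycle_scores(normed, gene_ids, s_genes, g2m_genes,
                      n_bins: int = 24, n_ctrl: int = 100, seed: int = 0):
    """(S score, G2M score) per cell via the binned-control module score."""
    from .signatures_scoring import module_score

    s = module_score(normed, gene_ids, list(s_genes), n_bins=n_bins,
                     n_ctrl=n_ctrl, seed=seed)
    g2m = module_score(normed, gene_ids, list(g2m_genes), n_bins=n_bins,
                       n_ctrl=n_ctrl, seed=seed + 1)
    return s, g2m


def scale_genes(normed, max_value: float = 10.0) -> np.ndarray:
    """Dense per-gene z-scores clipped at ``max_value`` (zero-variance -> 0)."""
    X = np.asarray(sp.csr_matrix(normed).todense())
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return np.clip((X - mean) / sd, -max_value, max_value)


def regress_out(X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of X on the covariates (with intercept)."""
    X = np.asarray(X, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    C = np.column_stack([np.ones(len(C)), C])
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ beta


def pca(X: np.ndarray, n: int = 60, seed: int = 0) -> Embedding:
    """Centered PCA with a deterministic sign convention.

    Each component is flipped so its largest-|loading| coordinate is
    positive; explained variance is non-increasing by construction.
    """
    X = np.asarray(X, dtype=float)
    n = min(n, min(X.shape) - 1) if min(X.shape) > 1 else 1
    center = X.mean(axis=0)
    Xc = X - center
    if min(Xc.shape) <= 200:
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        U, S, Vt = U[:, :n], S[:n], Vt[:n]
    else:
        U, S, Vt = randomized_svd(Xc, n_components=n, random_state=seed, n_iter=7)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    coords = Xc @ Vt.T
    return Embedding(
        coords=coords,
        method="pca",
        params={"n": n, "seed": seed, "center": center, "loadings": Vt,
                "explained_variance": (S ** 2) / max(len(X) - 1, 1)},
    )


# ---------------------------------------------------------------------------
# ATAC: TF-IDF + iterative LSI
# ---------------------------------------------------------------------------

def tfidf(binary, scale: float = 1e4) -> sp.csr_matrix:
    """log(1 + scale * tf * idf) weighting of a binary cells x peaks matrix.

    tf = count / cell_total; idf = log(1 + n_cells / (1 + n_cells_with_peak)).
    All-zero peaks give zero columns; all-zero cells give zero rows.
    """
    X = sp.csr_matrix(binary, dtype=np.float64, copy=True)
    n_cells = X.shape[0]
    totals = np.asarray(X.sum(axis=1)).ravel()
    inv = np.divide(1.0, totals, out=np.zeros_like(totals, dtype=float),
                    where=totals > 0)
    tf_mat = sp.diags(inv) @ X
    n_with = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + n_cells / (1.0 + n_with))
    out = tf_mat @ sp.diags(idf)
    out = out.tocsr()
    out.data = np.log1p(scale * out.data)
    return out


def _svd_embed(weighted: sp.csr_matrix, n_dims: int, seed: int):
    svd = TruncatedSVD(n_components=n_dims, random_state=seed, algorithm="randomized")
    coords = svd.fit_transform(weighted)
    comps = svd.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    return coords * flip[None, :], comps * flip[:, None]


def _depth_filter(coords: np.ndarray, log_depth: np.ndarray, threshold: float):
    d = log_depth - log_depth.mean()
    dn = np.linalg.norm(d)
    corr = np.zeros(coords.shape[1])
    if dn > 0:
        for j in range(coords.shape[1]):
            c = coords[:, j] - coords[:, j].mean()
            cn = np.linalg.norm(c)
            corr[j] = (c @ d) / (cn * dn) if cn > 0 else 0.0
    keep = np.abs(corr) <= threshold
    return keep, corr


def iterative_lsi(
    atac_counts,
    iterations: int = 3,
    resolution: float = 0.2,
    var_features: int = 50000,
    n_dims: int = 30,
    seed: int = 0,
    depth_corr_threshold: float = 0.75,
    cluster_k: int = 20,
) -> Embedding:
    """Iterative LSI embedding of a cells x peaks count matrix.

    Iteration 1 uses the ``var_features`` most accessible peaks; later
    iterations reselect the peaks most variable across cluster pseudobulk
    profiles.  Components correlated with log depth beyond the threshold are
    dropped.  Deterministic given the seed.
    """
    from .state_definition import cluster_graph, snn_graph

    X = sp.csr_matrix(atac_counts)
    n_cells, n_peaks = X.shape
    var_features = min(var_features, n_peaks)
    binary = X.copy()
    binary.data = np.ones_like(binary.data)
    log_depth = np.log1p(np.asarray(X.sum(axis=1)).ravel())

    accessibility = np.asarray(binary.sum(axis=0)).ravel()
    features = np.argsort(-accessibility, kind="stable")[:var_features]

    coords = corr = None
    for it in range(iterations):
        weighted = tfidf(binary[:, features])
        full_coords, _ = _svd_embed(weighted, n_dims, seed)
        keep, corr = _depth_filter(full_coords, log_depth, depth_corr_threshold)
        coords = full_coords[:, keep]
        if coords.shape[1] < 2:
            raise ValueError(
                "fewer than 2 informative LSI components after depth filtering"
            )
        if it == iterations - 1:
            break
        graph = snn_graph(coords, k=min(cluster_k, n_cells - 1))
        part = cluster_graph(graph, resolution=resolution, seed=seed)
        labels = part.labels
        # pseudobulk log-CPM variance across clusters
        n_clusters = labels.max() + 1
        pb = np.zeros((n_clusters, n_peaks))
        for c in range(n_clusters):
            pb[c] = np.asarray(X[labels == c].sum(axis=0)).ravel()
        totals = pb.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        pb = np.log1p(1e6 * pb / totals)
        peak_var = pb.var(axis=0)
        features = np.argsort(-peak_var, kind="stable")[:var_features]
        if (peak_var[features] > 0).sum() < n_dims + 1:
            raise ValueError("fewer than n_dims+1 informative features")

    return Embedding(
        coords=coords,
        method="lsi",
        params={
            "iterations": iterations,
            "resolution": resolution,
            "var_features": var_features,
            "n_dims": n_dims,
            "seed": seed,
            "depth_corr_threshold": depth_corr_threshold,
        },
        features=features,
        depth_correlation=corr,
    )
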