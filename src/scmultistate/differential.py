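"""Wilcoxon rank-sum differential testing.

Genes: rank-sum on normalized expression with min-percent and log-fold-change
pre-filters (defaults 0.05 and 0.5).  Peaks: the same test on a
confounder-matched subset of cells — cells are stratified on a quantile grid
of TSS enrichment and log fragment count, and the larger group is subsampled
within each stratum so the two groups are depth- and quality-balanced.

P-values use exact permutation enumeration when the smaller group has <= 8
cells and a tie-corrected normal approximation (with continuity correction)
otherwise.  Multiple testing: Benjamini-Hochberg by default, Bonferroni on
request.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_de",
    "differential_peaks",
    "wilcoxon_rank_sum",
    "adjust_pvalues",
    "EXACT_MAX_GROUP",
]

EXACT_MAX_GROUP = 8


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown adjustment {method!r}")


# ---------------------------------------------------------------------------
# rank-sum core
# ---------------------------------------------------------------------------

def _exact_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for the rank-sum of the smaller group."""
    swap = len(x) > len(y)
    small, large = (y, x) if swap else (x, y)
    pooled = np.concatenate([small, large])
    ranks = rankdata(pooled)
    n_small, n = len(small), len(pooled)
    mu = n_small * (n + 1) / 2.0
    w_obs = ranks[:n_small].sum()
    dev = abs(w_obs - mu) - 1e-9  # tolerate float midranks
    count = total = 0
    for comb in combinations(range(n), n_small):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev:
            count += 1
    return count / total


def _normal_pvalues(ranks: np.ndarray, n_a: int, n_b: int,
                    tie_term: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal approximation with tie + continuity correction.

    ranks: features x cells midranks (group A first), tie_term: per-feature
    sum of (t^3 - t) over tie groups.
    """
    n = n_a + n_b
    w = ranks[:, :n_a].sum(axis=1)
    mu = n_a * (n + 1) / 2.0
    var = (n_a * n_b / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    z = np.zeros_like(w, dtype=float)
    nz = var > 0
    z[nz] = (np.abs(w[nz] - mu) - 0.5) / np.sqrt(var[nz])
    z = np.maximum(z, 0.0)
    from scipy.stats import norm

    p = 2 * norm.sf(z)
    p[~nz] = 1.0
    return np.minimum(p, 1.0)


def _tie_terms(sorted_rows: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tie groups for each row of a sorted matrix."""
    out = np.zeros(sorted_rows.shape[0])
    for i, row in enumerate(sorted_rows):
        _, counts = np.unique(row, return_counts=True)
        out[i] = np.sum(counts.astype(float) ** 3 - counts)
    return out


def wilcoxon_rank_sum(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided rank-sum p for one feature (exact when min group <= 8)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(len(a), len(b)) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(a), len(b)) <= EXACT_MAX_GROUP:
        return _exact_pvalue(a, b)
    pooled = np.concatenate([a, b])[None, :]
    ranks = rankdata(pooled, axis=1)
    tie = _tie_terms(np.sort(pooled, axis=1))
    return float(_normal_pvalues(ranks, len(a), len(b), tie)[0])


def _test_matrix(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Rank-sum p per row (feature); exact or normal mode by group size."""
    n_a, n_b = Xa.shape[1], Xb.shape[1]
    if min(n_a, n_b) <= EXACT_MAX_GROUP:
        return np.array([_exact_pvalue(Xa[i], Xb[i]) for i in range(Xa.shape[0])])
    pooled = np.hstack([Xa, Xb])
    ranks = rankdata(pooled, axis=1)
    tie = _tie_terms(np.sort(pooled, axis=1))
    return _normal_pvalues(ranks, n_a, n_b, tie)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _group_masks(n, group_a, group_b):
    ma = np.zeros(n, dtype=bool)
    mb = np.zeros(n, dtype=bool)
    ga = np.asarray(group_a)
    gb = np.asarray(group_b)
    if ga.dtype == bool:
        ma, mb = ga.copy(), gb.copy()
    else:
        ma[ga] = True
        mb[gb] = True
    if not ma.any() or not mb.any():
        raise ValueError("both groups must be non-empty")
    if (ma & mb).any():
        raise ValueError("groups must be disjoint")
    return ma, mb


def wilcoxon_de(
    normed,
    feature_ids,
    group_a,
    group_b,
    min_pct: float = 0.05,
    lfc_threshold: float = 0.5,
    adjust: str = "bh",
    group_label: str = "A",
    chunk: int = 512,
) -> pd.DataFrame:
    """Wilcoxon DE table between two cell groups on normalized values.

    Features are tested only if expressed in >= min_pct of either group and
    |log2FC| >= lfc_threshold, where log2FC compares group means of the
    normalized values with pseudocount 1.  BH (or Bonferroni) adjustment is
    applied across tested features only.
    """
    X = sp.csr_matrix(normed)
    feature_ids = np.asarray(feature_ids, dtype=object)
    ma, mb = _group_masks(X.shape[0], group_a, group_b)
    if np.array_equal(ma, mb):
        raise ValueError("groups are identical")

    Xa_s, Xb_s = X[ma].tocsc(), X[mb].tocsc()
    n_a, n_b = int(ma.sum()), int(mb.sum())
    pct_in = Xa_s.getnnz(axis=0) / n_a
    pct_out = Xb_s.getnnz(axis=0) / n_b
    mean_a = np.asarray(Xa_s.mean(axis=0)).ravel()
    mean_b = np.asarray(Xb_s.mean(axis=0)).ravel()
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    tested = np.flatnonzero(
        ((pct_in >= min_pct) | (pct_out >= min_pct))
        & (np.abs(log2fc) >= lfc_threshold)
    )
    pvals = np.empty(tested.size)
    for start in range(0, tested.size, chunk):
        sel = tested[start : start + chunk]
        Xa = np.asarray(Xa_s[:, sel].todense()).T
        Xb = np.asarray(Xb_s[:, sel].todense()).T
        pvals[start : start + chunk] = _test_matrix(Xa, Xb)

    table = pd.DataFrame(
        {
            "feature": feature_ids[tested],
            "group": group_label,
            "log2fc": log2fc[tested],
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "p_value": pvals,
            "adj_p": adjust_pvalues(pvals, adjust),
            "direction": np.where(log2fc[tested] >= 0, "up", "down"),
        }
    )
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# differential accessibility with confounder matching
# ---------------------------------------------------------------------------

def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, values, side="right")


def match_cells_by_confounders(
    group_a_mask: np.ndarray,
    group_b_mask: np.ndarray,
    cell_meta: pd.DataFrame,
    confounders=("tss_enrichment", "log_n_fragments"),
    n_bins: int = 4,
    seed: int = 0,
) -> tuple:
    """Stratified subsampling so both groups match on the confounder grid.

    Returns (matched_a_indices, matched_b_indices, stratum report).
    """
    meta = cell_meta.copy()
    if "log_n_fragments" in confounders and "log_n_fragments" not in meta:
        meta["log_n_fragments"] = np.log1p(meta["n_fragments"])
    for c in confounders:
        if c not in meta:
            raise KeyError(f"cell_meta is missing confounder column {c!r}")
    rng = np.random.default_rng(seed)
    both = group_a_mask | group_b_mask
    idx = np.flatnonzero(both)
    strata = np.zeros(idx.size, dtype=int)
    for c in confounders:
        strata = strata * n_bins + _quantile_bins(
            meta[c].to_numpy()[idx], n_bins
        )
    keep_a, keep_b, report = [], [], []
    for s in np.unique(strata):
        cells = idx[strata == s]
        a = cells[group_a_mask[cells]]
        b = cells[group_b_mask[cells]]
        if a.size == 0 or b.size == 0:
            report.append((s, a.size, b.size, 0))
            continue
        m = min(a.size, b.size)
        if a.size > m:
            a = rng.choice(a, m, replace=False)
        if b.size > m:
            b = rng.choice(b, m, replace=False)
        keep_a.append(np.sort(a))
        keep_b.append(np.sort(b))
        report.append((s, a.size, b.size, m))
    if not keep_a:
        raise ValueError("no confounder stratum contains cells from both groups")
    report = pd.DataFrame(report, columns=["stratum", "n_a", "n_b", "n_matched"])
    return np.concatenate(keep_a), np.concatenate(keep_b), report


def differential_peaks(
    atac_counts,
    peak_ids,
    group_a,
    group_b,
    cell_meta: pd.DataFrame,
    confounders=("tss_enrichment", "log_n_fragments"),
    n_bins: int = 4,
    min_pct: float = 0.05,
    lfc_threshold: float = 0.5,
    adjust: str = "bh",
    seed: int = 0,
    group_label: str = "A",
    return_matching: bool = False,
):
    """Confounder-matched Wilcoxon differential accessibility.

    Cells are stratified into an ``n_bins``-per-confounder quantile grid;
    within each stratum the larger group is subsampled (seeded) to the
    smaller group's size; the pooled matched cells are then tested per peak
    on log-normalized fragment counts.
    """
    from .embeddings import normalize_log1p

    X = sp.csr_matrix(atac_counts)
    ma, mb = _group_masks(X.shape[0], group_a, group_b)
    matched_a, matched_b, report = match_cells_by_confounders(
        ma, mb, cell_meta, confounders=confounders, n_bins=n_bins, seed=seed
    )
    sub = np.concatenate([matched_a, matched_b])
    normed = normalize_log1p(X[sub])
    new_a = np.zeros(sub.size, dtype=bool)
    new_a[: matched_a.size] = True
    table = wilcoxon_de(
        normed,
        peak_ids,
        new_a,
        ~new_a,
        min_pct=min_pct,
        lfc_threshold=lfc_threshold,
        adjust=adjust,
        group_label=group_label,
    )
    if return_matching:
        return table, report
    return table
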