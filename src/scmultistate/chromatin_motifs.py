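"""Bias-corrected accessibility deviations for motifs and peak modules.

For every peak set (all peaks carrying a TF motif, or a co-accessibility
module) the observed per-cell accessibility is compared with the expectation
under a cell x peak independence model, then centered and scaled against
``n_bg`` background peak sets matched on GC content and mean accessibility:

    raw      = (obs - exp) / exp,   exp = cell_total/grand_total * set_total
    deviation = raw - mean(background raws)
    z         = deviation / sd(background raws)

The raw deviation is invariant to rescaling any cell's counts, and the
expectation conserves the observed set totals across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "DeviationMatrix",
    "match_background_peaks",
    "compute_deviations",
    "differential_motif_scores",
    "peak_module_scores",
]


@dataclass
class DeviationMatrix:
    """Peak-set x cell deviations and z-scores with their backgrounds."""

    deviations: np.ndarray          # sets x cells
    z: np.ndarray                   # sets x cells (NaN where background sd == 0)
    set_names: list
    backgrounds: np.ndarray         # peaks x n_bg background peak ids
    flags: pd.DataFrame             # per-set: empty_set, zero_sd_cells
    peak_stats: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# background peak matching
# ---------------------------------------------------------------------------

def match_background_peaks(
    peak_gc: np.ndarray,
    peak_mean_accessibility: np.ndarray,
    n_bg: int = 50,
    n_bins: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """For each peak, sample ``n_bg`` background peaks with similar stats.

    Peaks are embedded in standardized (GC, log mean accessibility) space and
    binned on an ``n_bins`` x ``n_bins`` grid; backgrounds are sampled (with
    replacement, seeded) from the peak's bin neighborhood, expanded in
    Chebyshev rings until >= n_bg candidates exist.  A peak may draw itself.
    """
    gc = np.asarray(peak_gc, dtype=float)
    acc = np.log1p(np.asarray(peak_mean_accessibility, dtype=float))
    n_peaks = gc.size
    if n_peaks < n_bg:
        raise ValueError(f"need at least n_bg={n_bg} peaks, got {n_peaks}")

    def standardize(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    def bin_of(v):
        z = standardize(v)
        lo, hi = z.min(), z.max()
        width = (hi - lo) or 1.0
        return np.minimum(((z - lo) / width * n_bins).astype(int), n_bins - 1)

    bx, by = bin_of(gc), bin_of(acc)
    grid: dict = {}
    for p in range(n_peaks):
        grid.setdefault((bx[p], by[p]), []).append(p)
    grid = {k: np.asarray(v) for k, v in grid.items()}

    rng = np.random.default_rng(seed)
    out = np.empty((n_peaks, n_bg), dtype=int)
    cache: dict = {}
    for key in grid:
        cands = grid[key]
        ring = 0
        while cands.size < n_bg:
            ring += 1
            extra = [
                grid[k]
                for k in grid
                if max(abs(k[0] - key[0]), abs(k[1] - key[1])) == ring
            ]
            if extra:
                cands = np.concatenate([cands, *extra])
            if ring > 2 * n_bins:
                break
        cache[key] = np.sort(cands)
    for p in range(n_peaks):
        cands = cache[(bx[p], by[p])]
        out[p] = rng.choice(cands, size=n_bg, replace=True)
    return out


# ---------------------------------------------------------------------------
# deviations
# ---------------------------------------------------------------------------

def _annotation_matrix(annotation, n_peaks: int):
    """Normalize an annotation to (csr sets x peaks with multiplicity, names)."""
    if isinstance(annotation, dict):
        names = list(annotation)
        rows, cols = [], []
        for i, name in enumerate(names):
            pk = np.asarray(annotation[name], dtype=int)
            rows.extend([i] * pk.size)
            cols.extend(pk.tolist())
        M = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(names), n_peaks)
        )
        return M, names
    M = sp.csr_matrix(annotation)
    if M.shape[0] == n_peaks:  # peaks x sets -> sets x peaks
        M = M.T.tocsr()
    names = [f"set{i}" for i in range(M.shape[0])]
    return M.astype(np.float64), names


def _raw_deviations(M: sp.csr_matrix, X_T: sp.csc_matrix,
                    cell_totals: np.ndarray, peak_fracs: np.ndarray):
    """(obs - exp)/exp for each set (rows of M) x cell; zero-fraction sets -> 0."""
    obs = np.asarray((M @ X_T).todense())
    set_fracs = M @ peak_fracs
    exp = set_fracs[:, None] * cell_totals[None, :]
    raw = np.zeros_like(obs)
    nz = set_fracs > 0
    raw[nz] = (obs[nz] - exp[nz]) / exp[nz]
    return raw, nz


def compute_deviations(
    atac_counts,
    annotation,
    backgrounds: np.ndarray,
    set_names=None,
    expectation_counts=None,
) -> DeviationMatrix:
    """Bias-corrected deviations of peak-set accessibility per cell.

    ``annotation`` is a dict {name: peak index array} or a binary
    peaks x sets (or sets x peaks) matrix.  ``backgrounds`` is the
    peaks x n_bg assignment from :func:`match_background_peaks`; iteration b
    substitutes every peak of every set with its b-th background peak.

    The expectation conditions on the per-peak accessibility fractions of
    ``expectation_counts`` (defaults to ``atac_counts``); holding those
    fractions fixed makes the raw deviation exactly invariant to rescaling
    any single cell's counts.
    """
    X = sp.csr_matrix(atac_counts, dtype=np.float64)
    n_cells, n_peaks = X.shape
    M, names = _annotation_matrix(annotation, n_peaks)
    if set_names is not None:
        names = list(set_names)
    n_sets = M.shape[0]
    n_bg = backgrounds.shape[1]

    X_T = X.T.tocsc()
    cell_totals = np.asarray(X.sum(axis=1)).ravel()
    E = X if expectation_counts is None else sp.csr_matrix(
        expectation_counts, dtype=np.float64
    )
    peak_totals_e = np.asarray(E.sum(axis=0)).ravel()
    grand_e = peak_totals_e.sum()
    if grand_e == 0:
        raise ValueError("ATAC matrix is all zeros")
    # exp[s, c] = cell_total_c * (set fraction of the expectation profile)
    peak_fracs = peak_totals_e / grand_e

    raw, nonzero_sets = _raw_deviations(M, X_T, cell_totals, peak_fracs)

    Mc = M.tocoo()
    bg_sum = np.zeros_like(raw)
    bg_sumsq = np.zeros_like(raw)
    for b in range(n_bg):
        bg_cols = backgrounds[Mc.col, b]
        Mb = sp.csr_matrix(
            (Mc.data, (Mc.row, bg_cols)), shape=(n_sets, n_peaks)
        )
        raw_b, _ = _raw_deviations(Mb, X_T, cell_totals, peak_fracs)
        bg_sum += raw_b
        bg_sumsq += raw_b ** 2

    bg_mean = bg_sum / n_bg
    bg_var = np.maximum((bg_sumsq - bg_sum ** 2 / n_bg) / max(n_bg - 1, 1), 0.0)
    bg_sd = np.sqrt(bg_var)
    dev = raw - bg_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(bg_sd > 0, dev / bg_sd, np.nan)

    empty = ~nonzero_sets | (np.asarray(M.sum(axis=1)).ravel() == 0)
    dev[empty] = 0.0
    z[empty] = 0.0
    flags = pd.DataFrame(
        {
            "set": names,
            "empty_set": empty,
            "zero_sd_cells": np.isnan(z).sum(axis=1),
        }
    )
    return DeviationMatrix(
        deviations=dev,
        z=z,
        set_names=names,
        backgrounds=backgrounds,
        flags=flags,
        peak_stats=pd.DataFrame(
            {"mean_accessibility": np.asarray(X.mean(axis=0)).ravel()}
        ),
    )


# ---------------------------------------------------------------------------
# per-state enrichment
# ---------------------------------------------------------------------------

def differential_motif_scores(z: np.ndarray, set_names, state_labels,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Per-state Wilcoxon enrichment of deviation z-scores (state vs rest).

    Enriched iff BH-adjusted p < alpha and the state's mean z exceeds the
    rest.  NaN z entries (undefined backgrounds) are treated as 0.
    """
    from .differential import _test_matrix, adjust_pvalues

    Z = np.nan_to_num(np.asarray(z, dtype=float))
    labels = np.asarray(state_labels)
    rows = []
    for state in np.unique(labels):
        m = labels == state
        if m.all() or not m.any():
            continue
        pv = _test_matrix(Z[:, m], Z[:, ~m])
        diff = Z[:, m].mean(axis=1) - Z[:, ~m].mean(axis=1)
        adj = adjust_pvalues(pv)
        for i, name in enumerate(set_names):
            rows.append(
                {
                    "set": name,
                    "state": state,
                    "mean_z_diff": diff[i],
                    "p_value": pv[i],
                    "adj_p": adj[i],
                    "enriched": (adj[i] < alpha) and (diff[i] > 0),
                }
            )
    return pd.DataFrame(
        rows, columns=["set", "state", "mean_z_diff", "p_value", "adj_p", "enriched"]
    )


def peak_module_scores(atac_counts, peak_modules: dict, backgrounds: np.ndarray,
                       state_labels=None):
    """Deviation scoring of co-accessibility peak modules.

    Same machinery as :func:`compute_deviations`; when state labels are given
    a state x module mean-z matrix is also returned.
    """
    dm = compute_deviations(atac_counts, peak_modules, backgrounds)
    if state_labels is None:
        return dm
    labels = np.asarray(state_labels)
    states = np.unique(labels)
    Z = np.nan_to_num(dm.z)
    mat = pd.DataFrame(
        {s: Z[:, labels == s].mean(axis=1) for s in states},
        index=dm.set_names,
    ).T
    mat.index.name = "state"
    return dm, mat
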