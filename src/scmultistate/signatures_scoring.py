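"""Gene-signature scoring with expression-matched control genes.

A module score is the mean normalized expression of the signature genes minus
the mean of a control set drawn from the same expression bins, so depth and
baseline-abundance effects cancel.  State program matrices summarize many
signatures as row-scaled state averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "module_score",
    "score_signatures",
    "state_program_matrix",
]


def module_score(normed, gene_ids, signature, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Per-cell binned-control score of one gene signature.

    Genes are binned into ``n_bins`` equal-count bins of mean expression;
    for each signature gene, ``n_ctrl`` control genes are sampled (seeded,
    with replacement) from its bin.  Score = mean(signature) - mean(controls).
    Signature genes missing from the dataset are ignored with a warning; a
    signature disjoint from the dataset yields an all-NaN score vector.
    """
    X = sp.csr_matrix(normed, dtype=np.float64).tocsc()
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cells, n_genes = X.shape
    pos_of = {g: i for i, g in enumerate(gene_ids)}
    sig = [g for g in signature if g in pos_of]
    missing = [g for g in signature if g not in pos_of]
    if missing:
        warnings.warn(f"{len(missing)} signature genes not in dataset; ignored")
    if not sig:
        warnings.warn("signature disjoint from dataset genes; scores are NaN")
        return np.full(n_cells, np.nan)
    sig_idx = np.asarray([pos_of[g] for g in sig], dtype=int)

    mean = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(mean, kind="stable")
    bins = np.zeros(n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    rng = np.random.default_rng(seed)
    ctrl_idx = []
    for g in sig_idx:
        pool = np.flatnonzero(bins == bins[g])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)

    sig_mean = np.asarray(X[:, sig_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    return sig_mean - ctrl_mean


def score_signatures(normed, gene_ids, signatures: dict, n_bins: int = 24,
                     n_ctrl: int = 100, seed: int = 0):
    """Cells x signatures module-score matrix (per-signature derived seeds).

    Returns (scores DataFrame, flags DataFrame); a signature disjoint from
    the dataset produces an all-NaN column and is flagged.
    """
    cols, flags = {}, []
    for k, (name, genes) in enumerate(signatures.items()):
        cols[name] = module_score(
            normed, gene_ids, genes, n_bins=n_bins, n_ctrl=n_ctrl,
            seed=seed + k,
        )
        flags.append((name, bool(np.isnan(cols[name]).all())))
    scores = pd.DataFrame(cols)
    return scores, pd.DataFrame(flags, columns=["signature", "disjoint"])


def state_program_matrix(scores: pd.DataFrame, state_labels,
                         scale: bool = True):
    """State x signature mean-score matrix, optionally row-scaled to z.

    Row scaling divides by the per-state standard deviation across
    signatures; a zero-variance row is left centered and flagged.  Returns
    (matrix, flags DataFrame).
    """
    labels = np.asarray(state_labels)
    states = np.unique(labels)
    mat = pd.DataFrame(
        {name: [scores[name][labels == s].mean() for s in states]
         for name in scores.columns},
        index=pd.Index(states, name="state"),
    )
    flags = pd.DataFrame({"state": states, "zero_variance": False})
    if scale:
        vals = mat.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(vals, axis=1, keepdims=True)
            sd = np.nanstd(vals, axis=1, ddof=0, keepdims=True)
        zero = sd.ravel() == 0
        sd[sd == 0] = 1.0
        mat = pd.DataFrame((vals - mu) / sd, index=mat.index,
                           columns=mat.columns)
        flags["zero_variance"] = zero
    return mat, flags
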