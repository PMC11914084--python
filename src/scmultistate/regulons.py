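"""TF-centric regulons: co-expression candidates, motif-evidence pruning and
rank-based per-cell activity.

A regulon is a transcription factor plus inferred targets.  Candidates are
the genes most positively Spearman-correlated with the TF; a candidate is
retained only if a peak linked to its promoter carries the TF's motif.
Activity is the area under the recovery curve of regulon members within the
top fraction of each cell's expression ranking, normalized to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

__all__ = [
    "RegulonSet",
    "PeakGeneLinks",
    "coexpression_candidates",
    "link_peaks_to_genes",
    "prune_by_motif",
    "aucell_scores",
    "differential_regulon",
]


@dataclass
class RegulonSet:
    """TF -> weighted target lists plus (optionally) per-cell AUC activity."""

    targets: dict                        # tf -> DataFrame(gene, weight)
    provenance: pd.DataFrame             # tf, n_candidates, n_pruned, kept
    params: dict = field(default_factory=dict)
    activity: pd.DataFrame | None = None  # cells x regulons, AUC in [0, 1]

    def __post_init__(self) -> None:
        min_targets = self.params.get("min_targets", 0)
        for tf, tab in self.targets.items():
            if len(tab) < min_targets:
                raise ValueError(f"regulon {tf} smaller than min_targets")
            if not np.isfinite(tab["weight"]).all():
                raise ValueError(f"regulon {tf} has non-finite weights")


@dataclass
class PeakGeneLinks:
    """Promoter-rule peak -> gene assignments."""

    links: pd.DataFrame                  # peak_idx, gene
    window: int

    def genes_of_peak(self) -> dict:
        return {
            int(p): g["gene"].tolist()
            for p, g in self.links.groupby("peak_idx")
        }

    def peaks_of_gene(self) -> dict:
        return {g: t["peak_idx"].to_numpy() for g, t in self.links.groupby("gene")}


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def coexpression_candidates(normed_rna, gene_ids, tf_list,
                            n_candidates: int = 50) -> dict:
    """Top positively Spearman-correlated genes per TF.

    The TF itself is excluded; TFs with zero-variance expression are dropped
    with a warning.  Returns {tf: DataFrame(gene, weight)} sorted by weight
    descending (ties by gene id).
    """
    X = np.asarray(sp.csr_matrix(normed_rna).todense())
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cells = X.shape[0]
    ranks = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks[:, j] = rankdata(X[:, j])
    ranks -= ranks.mean(axis=0)
    norms = np.linalg.norm(ranks, axis=0)

    out = {}
    for tf in tf_list:
        hits = np.flatnonzero(gene_ids == tf)
        if hits.size == 0:
            warnings.warn(f"TF {tf!r} not in the dataset; skipped")
            continue
        t = hits[0]
        if norms[t] == 0:
            warnings.warn(f"TF {tf!r} has zero-variance expression; dropped")
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (ranks.T @ ranks[:, t]) / (norms * norms[t])
        rho[norms == 0] = 0.0
        rho[t] = -np.inf
        order = np.lexsort((gene_ids, -rho))
        order = order[rho[order] > 0][:n_candidates]
        out[tf] = pd.DataFrame({"gene": gene_ids[order], "weight": rho[order]})
    return out


# ---------------------------------------------------------------------------
# peak-gene linking and motif pruning
# ---------------------------------------------------------------------------

def link_peaks_to_genes(peaks: pd.DataFrame, tss_table: pd.DataFrame,
                        window: int = 2000) -> PeakGeneLinks:
    """Link a peak to a gene iff it overlaps [TSS - window, TSS + window).

    Intervals are 0-based half-open; TSS is a single position.  Multi-gene
    overlaps keep all links.
    """
    rows = []
    for chrom, pgrp in peaks.reset_index().groupby("chrom"):
        tgrp = tss_table[tss_table["chrom"] == chrom]
        if tgrp.empty:
            continue
        tpos = tgrp["pos"].to_numpy()
        order = np.argsort(tpos, kind="stable")
        tpos_sorted = tpos[order]
        genes = tgrp["gene"].to_numpy()[order]
        starts = pgrp["start"].to_numpy()
        ends = pgrp["end"].to_numpy()
        pidx = pgrp["index"].to_numpy()
        # peak [s, e) overlaps [tss-w, tss+w) iff s - w < tss < e + w... more
        # precisely: tss - w < e and s < tss + w  <=>  s - w < tss <= e + w - 1
        lo = np.searchsorted(tpos_sorted, starts - window, side="right")
        hi = np.searchsorted(tpos_sorted, ends + window, side="left")
        for k in range(len(pidx)):
            for j in range(lo[k], hi[k]):
                t = tpos_sorted[j]
                if (t - window < ends[k]) and (starts[k] < t + window):
                    rows.append((int(pidx[k]), genes[j]))
    links = pd.DataFrame(rows, columns=["peak_idx", "gene"])
    return PeakGeneLinks(links=links, window=window)


def prune_by_motif(candidates: dict, motif_annotation, motif_names,
                   links: PeakGeneLinks, tf_motif_map: dict | None = None,
                   min_targets: int = 10) -> RegulonSet:
    """Keep a candidate target iff a linked peak carries the TF's motif.

    ``tf_motif_map`` maps TF symbol -> motif id (defaults to
    ``f"{tf}_motif"``).  Regulons with fewer than ``min_targets`` surviving
    targets are dropped with a warning.
    """
    ann = sp.csc_matrix(motif_annotation)
    motif_index = {m: j for j, m in enumerate(motif_names)}
    peaks_of_gene = links.peaks_of_gene()

    kept, prov = {}, []
    for tf, tab in candidates.items():
        motif_id = (tf_motif_map or {}).get(tf, f"{tf}_motif")
        if motif_id not in motif_index:
            warnings.warn(f"TF {tf!r} has no motif column; regulon dropped")
            prov.append((tf, len(tab), 0, False))
            continue
        col = ann[:, motif_index[motif_id]]
        motif_peaks = set(col.indices.tolist())
        keep_mask = [
            any(int(p) in motif_peaks for p in peaks_of_gene.get(g, ()))
            for g in tab["gene"]
        ]
        pruned = tab[np.asarray(keep_mask, dtype=bool)].reset_index(drop=True)
        ok = len(pruned) >= min_targets
        if not ok:
            warnings.warn(
                f"regulon {tf!r} has {len(pruned)} targets after pruning "
                f"(< min_targets={min_targets}); dropped"
            )
        prov.append((tf, len(tab), len(pruned), ok))
        if ok:
            kept[tf] = pruned
    provenance = pd.DataFrame(
        prov, columns=["tf", "n_candidates", "n_after_pruning", "kept"]
    )
    return RegulonSet(
        targets=kept, provenance=provenance, params={"min_targets": min_targets}
    )


# ---------------------------------------------------------------------------
# AUC activity
# ---------------------------------------------------------------------------

def _cell_auc(r: np.ndarray, t: np.ndarray, T: int) -> float:
    """Area of the tie-aware recovery curve over the top-T ranks.

    ``r`` = descending midranks of the regulon genes, ``t`` = their tie-block
    sizes.  A gene in a tie block spanning ranks [a, b] contributes its
    expected recovery fraction at each cutoff x <= T.
    """
    a = r - (t - 1) / 2.0
    b = r + (t - 1) / 2.0
    contrib = np.where(
        b <= T,
        T - r + 1.0,
        np.where(a > T, 0.0, (T - a + 1.0) * (T - a + 2.0) / (2.0 * t)),
    )
    return float(contrib.sum())


def aucell_scores(normed_rna, gene_ids, regulons, top_frac: float = 0.05) -> pd.DataFrame:
    """Cells x regulons recovery-curve AUC matrix.

    Per cell, genes are ranked by expression descending with midrank ties;
    the AUC integrates the number of regulon members recovered within the
    top ``ceil(top_frac * n_genes)`` ranks, normalized by the maximum
    achievable area.  Always in [0, 1].
    """
    X = np.asarray(sp.csr_matrix(normed_rna).todense())
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cells, n_genes = X.shape
    T = int(np.ceil(top_frac * n_genes))
    if isinstance(regulons, RegulonSet):
        reg_genes = {tf: tab["gene"].tolist() for tf, tab in regulons.targets.items()}
    else:
        reg_genes = {tf: list(g) for tf, g in regulons.items()}
    pos_of = {g: i for i, g in enumerate(gene_ids)}
    reg_pos = {
        tf: np.asarray([pos_of[g] for g in genes if g in pos_of], dtype=int)
        for tf, genes in reg_genes.items()
    }
    max_area = {
        tf: float(sum(min(x, len(p)) for x in range(1, T + 1)))
        for tf, p in reg_pos.items()
    }

    out = np.zeros((n_cells, len(reg_pos)))
    tfs = list(reg_pos)
    for c in range(n_cells):
        x = X[c]
        r = rankdata(-x)
        _, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
        t = counts[inverse].astype(float)
        for j, tf in enumerate(tfs):
            p = reg_pos[tf]
            if p.size == 0 or max_area[tf] == 0:
                continue
            out[c, j] = _cell_auc(r[p], t[p], T) / max_area[tf]
    return pd.DataFrame(np.clip(out, 0.0, 1.0), columns=tfs)


def differential_regulon(activity: pd.DataFrame, state_labels,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-state Wilcoxon enrichment of regulon AUC (state vs rest)."""
    from .differential import _test_matrix, adjust_pvalues

    labels = np.asarray(state_labels)
    A = activity.to_numpy().T            # regulons x cells
    rows = []
    for state in np.unique(labels):
        m = labels == state
        if m.all() or not m.any():
            continue
        pv = _test_matrix(A[:, m], A[:, ~m])
        diff = A[:, m].mean(axis=1) - A[:, ~m].mean(axis=1)
        adj = adjust_pvalues(pv)
        for i, tf in enumerate(activity.columns):
            rows.append(
                {
                    "tf": tf,
                    "state": state,
                    "mean_auc_diff": diff[i],
                    "p_value": pv[i],
                    "adj_p": adj[i],
                    "enriched": (adj[i] < alpha) and (diff[i] > 0),
                }
            )
    return pd.DataFrame(
        rows, columns=["tf", "state", "mean_auc_diff", "p_value", "adj_p", "enriched"]
    )
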