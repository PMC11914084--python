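"""Readers/writers for the standard on-disk formats and per-cell quality control.

The pipeline's central container is :class:`MultiomeDataset`: a pair of
cells x features count matrices (RNA UMIs, ATAC fragment counts in peaks)
that share one cell ordering, plus feature annotations and per-cell QC
metadata.  All genomic intervals are BED-style 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "MultiomeDataset",
    "QCThresholds",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_fragments",
    "compute_qc_metrics",
    "compute_tss_enrichment",
    "filter_cells",
]

QC_COLUMNS = ("n_genes", "n_counts", "pct_mito", "n_fragments", "tss_enrichment")


@dataclass
class MultiomeDataset:
    """Paired RNA + ATAC counts with shared cell ordering.

    Attributes
    ----------
    rna : scipy.sparse.csr_matrix
        cells x genes non-negative integer UMI counts.
    atac : scipy.sparse.csr_matrix
        cells x peaks non-negative integer fragment counts.
    genes : pandas.DataFrame
        indexed by gene symbol, with at least a boolean ``mito`` column.
    peaks : pandas.DataFrame
        columns ``chrom``, ``start``, ``end`` (0-based half-open), optional
        ``gc``; one row per peak, same order as atac columns.
    cell_ids : list of str
    cell_meta : pandas.DataFrame
        indexed by cell id, QC metric columns plus ``sample_label``.
    """

    rna: sp.csr_matrix
    atac: sp.csr_matrix
    genes: pd.DataFrame
    peaks: pd.DataFrame
    cell_ids: list
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rna.shape[0] != self.atac.shape[0]:
            raise ValueError(
                f"RNA ({self.rna.shape[0]}) and ATAC ({self.atac.shape[0]}) "
                "matrices disagree on cell count"
            )
        if self.rna.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match matrix rows")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    @property
    def gene_symbols(self) -> np.ndarray:
        return self.genes.index.to_numpy()

    def subset_cells(self, keep_ids: Sequence) -> "MultiomeDataset":
        """Return a new dataset restricted to ``keep_ids`` (order preserved)."""
        pos = pd.Index(self.cell_ids).get_indexer(list(keep_ids))
        if (pos < 0).any():
            missing = [c for c, p in zip(keep_ids, pos) if p < 0]
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return replace(
            self,
            rna=self.rna[pos],
            atac=self.atac[pos],
            cell_ids=list(keep_ids),
            cell_meta=self.cell_meta.iloc[pos],
        )


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality thresholds.

    RNA thresholds are strict inequalities as printed ("genes > 200",
    "reads > 2500", "mito < 10%"); ATAC minimums are inclusive ("minimal
    number of fragments to be 1000", "minimal TSS enrichment to be 4").
    """

    min_genes: float = 200
    min_counts: float = 2500
    max_pct_mito: float = 10.0
    min_fragments: float = 1000
    min_tss_enrichment: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "min_genes",
            "min_counts",
            "max_pct_mito",
            "min_fragments",
            "min_tss_enrichment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# MatrixMarket triplets
# ---------------------------------------------------------------------------

def read_mtx_triplet(directory, features_on_rows: bool = True):
    """Read a 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv).

    Returns ``(counts, feature_ids, cell_ids)`` with counts normalised to
    cells x features orientation.  ``features_on_rows`` describes the on-disk
    orientation (10x writes features on rows).
    """
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    data = mat.tocoo().data
    if data.size and not np.allclose(data, np.round(data)):
        bad = np.flatnonzero(~np.isclose(data, np.round(data)))[0]
        raise ValueError(
            f"{directory / 'matrix.mtx'}: non-integer entry {data[bad]!r} "
            f"(nonzero #{bad})"
        )
    features = _read_single_column(directory / "features.tsv")
    barcodes = _read_single_column(directory / "barcodes.tsv")
    if features_on_rows:
        mat = mat.T
    n_cells, n_feat = mat.shape
    if n_feat != len(features):
        raise ValueError(
            f"{directory}: matrix has {n_feat} features but features.tsv "
            f"lists {len(features)}"
        )
    if n_cells != len(barcodes):
        raise ValueError(
            f"{directory}: matrix has {n_cells} cells but barcodes.tsv "
            f"lists {len(barcodes)}"
        )
    counts = sp.csr_matrix(mat)
    counts.data = counts.data.astype(np.int64).astype(np.float64)
    return counts.astype(np.int64), features, barcodes


def write_mtx_triplet(directory, counts, feature_ids, cell_ids,
                      features_on_rows: bool = True) -> None:
    """Write counts (cells x features) as a 10x-style triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts)
    if features_on_rows:
        mat = mat.T
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.Series(list(feature_ids)).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(list(cell_ids)).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def _read_single_column(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


# ---------------------------------------------------------------------------
# GMT / BED / fragments
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read GMT gene sets: name, description, members.

    Duplicate members within a line are dropped; first-seen order is kept.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = parts[0]
            members = list(dict.fromkeys(m for m in parts[2:] if m))
            sets[name] = members
    return sets


def write_gmt(path, sets: dict, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(path, intervals: pd.DataFrame) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments(path) -> pd.DataFrame:
    """Read 5-column fragment records (chrom, start, end, barcode, count)."""
    frags = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "barcode", "count"],
        comment="#",
    )
    if frags[["start", "end", "count"]].isna().any().any():
        raise ValueError(f"{path}: malformed fragment records")
    return frags


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

def compute_qc_metrics(dataset: MultiomeDataset) -> pd.DataFrame:
    """Compute n_genes, n_counts, pct_mito and n_fragments per cell.

    pct_mito is a percentage in [0, 100]; an all-zero cell gets 0.
    """
    rna = dataset.rna.tocsr()
    mito = dataset.genes["mito"].to_numpy(dtype=bool)
    n_counts = np.asarray(rna.sum(axis=1)).ravel()
    n_genes = rna.getnnz(axis=1)
    mito_counts = np.asarray(rna[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_counts > 0, 100.0 * mito_counts / np.maximum(n_counts, 1), 0.0)
    n_fragments = np.asarray(dataset.atac.sum(axis=1)).ravel()
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_counts": n_counts.astype(int),
            "pct_mito": pct_mito,
            "n_fragments": n_fragments.astype(int),
        },
        index=pd.Index(dataset.cell_ids, name="cell_id"),
    )


def compute_tss_enrichment(
    fragments: pd.DataFrame,
    tss: pd.DataFrame,
    flank: int = 2000,
    center_halfwidth: int = 50,
    background_width: int = 100,
) -> pd.DataFrame:
    """Per-barcode TSS enrichment from fragment records.

    Insertions are both fragment endpoints (positions ``start`` and
    ``end - 1`` of the half-open interval).  For every TSS the insertion
    offset is accumulated over ``[-flank, flank]`` (strand-aware); the score
    is the mean per-base coverage in ``TSS +/- center_halfwidth`` divided by
    the mean per-base coverage in the two outermost ``background_width``-bp
    windows, aggregated over all TSSs.  A zero background with nonzero
    center is reported as score 0 with ``zero_background=True``; a barcode
    with no fragments scores 0.

    Parameters
    ----------
    tss : DataFrame with columns ``chrom``, ``pos`` (0-based) and ``strand``.
    """
    barcodes = pd.unique(fragments["barcode"])
    hist_width = 2 * flank + 1
    hists = {bc: np.zeros(hist_width, dtype=np.int64) for bc in barcodes}

    tss_by_chrom = {c: g for c, g in tss.groupby("chrom")}
    for chrom, frag_group in fragments.groupby("chrom"):
        tgroup = tss_by_chrom.get(chrom)
        if tgroup is None:
            continue
        starts = frag_group["start"].to_numpy()
        ends = frag_group["end"].to_numpy() - 1  # second insertion site
        counts = frag_group["count"].to_numpy()
        bcs = frag_group["barcode"].to_numpy()
        for _, trow in tgroup.iterrows():
            sign = -1 if trow["strand"] == "-" else 1
            for ins in (starts, ends):
                off = sign * (ins - int(trow["pos"]))
                inside = np.abs(off) <= flank
                if not inside.any():
                    continue
                idx = off[inside] + flank
                for bc, i, c in zip(bcs[inside], idx, counts[inside]):
                    hists[bc][i] += c

    center = slice(flank - center_halfwidth, flank + center_halfwidth + 1)
    n_center = 2 * center_halfwidth + 1
    rows = []
    for bc in barcodes:
        h = hists[bc]
        center_cov = h[center].sum() / n_center
        bg_cov = (h[:background_width].sum() + h[-background_width:].sum()) / (
            2 * background_width
        )
        if bg_cov == 0:
            if center_cov > 0:
                warnings.warn(
                    f"barcode {bc}: zero background coverage, TSS score set to 0"
                )
            rows.append((bc, 0.0, center_cov > 0))
        else:
            rows.append((bc, center_cov / bg_cov, False))
    return pd.DataFrame(
        rows, columns=["barcode", "tss_enrichment", "zero_background"]
    ).set_index("barcode")


# ---------------------------------------------------------------------------
# Cell filtering
# ---------------------------------------------------------------------------

def filter_cells(cell_meta: pd.DataFrame, thresholds: QCThresholds | None = None) -> list:
    """Return ids of cells passing all QC thresholds.

    Kept iff n_genes > min_genes AND n_counts > min_counts AND
    pct_mito < max_pct_mito AND n_fragments >= min_fragments AND
    tss_enrichment >= min_tss_enrichment.
    """
    thresholds = thresholds or QCThresholds()
    for col in QC_COLUMNS:
        if col not in cell_meta.columns:
            raise KeyError(f"cell_meta is missing required QC column {col!r}")
    keep = (
        (cell_meta["n_genes"] > thresholds.min_genes)
        & (cell_meta["n_counts"] > thresholds.min_counts)
        & (cell_meta["pct_mito"] < thresholds.max_pct_mito)
        & (cell_meta["n_fragments"] >= thresholds.min_fragments)
        & (cell_meta["tss_enrichment"] >= thresholds.min_tss_enrichment)
    )
    return list(cell_meta.index[keep])
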