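"""Branching pseudotime over cell states.

Trajectory-informative genes (expressed in enough cells, top differential
genes between the two super-states, cell-cycle genes removed) define a PCA
space; k-means sub-centroids per state are joined by a Euclidean minimum
spanning tree; cells are projected onto tree edges and pseudotime is the
geodesic distance of the projection from the root.  Branches are the maximal
unbranched chains of the tree.  A second dataset is projected through the
reference loadings and inherits pseudotime/branch from nearest reference
cells.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "Trajectory",
    "select_trajectory_genes",
    "build_trajectory",
    "project_dataset",
    "density_along_pseudotime",
    "branch_mass",
]


@dataclass
class Trajectory:
    """Centroid-MST trajectory plus the per-cell assignment of the reference."""

    nodes: np.ndarray                # n_nodes x 10 centroid coords
    node_state: np.ndarray           # state label per node
    edges: list                      # (u, v) with u < v
    root: int
    node_pseudotime: np.ndarray      # geodesic distance from root per node
    edge_branch: dict                # (u, v) -> branch id string
    genes: np.ndarray                # trajectory gene list (ordered)
    pca_center: np.ndarray
    pca_loadings: np.ndarray         # 10 x n_genes
    cell_coords: np.ndarray          # reference cells x 10
    cell_pseudotime: np.ndarray
    cell_branch: np.ndarray          # branch id per reference cell
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if n > 1 and len(self.edges) != n - 1:
            raise ValueError("tree must have node count - 1 edges")
        if (self.cell_pseudotime < 0).any():
            raise ValueError("pseudotime must be non-negative")

    @property
    def branching_nodes(self) -> list:
        deg = Counter()
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return sorted(node for node, d in deg.items() if d >= 3)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def select_trajectory_genes(
    normed_rna,
    gene_ids,
    superstate_labels,
    cc_genes=(),
    top_n: int = 2000,
    min_cell_frac: float = 0.10,
) -> np.ndarray:
    """Trajectory-informative gene list.

    Keeps genes expressed in >= ``min_cell_frac`` of all cells, removes
    cell-cycle genes, then takes the ``top_n`` genes by super-state Wilcoxon
    adjusted p (ties by |log2FC| descending, then gene id).  Exactly two
    super-states are required.
    """
    from .differential import wilcoxon_de

    X = sp.csr_matrix(normed_rna).tocsc()
    gene_ids = np.asarray(gene_ids, dtype=object)
    labels = np.asarray(superstate_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"expected exactly 2 super-states, got {groups.size}")

    frac = X.getnnz(axis=0) / X.shape[0]
    cc = set(cc_genes)
    eligible = np.flatnonzero(frac >= min_cell_frac)
    eligible = eligible[[g not in cc for g in gene_ids[eligible]]]
    if eligible.size == 0:
        raise ValueError("no genes pass the expression-fraction filter")

    de = wilcoxon_de(
        X[:, eligible],
        gene_ids[eligible],
        labels == groups[0],
        labels == groups[1],
        min_pct=0.0,
        lfc_threshold=0.0,
    )
    de = de.assign(abs_lfc=de["log2fc"].abs()).sort_values(
        ["adj_p", "abs_lfc", "feature"],
        ascending=[True, False, True],
        kind="stable",
    )
    return de["feature"].to_numpy()[:top_n]


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _branch_decomposition(edges: list, n_nodes: int, root: int) -> dict:
    """Label every edge with the maximal unbranched chain it belongs to.

    Chains break at the root, at leaves, and at nodes of degree >= 3, so a
    fork yields one branch per arm.  Labels are "branch0", "branch1", ... in
    a deterministic order (sorted break node, then neighbor).
    """
    adj: dict = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    deg = {i: len(adj[i]) for i in adj}
    breaks = {i for i in adj if deg[i] != 2} | {root}
    if not edges:
        return {}
    edge_branch: dict = {}
    label = 0
    for start in sorted(breaks):
        for nxt in sorted(adj[start]):
            key = (min(start, nxt), max(start, nxt))
            if key in edge_branch:
                continue
            name = f"branch{label}"
            label += 1
            prev, cur = start, nxt
            edge_branch[key] = name
            while cur not in breaks:
                nxt2 = [w for w in adj[cur] if w != prev][0]
                edge_branch[(min(cur, nxt2), max(cur, nxt2))] = name
                prev, cur = cur, nxt2
    return edge_branch


def _project_cells(coords, nodes, edges, node_pt, edge_branch, root):
    """Project each cell onto the best incident edge of its nearest centroid.

    Returns (pseudotime, branch id) per cell; pseudotime is the geodesic
    distance from the root to the projection point.
    """
    n_cells = coords.shape[0]
    pt = np.zeros(n_cells)
    branch = np.empty(n_cells, dtype=object)
    if not edges:
        branch[:] = "branch0"
        return pt, branch
    incident: dict = {i: [] for i in range(len(nodes))}
    for u, v in edges:
        incident[u].append((u, v))
        incident[v].append((u, v))
    d2 = ((coords[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    for c in range(n_cells):
        best = (np.inf, 0.0, None)
        for (u, v) in incident[nearest[c]]:
            seg = nodes[v] - nodes[u]
            L2 = float(seg @ seg)
            t = 0.0 if L2 == 0 else float(
                np.clip((coords[c] - nodes[u]) @ seg / L2, 0.0, 1.0)
            )
            point = nodes[u] + t * seg
            dist = float(np.linalg.norm(coords[c] - point))
            if dist < best[0]:
                L = np.sqrt(L2)
                geo = min(node_pt[u] + t * L, node_pt[v] + (1.0 - t) * L)
                best = (dist, geo, (u, v))
        pt[c] = best[1]
        branch[c] = edge_branch[(min(best[2]), max(best[2]))]
    return pt, branch


def build_trajectory(
    normed_rna,
    gene_ids,
    trajectory_genes,
    state_labels,
    root_state,
    n_nodes_per_state: int = 3,
    n_dims: int = 10,
    seed: int = 0,
) -> Trajectory:
    """Centroid-MST trajectory over the states.

    PCA (``n_dims``) on the trajectory genes, ``n_nodes_per_state`` seeded
    k-means centroids per state, MST with Euclidean weights, root = the
    ``root_state`` centroid closest (geodesically) to the tree's degree->=2
    backbone.  Deterministic given the seed.
    """
    from .embeddings import pca

    gene_ids = np.asarray(gene_ids, dtype=object)
    labels = np.asarray(state_labels)
    states = np.unique(labels)
    if root_state not in states:
        raise ValueError(f"root state {root_state!r} not present")
    pos_of = {g: i for i, g in enumerate(gene_ids)}
    genes = np.asarray([g for g in trajectory_genes if g in pos_of], dtype=object)
    if genes.size == 0:
        raise ValueError("no trajectory genes present in the dataset")
    cols = np.asarray([pos_of[g] for g in genes], dtype=int)

    X = np.asarray(sp.csr_matrix(normed_rna).tocsc()[:, cols].todense())
    emb = pca(X, n=n_dims, seed=seed)
    coords = emb.coords

    nodes, node_state = [], []
    for s in states:
        pts = coords[labels == s]
        k = min(n_nodes_per_state, len(pts))
        if k == 1:
            centers = pts.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pts)
            centers = km.cluster_centers_[
                np.lexsort(tuple(centers_col for centers_col in
                                 km.cluster_centers_.T[::-1]))
            ]
        nodes.append(centers)
        node_state.extend([s] * len(centers))
    nodes = np.vstack(nodes)
    node_state = np.asarray(node_state)
    n_nodes = len(nodes)

    if n_nodes == 1:
        return Trajectory(
            nodes=nodes, node_state=node_state, edges=[], root=0,
            node_pseudotime=np.zeros(1), edge_branch={}, genes=genes,
            pca_center=emb.params["center"], pca_loadings=emb.params["loadings"],
            cell_coords=coords, cell_pseudotime=np.zeros(len(coords)),
            cell_branch=np.asarray(["branch0"] * len(coords), dtype=object),
            params={"n_nodes_per_state": n_nodes_per_state, "n_dims": n_dims,
                    "seed": seed, "root_state": root_state},
        )

    D = np.sqrt(((nodes[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2))
    mst = minimum_spanning_tree(D).toarray()
    edges = sorted(
        (min(u, v), max(u, v)) for u, v in zip(*np.nonzero(mst))
    )
    W = np.zeros_like(D)
    for u, v in edges:
        W[u, v] = W[v, u] = D[u, v]
    geo = shortest_path(sp.csr_matrix(W), method="D", directed=False)

    deg = Counter()
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    backbone = [i for i in range(n_nodes) if deg[i] >= 2]
    if not backbone:
        backbone = list(range(n_nodes))
    root_cands = np.flatnonzero(node_state == root_state)
    # the root is the outer end of the root state: among its leaf centroids
    # (an interior centroid cannot start the trajectory), the one nearest the
    # backbone; if every candidate is interior, fall back to all of them
    leaf_cands = [int(i) for i in root_cands if deg[i] <= 1]
    cands = leaf_cands or [int(i) for i in root_cands]
    root = int(min(cands, key=lambda i: (geo[i, backbone].min(), i)))

    node_pt = geo[root]
    edge_branch = _branch_decomposition(edges, n_nodes, root)
    cell_pt, cell_branch = _project_cells(
        coords, nodes, edges, node_pt, edge_branch, root
    )
    return Trajectory(
        nodes=nodes,
        node_state=node_state,
        edges=edges,
        root=root,
        node_pseudotime=node_pt,
        edge_branch=edge_branch,
        genes=genes,
        pca_center=emb.params["center"],
        pca_loadings=emb.params["loadings"],
        cell_coords=coords,
        cell_pseudotime=cell_pt,
        cell_branch=cell_branch,
        params={"n_nodes_per_state": n_nodes_per_state, "n_dims": n_dims,
                "seed": seed, "root_state": root_state},
    )


# ---------------------------------------------------------------------------
# projection of a second dataset
# ---------------------------------------------------------------------------

def project_dataset(new_normed_rna, new_gene_ids, trajectory: Trajectory,
                    k: int = 25, ref_labels=None) -> pd.DataFrame:
    """Map new cells into the reference trajectory space.

    Expression on the trajectory genes (missing genes imputed as 0, count
    reported in a warning) is centered with the reference means and projected
    through the reference loadings; each new cell's pseudotime is the median,
    and its branch the majority label, of its ``k`` nearest reference cells.
    When per-reference-cell ``ref_labels`` are given (e.g. state labels), the
    majority label of the same neighbors is reported as ``ref_label``, ties
    broken by the smallest label.
    """
    gene_ids = np.asarray(new_gene_ids, dtype=object)
    pos_of = {g: i for i, g in enumerate(gene_ids)}
    X = sp.csr_matrix(new_normed_rna).tocsc()
    n_cells = X.shape[0]
    cols = np.full(len(trajectory.genes), -1, dtype=int)
    for j, g in enumerate(trajectory.genes):
        cols[j] = pos_of.get(g, -1)
    n_missing = int((cols < 0).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} trajectory genes missing from new dataset; imputed 0"
        )
    expr = np.zeros((n_cells, len(trajectory.genes)))
    present = cols >= 0
    expr[:, present] = np.asarray(X[:, cols[present]].todense())
    coords = (expr - trajectory.pca_center) @ trajectory.pca_loadings.T

    k_eff = min(k, len(trajectory.cell_coords))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(trajectory.cell_coords)
    idx = nn.kneighbors(coords, return_distance=False)
    pt = np.median(trajectory.cell_pseudotime[idx], axis=1)
    def _majority(values):
        out = np.empty(n_cells, dtype=object)
        for c in range(n_cells):
            counts = Counter(values[idx[c]])
            top = max(counts.values())
            out[c] = min(b for b, n in counts.items() if n == top)
        return out

    table = pd.DataFrame(
        {"pseudotime": pt, "branch": _majority(trajectory.cell_branch)}
    )
    if ref_labels is not None:
        ref_labels = np.asarray(ref_labels)
        if len(ref_labels) != len(trajectory.cell_coords):
            raise ValueError("ref_labels length must match reference cells")
        table["ref_label"] = _majority(ref_labels)
    return table


# ---------------------------------------------------------------------------
# density and branch mass
# ---------------------------------------------------------------------------

def density_along_pseudotime(pseudotime, sample_labels, bandwidth=None,
                             grid: int = 200) -> pd.DataFrame:
    """Per-sample Gaussian KDE over the shared observed pseudotime range.

    Bandwidth defaults to Silverman's rule per sample; each curve is
    renormalized to integrate to 1 over the grid (trapezoid rule).  Returns
    a long DataFrame (sample, pseudotime, density).
    """
    t = np.asarray(pseudotime, dtype=float)
    labels = np.asarray(sample_labels)
    lo, hi = float(t.min()), float(t.max())
    if hi == lo:
        hi = lo + 1.0
    xs = np.linspace(lo, hi, grid)
    rows = []
    for s in np.unique(labels):
        v = t[labels == s]
        if bandwidth is None:
            sd = v.std(ddof=1) if v.size > 1 else 0.0
            iqr = np.subtract(*np.percentile(v, [75, 25]))
            spread = min(sd, iqr / 1.34) if iqr > 0 else sd
            bw = 0.9 * spread * v.size ** (-0.2) if spread > 0 else 0.0
        else:
            bw = float(bandwidth)
        if bw <= 0:
            bw = 1e-3 * (hi - lo)
        dens = np.exp(
            -0.5 * ((xs[:, None] - v[None, :]) / bw) ** 2
        ).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
        area = np.trapezoid(dens, xs)
        if area > 0:
            dens = dens / area
        rows.append(pd.DataFrame(
            {"sample": s, "pseudotime": xs, "density": dens}
        ))
    return pd.concat(rows, ignore_index=True)


def branch_mass(branch_ids, sample_labels=None) -> pd.DataFrame:
    """Fraction of cells per branch (per sample when labels are given)."""
    b = np.asarray(branch_ids)
    if sample_labels is None:
        sample_labels = np.asarray(["all"] * len(b))
    s = np.asarray(sample_labels)
    rows = []
    for sample in np.unique(s):
        m = s == sample
        total = int(m.sum())
        for br in np.unique(b[m]):
            rows.append(
                {"sample": sample, "branch": br,
                 "fraction": float((b[m] == br).sum()) / total}
            )
    return pd.DataFrame(rows)
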