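"""Cell-state definition: RNA clustering plus chromatin-concordance merging.

RNA clusters are communities of a shared-nearest-neighbor graph.  Clusters
whose cells are mutually mixed among each other's nearest neighbors in the
ATAC embedding are merged, so every resulting state carries a unique
signature in both modalities.  The mixing score is size-normalized: 1 means
the two clusters are as intermingled in chromatin space as random labels
would be, 0 means fully separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterPartition",
    "StatePartition",
    "snn_graph",
    "cluster_graph",
    "chromatin_similarity",
    "merge_clusters_by_chromatin",
    "split_superstates",
    "validate_dual_signatures",
    "select_surface_marker",
    "auroc",
]


@dataclass
class ClusterPartition:
    labels: np.ndarray              # contiguous ints from 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster labels must be contiguous from 0")
        self.labels = labels

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class StatePartition:
    labels: np.ndarray              # per-cell state label (contiguous ints)
    provenance: dict                # state -> frozenset of merged RNA clusters
    merge_trace: list               # ordered (cluster_a, cluster_b, score)
    cluster_labels: np.ndarray      # the RNA clusters the states came from

    def __post_init__(self) -> None:
        merged = [c for s in self.provenance.values() for c in s]
        if sorted(merged) != sorted(set(self.cluster_labels.tolist())):
            raise ValueError("provenance does not partition the cluster label set")

    @property
    def n_states(self) -> int:
        return len(self.provenance)


# ---------------------------------------------------------------------------
# SNN graph + community detection
# ---------------------------------------------------------------------------

def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    # drop self (guaranteed present with exact neighbors)
    out = np.empty((coords.shape[0], k), dtype=int)
    for i in range(coords.shape[0]):
        row = idx[i][idx[i] != i][:k]
        out[i] = row
    return out


def snn_graph(embedding: np.ndarray, k: int = 20, prune: float = 1 / 15) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Edges exist between k-NN pairs whose neighbor-set Jaccard exceeds
    ``prune``.  Raises if k >= number of cells.
    """
    coords = np.asarray(embedding, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    idx = _knn_indices(coords, k)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    # include self so Jaccard counts shared membership like Seurat's SNN
    A = ((A + sp.eye(n, format="csr")) > 0).astype(np.float64)
    inter = (A @ A.T).tocoo()
    set_size = k + 1
    jac = inter.data / (2 * set_size - inter.data)
    mask = (inter.row < inter.col) & (jac > prune)
    g = ig.Graph(
        n=n,
        edges=list(zip(inter.row[mask].tolist(), inter.col[mask].tolist())),
        edge_attrs={"weight": jac[mask].tolist()},
    )
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 1.0,
                  seed: int = 0) -> ClusterPartition:
    """Leiden modularity (RB configuration) communities at a resolution."""
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by decreasing size, ties by first occurrence
    sizes = np.bincount(labels)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    remap = np.empty(sizes.size, dtype=int)
    remap[order] = np.arange(sizes.size)
    return ClusterPartition(
        labels=remap[labels],
        params={"resolution": resolution, "seed": seed},
    )


# ---------------------------------------------------------------------------
# chromatin-space mixing and merging
# ---------------------------------------------------------------------------

def chromatin_similarity(partition: ClusterPartition, atac_embedding: np.ndarray,
                         k: int = 20) -> np.ndarray:
    """Size-normalized k-NN mixing of RNA clusters in the ATAC embedding.

    mixing[i, j] = (mean over cells of cluster i of the fraction of their
    ATAC neighbors in cluster j) / (n_j / (n-1)), symmetrized by averaging.
    Random labels give ~1; full separation gives ~0 off-diagonal.
    """
    coords = np.asarray(atac_embedding, dtype=float)
    labels = partition.labels
    if coords.shape[0] != labels.shape[0]:
        raise ValueError("partition and embedding disagree on cell count")
    n = coords.shape[0]
    n_clusters = partition.n_clusters
    idx = _knn_indices(coords, min(k, n - 1))
    neigh_labels = labels[idx]
    frac = np.zeros((n, n_clusters))
    for j in range(n_clusters):
        frac[:, j] = (neigh_labels == j).mean(axis=1)
    raw = np.zeros((n_clusters, n_clusters))
    for i in range(n_clusters):
        raw[i] = frac[labels == i].mean(axis=0)
    sizes = np.bincount(labels, minlength=n_clusters).astype(float)
    expected = sizes / (n - 1)
    mixing = raw / expected[None, :]
    return 0.5 * (mixing + mixing.T)


def merge_clusters_by_chromatin(partition: ClusterPartition, mixing: np.ndarray,
                                threshold: float = 0.5) -> StatePartition:
    """Average-linkage agglomeration of clusters over the mixing matrix.

    Merges the best pair while its linkage (mean of the original pairwise
    mixing entries between group members) is >= threshold; ties break on the
    lowest cluster-id pair.  States are labeled by order of their smallest
    member cluster id.
    """
    n_clusters = partition.n_clusters
    groups = [frozenset([i]) for i in range(n_clusters)]
    trace = []

    def linkage(a: frozenset, b: frozenset) -> float:
        return float(np.mean([mixing[i, j] for i in a for j in b]))

    while len(groups) > 1:
        best, best_pair = -np.inf, None
        for ai in range(len(groups)):
            for bi in range(ai + 1, len(groups)):
                s = linkage(groups[ai], groups[bi])
                key = (min(min(groups[ai]), min(groups[bi])),
                       max(min(groups[ai]), min(groups[bi])))
                if s > best or (s == best and best_pair is not None
                                and key < best_pair[2]):
                    best, best_pair = s, (ai, bi, key)
        if best < threshold or best_pair is None:
            break
        ai, bi, _ = best_pair
        trace.append((sorted(groups[ai]), sorted(groups[bi]), best))
        groups = (
            [g for gi, g in enumerate(groups) if gi not in (ai, bi)]
            + [groups[ai] | groups[bi]]
        )

    groups.sort(key=min)
    cluster_to_state = {}
    provenance = {}
    for state, g in enumerate(groups):
        provenance[state] = g
        for c in g:
            cluster_to_state[c] = state
    labels = np.array([cluster_to_state[c] for c in partition.labels])
    return StatePartition(
        labels=labels,
        provenance=provenance,
        merge_trace=trace,
        cluster_labels=partition.labels.copy(),
    )


def split_superstates(state_labels, embedding: np.ndarray,
                      n_groups: int = 2) -> np.ndarray:
    """Group states into super-states by average-linkage on state centroids.

    Computes state centroids in the given embedding, clusters them
    hierarchically (average linkage, Euclidean) and cuts to ``n_groups``.
    Returns a per-cell super-state label (contiguous ints ordered by the
    smallest member state).
    """
    from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

    labels = np.asarray(state_labels)
    coords = np.asarray(embedding, dtype=float)
    states = np.unique(labels)
    if states.size < n_groups:
        raise ValueError("fewer states than requested super-state groups")
    centroids = np.vstack([coords[labels == s].mean(axis=0) for s in states])
    if states.size == n_groups:
        assign = np.arange(n_groups)
    else:
        Z = scipy_linkage(centroids, method="average")
        assign = fcluster(Z, t=n_groups, criterion="maxclust") - 1
    # relabel groups by their smallest member state
    order = {}
    for g in sorted(set(assign), key=lambda g: min(states[assign == g])):
        order[g] = len(order)
    state_to_super = {s: order[a] for s, a in zip(states, assign)}
    return np.array([state_to_super[s] for s in labels])


# ---------------------------------------------------------------------------
# dual-signature validation and surface markers
# ---------------------------------------------------------------------------

def validate_dual_signatures(state_labels, normed_rna, gene_ids, atac_counts,
                             peak_ids, cell_meta, min_features: int = 10,
                             alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Count DE genes and DA peaks per state pair; pass iff both >= min_features."""
    from .differential import differential_peaks, wilcoxon_de

    labels = np.asarray(state_labels)
    states = np.unique(labels)
    rows = []
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            ma, mb = labels == a, labels == b
            de = wilcoxon_de(normed_rna, gene_ids, ma, mb)
            n_de = int((de["adj_p"] < alpha).sum())
            da = differential_peaks(
                atac_counts, peak_ids, ma, mb, cell_meta, seed=seed
            )
            n_da = int((da["adj_p"] < alpha).sum())
            rows.append(
                {
                    "state_a": a,
                    "state_b": b,
                    "n_de_genes": n_de,
                    "n_da_peaks": n_da,
                    "passed": (n_de >= min_features) and (n_da >= min_features),
                }
            )
    return pd.DataFrame(rows)


def auroc(values: np.ndarray, positive_mask: np.ndarray) -> float:
    """AUROC of ``values`` for membership in the positive class (midrank ties)."""
    values = np.asarray(values, dtype=float)
    pos = np.asarray(positive_mask, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative cells")
    ranks = rankdata(values)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def select_surface_marker(state_labels, normed_rna, gene_ids, surface_genes,
                          target_state) -> pd.DataFrame:
    """Rank candidate surface genes by AUROC for the target state.

    Returns a table (gene, auroc, pct_in, pct_out) sorted by AUROC
    descending, ties by pct_in - pct_out.
    """
    surface_genes = list(surface_genes)
    if not surface_genes:
        raise ValueError("surface gene list is empty")
    gene_ids = np.asarray(gene_ids, dtype=object)
    labels = np.asarray(state_labels)
    pos = labels == target_state
    X = sp.csr_matrix(normed_rna).tocsc()
    rows = []
    for gene in surface_genes:
        hits = np.flatnonzero(gene_ids == gene)
        if hits.size == 0:
            continue
        col = np.asarray(X[:, hits[0]].todense()).ravel()
        rows.append(
            {
                "gene": gene,
                "auroc": auroc(col, pos),
                "pct_in": float((col[pos] > 0).mean()),
                "pct_out": float((col[~pos] > 0).mean()),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no surface genes found in the dataset")
    table["gap"] = table["pct_in"] - table["pct_out"]
    table = table.sort_values(["auroc", "gap"], ascending=False, kind="stable")
    return table.drop(columns="gap").reset_index(drop=True)
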