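"""Trajectory gene selection, centroid-MST construction and projection."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from scmultistate.trajectory import (
    Trajectory,
    branch_mass,
    build_trajectory,
    density_along_pseudotime,
    project_dataset,
    select_trajectory_genes,
)


def _gene_names(p):
    return np.array([f"g{i}" for i in range(p)], dtype=object)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def test_select_genes_min_cell_frac_boundary(rng):
    n, p = 1000, 6
    X = rng.poisson(2.0, size=(n, p)).astype(float) + 1.0
    X[99:, 2] = 0.0   # expressed in exactly 9.9% of cells -> excluded
    X[100:, 3] = 0.0  # expressed in exactly 10.0% of cells -> kept
    labels = np.where(np.arange(n) < 500, "SS1", "SS2")
    genes = select_trajectory_genes(
        sp.csr_matrix(X), _gene_names(p), labels, min_cell_frac=0.10
    )
    assert "g2" not in set(genes)
    assert "g3" in set(genes)


def test_select_genes_removes_cell_cycle(rng):
    n, p = 200, 10
    X = rng.poisson(3.0, size=(n, p)).astype(float) + 1.0
    labels = np.where(np.arange(n) < 100, "SS1", "SS2")
    X[:100, 4] *= 8  # strongest separating gene... but it is a cc gene
    genes = select_trajectory_genes(
        sp.csr_matrix(X), _gene_names(p), labels, cc_genes=["g4"]
    )
    assert "g4" not in set(genes)


def test_select_genes_ranks_separating_genes_first(rng):
    n, p = 300, 30
    X = rng.poisson(3.0, size=(n, p)).astype(float) + 1.0
    labels = np.where(np.arange(n) < 150, "SS1", "SS2")
    X[:150, 7] *= 6
    X[150:, 13] *= 6
    genes = select_trajectory_genes(
        sp.csr_matrix(X), _gene_names(p), labels, top_n=2
    )
    assert set(genes) == {"g7", "g13"}


def test_select_genes_requires_two_superstates(rng):
    X = sp.csr_matrix(rng.poisson(2.0, size=(50, 5)).astype(float) + 1.0)
    with pytest.raises(ValueError):
        select_trajectory_genes(X, _gene_names(5), np.repeat("only", 50))


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _linear_dataset(rng, n=300, p=20):
    """Cells along a 1-D gradient encoded in many genes."""
    pos = np.sort(rng.random(n))
    X = np.maximum(
        pos[:, None] * rng.uniform(2, 5, size=p)[None, :]
        + rng.normal(0, 0.05, size=(n, p)) + 1.0,
        0.0,
    )
    states = np.where(pos < 0.5, "A", "B")
    return X, pos, states


def test_two_linear_blobs_give_path_and_pseudotime(rng):
    X, pos, states = _linear_dataset(rng)
    genes = _gene_names(X.shape[1])
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="A", seed=0)
    assert tr.branching_nodes == []              # a path graph
    assert len(tr.edges) == len(tr.nodes) - 1
    rho = spearmanr(tr.cell_pseudotime, pos).statistic
    assert abs(rho) >= 0.95
    assert tr.cell_pseudotime.min() >= 0


def test_trajectory_root_state_absent_raises(rng):
    X, _, states = _linear_dataset(rng, n=60)
    genes = _gene_names(X.shape[1])
    with pytest.raises(ValueError):
        build_trajectory(sp.csr_matrix(X), genes, genes, states, root_state="Z")


def test_trajectory_single_state_single_node(rng):
    X = rng.random((40, 8)) + 1.0
    genes = _gene_names(8)
    tr = build_trajectory(sp.csr_matrix(X), genes, genes,
                          np.repeat("only", 40), root_state="only",
                          n_nodes_per_state=1)
    assert len(tr.nodes) == 1 and tr.edges == []
    assert (tr.cell_pseudotime == 0).all()
    assert (tr.cell_branch == "branch0").all()


def test_planted_fork_recovered(rng):
    # trunk then two diverging arms in gene space
    n_per = 150
    t = rng.random(n_per * 3)
    arm = np.repeat([0, 1, 2], n_per)  # 0 trunk, 1/2 arms
    p = 24
    base = np.full((n_per * 3, p), 1.0)
    # trunk program decays, arm programs grow on their own gene blocks
    base[:, :8] += 3 * np.where(arm == 0, 1 - t, 0)[:, None]
    base[:, 8:16] += 4 * np.where(arm == 1, t, 0)[:, None]
    base[:, 16:] += 4 * np.where(arm == 2, t, 0)[:, None]
    X = np.maximum(base + rng.normal(0, 0.08, size=base.shape), 0.0)
    states = np.array(["trunk", "armA", "armB"])[arm]
    genes = _gene_names(p)
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="trunk", seed=1)
    assert len(tr.branching_nodes) == 1
    # the two arms end on different branches
    bA = set(tr.cell_branch[(arm == 1) & (t > 0.7)])
    bB = set(tr.cell_branch[(arm == 2) & (t > 0.7)])
    assert bA.isdisjoint(bB)


def test_pseudotime_rotation_invariant(rng):
    X, pos, states = _linear_dataset(rng, n=200, p=12)
    genes = _gene_names(12)
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="A", seed=0)
    # rotate the expression space by an orthogonal map plus a shift; distances
    # among cells are preserved, so the tree and pseudotime are too
    Q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
    Xr = X @ Q + 5.0
    # keep all values observable by the sparse container
    tr2 = build_trajectory(sp.csr_matrix(Xr), genes, genes, states,
                           root_state="A", seed=0)
    rho = spearmanr(tr.cell_pseudotime, tr2.cell_pseudotime).statistic
    assert abs(rho) > 0.99


def test_geodesics_additive_along_paths(rng):
    X, _, states = _linear_dataset(rng)
    genes = _gene_names(X.shape[1])
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="A", seed=0)
    # along a path graph, node pseudotimes differ by exactly the edge length
    for u, v in tr.edges:
        L = np.linalg.norm(tr.nodes[u] - tr.nodes[v])
        assert abs(abs(tr.node_pseudotime[u] - tr.node_pseudotime[v]) - L) < 1e-9


def test_trajectory_invariants_enforced():
    with pytest.raises(ValueError):
        Trajectory(
            nodes=np.zeros((3, 2)), node_state=np.array(["a"] * 3),
            edges=[(0, 1)], root=0, node_pseudotime=np.zeros(3),
            edge_branch={}, genes=np.array(["g"], dtype=object),
            pca_center=np.zeros(1), pca_loadings=np.zeros((2, 1)),
            cell_coords=np.zeros((1, 2)), cell_pseudotime=np.zeros(1),
            cell_branch=np.array(["branch0"], dtype=object),
        )


# ---------------------------------------------------------------------------
# projection, density, branch mass
# ---------------------------------------------------------------------------

def test_project_reference_onto_itself(rng):
    X, pos, states = _linear_dataset(rng)
    genes = _gene_names(X.shape[1])
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="A", seed=0)
    proj = project_dataset(sp.csr_matrix(X), genes, tr, k=25)
    rho = spearmanr(proj["pseudotime"], tr.cell_pseudotime).statistic
    assert rho >= 0.99


def test_project_reference_labels_majority(rng):
    X, _, states = _linear_dataset(rng)
    genes = _gene_names(X.shape[1])
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="A", seed=0)
    proj = project_dataset(sp.csr_matrix(X), genes, tr, k=15,
                           ref_labels=states)
    # projecting the reference onto itself recovers its own labels
    assert (proj["ref_label"].to_numpy() == states).mean() > 0.95
    with pytest.raises(ValueError, match="ref_labels"):
        project_dataset(sp.csr_matrix(X), genes, tr, ref_labels=states[:-1])


def test_project_missing_genes_warns(rng):
    X, _, states = _linear_dataset(rng, n=100)
    genes = _gene_names(X.shape[1])
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="A", seed=0)
    with pytest.warns(UserWarning):
        proj = project_dataset(
            sp.csr_matrix(X[:, :10]), genes[:10], tr, k=5
        )
    assert len(proj) == 100


def test_project_k_clamped_to_reference_size(rng):
    X, _, states = _linear_dataset(rng, n=40)
    genes = _gene_names(X.shape[1])
    tr = build_trajectory(sp.csr_matrix(X), genes, genes, states,
                          root_state="A", seed=0)
    proj = project_dataset(sp.csr_matrix(X), genes, tr, k=500)
    assert len(proj) == 40


def test_density_uniform_flat_and_disjoint_supports(rng):
    t = np.linspace(0, 1, 500)
    d = density_along_pseudotime(t, np.repeat("s", 500))
    mid = d[(d["pseudotime"] > 0.2) & (d["pseudotime"] < 0.8)]["density"]
    assert mid.max() / mid.min() < 1.2  # flat away from KDE edge bias
    # disjoint supports barely overlap
    t2 = np.r_[rng.uniform(0, 0.3, 300), rng.uniform(0.7, 1.0, 300)]
    lab = np.repeat(["lo", "hi"], 300)
    d2 = density_along_pseudotime(t2, lab, grid=400)
    lo = d2[d2["sample"] == "lo"].set_index("pseudotime")["density"]
    hi = d2[d2["sample"] == "hi"].set_index("pseudotime")["density"]
    overlap = np.trapezoid(np.minimum(lo, hi), lo.index)
    assert overlap < 0.01
    # each curve integrates to 1
    assert np.trapezoid(lo, lo.index) == pytest.approx(1.0, abs=1e-6)


def test_branch_mass_fractions(rng):
    b = np.array(["x"] * 30 + ["y"] * 10, dtype=object)
    s = np.array(["kpy"] * 20 + ["ky"] * 20, dtype=object)
    tab = branch_mass(b, s)
    kpy = tab[tab["sample"] == "kpy"].set_index("branch")["fraction"]
    ky = tab[tab["sample"] == "ky"].set_index("branch")["fraction"]
    assert kpy.to_dict() == {"x": 1.0}
    assert ky.to_dict() == {"x": 0.5, "y": 0.5}
    assert tab.groupby("sample")["fraction"].sum().eq(1.0).all()
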