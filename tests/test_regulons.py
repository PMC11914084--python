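"""Co-expression candidates, promoter linking, motif pruning and AUC activity."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from scmultistate.regulons import (
    aucell_scores,
    coexpression_candidates,
    differential_regulon,
    link_peaks_to_genes,
    prune_by_motif,
)


# ---------------------------------------------------------------------------
# co-expression candidates
# ---------------------------------------------------------------------------

def test_coexpression_exact_copy_ranked_first(rng):
    n = 80
    tf = rng.normal(size=n)
    X = np.column_stack([tf, tf.copy(), rng.normal(size=(n, 3))])
    genes = np.array(["tf", "copy", "a", "b", "c"], dtype=object)
    out = coexpression_candidates(sp.csr_matrix(X), genes, ["tf"], n_candidates=3)
    tab = out["tf"]
    assert tab.iloc[0]["gene"] == "copy"
    assert tab.iloc[0]["weight"] == pytest.approx(1.0, abs=1e-12)
    assert "tf" not in set(tab["gene"])  # the TF never nominates itself


def test_coexpression_null_weights_small(rng):
    X = rng.normal(size=(300, 40))
    genes = np.array([f"g{i}" for i in range(40)], dtype=object)
    out = coexpression_candidates(sp.csr_matrix(X), genes, ["g0"], n_candidates=39)
    w = out["g0"]["weight"].to_numpy()
    assert (w > 0).all()                 # only positive weights retained
    assert np.abs(w).max() < 0.35        # null correlations at n=300


def test_coexpression_drops_flat_and_missing_tf(rng):
    X = rng.normal(size=(50, 3))
    X[:, 0] = 2.0
    genes = np.array(["flat", "a", "b"], dtype=object)
    with pytest.warns(UserWarning):
        out = coexpression_candidates(sp.csr_matrix(X), genes, ["flat"])
    assert out == {}
    with pytest.warns(UserWarning):
        out = coexpression_candidates(sp.csr_matrix(X), genes, ["absent"])
    assert out == {}


def test_coexpression_negative_correlations_excluded(rng):
    n = 100
    tf = rng.normal(size=n)
    X = np.column_stack([tf, -tf])
    genes = np.array(["tf", "anti"], dtype=object)
    out = coexpression_candidates(sp.csr_matrix(X), genes, ["tf"], n_candidates=5)
    assert len(out["tf"]) == 0


# ---------------------------------------------------------------------------
# promoter-window linking
# ---------------------------------------------------------------------------

def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_link_peaks_boundary_cases():
    tss = pd.DataFrame({"chrom": ["chr1"], "pos": [1000], "gene": ["G"]})
    # inside the window
    lk = link_peaks_to_genes(_peaks([("chr1", 100, 200)]), tss, window=2000)
    assert lk.links.iloc[0].tolist() == [0, "G"]
    # entirely beyond the window
    lk = link_peaks_to_genes(_peaks([("chr1", 5000, 5100)]), tss, window=2000)
    assert lk.links.empty
    # half-open arithmetic: window is [tss-w, tss+w); peak ending exactly at
    # tss-w does not overlap, peak starting at tss+w-1 does
    lk = link_peaks_to_genes(_peaks([("chr1", -1500, -1000)]), tss, window=2000)
    assert lk.links.empty
    lk = link_peaks_to_genes(_peaks([("chr1", 2999, 3050)]), tss, window=2000)
    assert len(lk.links) == 1
    lk = link_peaks_to_genes(_peaks([("chr1", 3000, 3050)]), tss, window=2000)
    assert lk.links.empty


def test_link_peaks_multi_gene_and_chrom():
    tss = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [1000, 1500, 1000],
            "gene": ["A", "B", "C"],
        }
    )
    lk = link_peaks_to_genes(
        _peaks([("chr1", 900, 1600), ("chr2", 900, 1100)]), tss, window=2000
    )
    got = set(map(tuple, lk.links.to_numpy()))
    assert got == {(0, "A"), (0, "B"), (1, "C")}


# ---------------------------------------------------------------------------
# motif pruning
# ---------------------------------------------------------------------------

@pytest.fixture
def prune_fixture():
    candidates = {
        "tf1": pd.DataFrame(
            {"gene": ["a", "b", "c"], "weight": [0.9, 0.8, 0.7]}
        )
    }
    # peaks 0,1,2 are promoters of a,b,c; motif present on peaks 0 and 1 only
    links = link_peaks_to_genes(
        _peaks([("chr1", 900, 1100), ("chr1", 4900, 5100), ("chr1", 8900, 9100)]),
        pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1000, 5000, 9000],
                "gene": ["a", "b", "c"],
            }
        ),
        window=2000,
    )
    ann = sp.csr_matrix(np.array([[1], [1], [0]]))
    return candidates, ann, ["tf1_motif"], links


def test_prune_keeps_motif_backed_targets(prune_fixture):
    candidates, ann, names, links = prune_fixture
    rs = prune_by_motif(candidates, ann, names, links, min_targets=2)
    assert rs.targets["tf1"]["gene"].tolist() == ["a", "b"]  # "c" motifless
    row = rs.provenance.iloc[0]
    assert (row["n_candidates"], row["n_after_pruning"], row["kept"]) == (3, 2, True)


def test_prune_identity_when_all_carry_motif(prune_fixture):
    candidates, _, names, links = prune_fixture
    ann = sp.csr_matrix(np.ones((3, 1)))
    rs = prune_by_motif(candidates, ann, names, links, min_targets=1)
    pd.testing.assert_frame_equal(rs.targets["tf1"], candidates["tf1"])


def test_prune_drops_small_and_motifless_regulons(prune_fixture):
    candidates, ann, names, links = prune_fixture
    with pytest.warns(UserWarning):
        rs = prune_by_motif(candidates, ann, names, links, min_targets=3)
    assert rs.targets == {}
    assert not rs.provenance.iloc[0]["kept"]
    with pytest.warns(UserWarning):
        rs = prune_by_motif(candidates, ann, ["other_motif"], links, min_targets=1)
    assert rs.targets == {}


# ---------------------------------------------------------------------------
# AUC activity
# ---------------------------------------------------------------------------

def _brute_force_auc(x, members, top_frac):
    """Step-curve integration with expected recovery under random tie order."""
    n = x.size
    T = int(np.ceil(top_frac * n))
    # expected number of members recovered at each cutoff k = 1..T
    hits = np.zeros(T)
    from scipy.stats import rankdata

    r = rankdata(-x)  # descending midranks
    for g in members:
        # tie block of gene g spans ranks [a, b]
        ties = np.isclose(x, x[g]).sum()
        a, b = r[g] - (ties - 1) / 2.0, r[g] + (ties - 1) / 2.0
        for k in range(1, T + 1):
            if b <= k:
                hits[k - 1] += 1.0
            elif a <= k:
                hits[k - 1] += (k - a + 1.0) / ties
    max_area = sum(min(k, len(members)) for k in range(1, T + 1))
    return hits.sum() / max_area if max_area else 0.0


def test_aucell_matches_brute_force_oracle(rng):
    n_genes = 60
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    for trial in range(30):
        x = np.round(rng.normal(size=n_genes), 1)  # many ties
        members = rng.choice(n_genes, size=rng.integers(2, 8), replace=False)
        got = aucell_scores(
            sp.csr_matrix(x[None, :]), genes, {"r": genes[members].tolist()},
            top_frac=0.1,
        ).iloc[0, 0]
        assert got == pytest.approx(
            _brute_force_auc(x, members, 0.1), abs=1e-9
        ), f"trial {trial}"


def test_aucell_boundaries_exact():
    genes = np.array([f"g{i}" for i in range(100)], dtype=object)
    x = np.arange(100, 0, -1, dtype=float)  # g0 highest
    top = aucell_scores(sp.csr_matrix(x[None, :]), genes,
                        {"r": ["g0", "g1", "g2"]}, top_frac=0.05)
    assert top.iloc[0, 0] == 1.0
    bottom = aucell_scores(sp.csr_matrix(x[None, :]), genes,
                           {"r": ["g97", "g98", "g99"]}, top_frac=0.05)
    assert bottom.iloc[0, 0] == 0.0


def test_aucell_regulon_larger_than_cutoff():
    genes = np.array([f"g{i}" for i in range(100)], dtype=object)
    x = np.arange(100, 0, -1, dtype=float)
    big = aucell_scores(sp.csr_matrix(x[None, :]), genes,
                        {"r": [f"g{i}" for i in range(20)]}, top_frac=0.05)
    assert big.iloc[0, 0] == 1.0  # top 20 genes fill the whole cutoff


@given(st.integers(0, 10 ** 4))
def test_aucell_monotone_adding_top_gene(seed):
    rng = np.random.default_rng(seed)
    n_genes = 40
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    x = rng.normal(size=(1, n_genes))
    top_gene = genes[np.argmax(x[0])]  # the cell's top-ranked gene
    members = rng.choice(np.flatnonzero(genes != top_gene), size=5, replace=False)
    base = aucell_scores(sp.csr_matrix(x), genes,
                         {"r": genes[members].tolist()}, top_frac=0.25)
    grown = aucell_scores(
        sp.csr_matrix(x), genes,
        {"r": genes[members].tolist() + [top_gene]}, top_frac=0.25,
    )
    assert grown.iloc[0, 0] >= base.iloc[0, 0] - 1e-12


def test_aucell_in_unit_interval(rng):
    genes = np.array([f"g{i}" for i in range(50)], dtype=object)
    X = rng.poisson(1.0, size=(20, 50)).astype(float)
    A = aucell_scores(sp.csr_matrix(X), genes,
                      {"a": ["g1", "g2"], "b": ["g3", "g4", "g5"]})
    assert ((A >= 0) & (A <= 1)).all().all()


def test_differential_regulon_planted_and_single_state(rng):
    n = 100
    labels = np.where(np.arange(n) < 50, "A", "B")
    act = pd.DataFrame(
        {"up": np.r_[rng.normal(0.8, 0.05, 50), rng.normal(0.2, 0.05, 50)],
         "flat": rng.normal(0.5, 0.05, n)}
    )
    tab = differential_regulon(act, labels)
    hit = tab[(tab["tf"] == "up") & (tab["state"] == "A")].iloc[0]
    assert hit["enriched"] and hit["mean_auc_diff"] > 0
    assert not tab[(tab["tf"] == "up") & (tab["state"] == "B")]["enriched"].any()
    empty = differential_regulon(act, np.repeat("A", n))
    assert empty.empty
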