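"""Wilcoxon rank-sum tests against independent enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from scmultistate.differential import (
    EXACT_MAX_GROUP,
    adjust_pvalues,
    differential_peaks,
    match_cells_by_confounders,
    wilcoxon_de,
    wilcoxon_rank_sum,
)


def oracle_permutation_p(a, b):
    """Brute-force two-sided rank-sum permutation p (test-side oracle)."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    mu = n_a * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n_a].sum() - mu)
    count = total = 0
    for comb in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9:
            count += 1
    return count / total


def test_spec_example_exact():
    # distinct untied groups (1,2,3) vs (4,5,6): 2 of C(6,3)=20 assignments
    # are as extreme -> p = 0.1
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n_a = rng.integers(2, EXACT_MAX_GROUP + 1)
        n_b = rng.integers(n_a, 13)
        a = rng.integers(0, 6, n_a).astype(float)
        b = rng.integers(0, 6, n_b).astype(float)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(
            oracle_permutation_p(a, b), abs=1e-12
        )


def test_normal_mode_close_to_enumeration():
    rng = np.random.default_rng(1)
    worst = 0.0
    for _ in range(40):
        n_a = rng.integers(9, 13)
        n_b = rng.integers(9, 13)
        a = rng.normal(size=n_a)
        b = rng.normal(size=n_b) + rng.normal() * 0.5
        p = wilcoxon_rank_sum(a, b)
        p_oracle = oracle_permutation_p(a, b)
        worst = max(worst, abs(p - p_oracle))
    assert worst < 0.01


def test_identical_values_give_p_one():
    assert wilcoxon_rank_sum([1.0] * 10, [1.0] * 12) == pytest.approx(1.0)


def test_empty_group_raises():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0, 2.0])


def test_bh_matches_hand_step_up():
    rng = np.random.default_rng(2)
    p = rng.random(200)
    adj = adjust_pvalues(p, "bh")
    # hand step-up oracle
    order = np.argsort(p)
    m = len(p)
    stair = p[order] * m / np.arange(1, m + 1)
    stair = np.minimum.accumulate(stair[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = np.minimum(stair, 1.0)
    np.testing.assert_allclose(adj, expected, atol=1e-12)


def test_bonferroni():
    np.testing.assert_allclose(
        adjust_pvalues(np.array([0.01, 0.5]), "bonferroni"), [0.02, 1.0]
    )
    with pytest.raises(ValueError):
        adjust_pvalues(np.array([0.5]), "nope")


def _toy_de_matrix():
    rng = np.random.default_rng(3)
    n = 60
    X = rng.poisson(2.0, size=(2 * n, 30)).astype(float)
    X[:n, :5] *= 6  # genes 0-4 up in group A
    return sp.csr_matrix(X), np.arange(2 * n) < n


def test_wilcoxon_de_finds_planted_and_filters():
    X, mask = _toy_de_matrix()
    ids = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    tab = wilcoxon_de(X, ids, mask, ~mask)
    top = set(tab[tab["adj_p"] < 0.05]["feature"])
    assert {f"g{i}" for i in range(5)} <= top
    # untested features were filtered by min_pct / lfc
    assert len(tab) < X.shape[1]
    assert (tab["p_value"].diff().dropna() >= 0).all()  # sorted by p


def test_wilcoxon_de_symmetry():
    X, mask = _toy_de_matrix()
    ids = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    t1 = wilcoxon_de(X, ids, mask, ~mask).set_index("feature")
    t2 = wilcoxon_de(X, ids, ~mask, mask).set_index("feature")
    common = t1.index.intersection(t2.index)
    np.testing.assert_allclose(
        t1.loc[common, "log2fc"], -t2.loc[common, "log2fc"], atol=1e-12
    )
    np.testing.assert_allclose(
        t1.loc[common, "p_value"], t2.loc[common, "p_value"], atol=1e-12
    )


def test_wilcoxon_de_identical_groups_error():
    X, mask = _toy_de_matrix()
    ids = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    with pytest.raises(ValueError):
        wilcoxon_de(X, ids, mask, mask)


@given(st.integers(0, 2 ** 31 - 1))
def test_p_invariant_to_cell_order(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 5, 12).astype(float)
    b = rng.integers(0, 5, 15).astype(float)
    p1 = wilcoxon_rank_sum(a, b)
    p2 = wilcoxon_rank_sum(rng.permutation(a), rng.permutation(b))
    assert p1 == pytest.approx(p2, abs=1e-12)


def _meta(n, rng):
    return pd.DataFrame(
        {
            "tss_enrichment": rng.normal(8, 2, n),
            "n_fragments": rng.integers(1000, 5000, n),
        }
    )


def test_matching_balances_strata():
    rng = np.random.default_rng(4)
    n = 400
    meta = _meta(n, rng)
    ga = np.arange(n) < 150
    gb = ~ga
    ia, ib, report = match_cells_by_confounders(ga, gb, meta, seed=0)
    assert len(ia) == len(ib)
    assert set(ia).issubset(set(np.flatnonzero(ga)))
    assert set(ib).issubset(set(np.flatnonzero(gb)))
    # per-stratum sizes equal after matching
    assert (report["n_matched"] <= report[["n_a", "n_b"]].min(axis=1)).all()


def test_matching_no_common_stratum_raises():
    meta = pd.DataFrame(
        {"tss_enrichment": [1, 1, 9, 9], "n_fragments": [10, 10, 9000, 9000]}
    )
    ga = np.array([True, True, False, False])
    with pytest.raises(ValueError):
        match_cells_by_confounders(ga, ~ga, meta, n_bins=2)


def test_differential_peaks_runs_and_reports_matching():
    rng = np.random.default_rng(5)
    n = 300
    X = sp.csr_matrix(rng.poisson(1.0, size=(n, 40)))
    meta = _meta(n, rng)
    ga = np.arange(n) < 120
    tab, report = differential_peaks(
        X, np.arange(40), ga, ~ga, meta, return_matching=True
    )
    assert {"feature", "p_value", "adj_p"} <= set(tab.columns)
    assert (report["n_matched"] >= 0).all()
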