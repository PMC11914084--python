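"""Three-axis regulator nomination set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scmultistate.evidence_nomination import (
    EvidenceTable,
    nominate_regulators,
    venn_counts,
)


def _de(rows):
    return pd.DataFrame(rows, columns=["feature", "group", "log2fc", "adj_p"])


def _motif(rows):
    return pd.DataFrame(rows, columns=["set", "state", "mean_z_diff", "adj_p"])


def _reg(rows):
    return pd.DataFrame(rows, columns=["tf", "state", "mean_auc_diff", "adj_p"])


def _tables(de_up, motif_up, reg_up, state="S"):
    """Build the three axis tables with the given 'up' TF sets."""
    all_tfs = sorted(set(de_up) | set(motif_up) | set(reg_up))
    de = _de([(t, state, 1.0 if t in de_up else -1.0,
               0.01 if t in de_up else 0.9) for t in all_tfs])
    mt = _motif([(f"{t}_motif", state, 1.0 if t in motif_up else -1.0,
                  0.01 if t in motif_up else 0.9) for t in all_tfs])
    rg = _reg([(t, state, 1.0 if t in reg_up else -1.0,
                0.01 if t in reg_up else 0.9) for t in all_tfs])
    return de, mt, rg


def test_nominate_is_three_set_intersection():
    de, mt, rg = _tables({"A", "B"}, {"B", "C"}, {"B", "D"})
    ev = nominate_regulators(de, mt, rg, "S")
    assert ev.nominated == ["B"]
    assert ev.venn == {
        "de_only": 1, "motif_only": 1, "regulon_only": 1,
        "de_motif": 0, "de_regulon": 0, "motif_regulon": 0, "all_three": 1,
    }
    # every TF seen on any axis appears in the table
    assert set(ev.table["tf"]) == {"A", "B", "C", "D"}


def test_nominate_empty_axis_empty_nomination():
    de, mt, rg = _tables({"A", "B"}, set(), {"A"})
    ev = nominate_regulators(de, mt, rg, "S")
    assert ev.nominated == []
    assert ev.venn["all_three"] == 0


def test_nominate_restricts_to_state_and_tf_list():
    de = _de([("A", "S", 2.0, 0.001), ("A", "T", 2.0, 0.001),
              ("housekeeping", "S", 2.0, 0.001)])
    mt = _motif([("A_motif", "S", 1.0, 0.001), ("A_motif", "T", -1.0, 0.9)])
    rg = _reg([("A", "S", 0.3, 0.001), ("A", "T", -0.3, 0.9)])
    ev = nominate_regulators(de, mt, rg, "S", tf_list=["A"])
    assert ev.nominated == ["A"]
    assert "housekeeping" not in set(ev.table["tf"])
    ev_t = nominate_regulators(de, mt, rg, "T", tf_list=["A"])
    assert ev_t.nominated == []


def test_nominate_unmappable_motifs_warn():
    de, _, rg = _tables({"A"}, {"A"}, {"A"})
    mt = _motif([("A_motif", "S", 1.0, 0.001), ("weird-id", "S", 1.0, 0.001)])
    with pytest.warns(UserWarning):
        ev = nominate_regulators(de, mt, rg, "S")
    assert ev.unmapped_motifs == ["weird-id"]
    assert ev.nominated == ["A"]
    # explicit map rescues the odd id
    ev2 = nominate_regulators(
        de, mt, rg, "S", motif_to_tf={"A_motif": "A", "weird-id": "B"}
    )
    assert "B" in set(ev2.table["tf"])


def test_nominate_requires_positive_effect():
    # significant but DOWN on one axis: not nominated
    de = _de([("A", "S", -1.0, 0.001)])
    mt = _motif([("A_motif", "S", 1.0, 0.001)])
    rg = _reg([("A", "S", 0.3, 0.001)])
    ev = nominate_regulators(de, mt, rg, "S")
    assert ev.nominated == []


def test_evidence_table_invariant_enforced():
    bad = pd.DataFrame(
        {"tf": ["A"], "de_up": [True], "motif_up": [True],
         "regulon_up": [True], "nominated": [False]}
    )
    with pytest.raises(ValueError):
        EvidenceTable(table=bad)


def test_ordering_by_expression_axis_adj_p():
    de = _de([("A", "S", 1.0, 0.04), ("B", "S", 1.0, 0.001)])
    mt = _motif([("A_motif", "S", 1.0, 0.01), ("B_motif", "S", 1.0, 0.01)])
    rg = _reg([("A", "S", 0.1, 0.01), ("B", "S", 0.1, 0.01)])
    ev = nominate_regulators(de, mt, rg, "S")
    assert ev.table["tf"].tolist() == ["B", "A"]
    assert ev.nominated == ["B", "A"]


@given(
    st.sets(st.sampled_from("ABCDEFGH"), max_size=8),
    st.sets(st.sampled_from("ABCDEFGH"), max_size=8),
    st.sets(st.sampled_from("ABCDEFGH"), max_size=8),
)
def test_venn_counts_partition_the_union(a, b, c):
    v = venn_counts(a, b, c)
    assert sum(v.values()) == len(a | b | c)
    assert v["all_three"] == len(a & b & c)
    assert all(n >= 0 for n in v.values())


@given(
    st.sets(st.sampled_from("ABCDEF"), min_size=1, max_size=6),
    st.floats(0.001, 0.2),
    st.floats(0.001, 0.2),
)
def test_tightening_alpha_never_adds_nominations(tfs, lo, hi):
    alpha_lo, alpha_hi = sorted((lo, hi))
    rng = np.random.default_rng(7)
    tfs = sorted(tfs)
    de = _de([(t, "S", 1.0, rng.uniform(0, 0.25)) for t in tfs])
    mt = _motif([(f"{t}_motif", "S", 1.0, rng.uniform(0, 0.25)) for t in tfs])
    rg = _reg([(t, "S", 0.1, rng.uniform(0, 0.25)) for t in tfs])
    strict = set(nominate_regulators(de, mt, rg, "S", alpha=alpha_lo).nominated)
    loose = set(nominate_regulators(de, mt, rg, "S", alpha=alpha_hi).nominated)
    assert strict <= loose


def test_nominate_brute_force_equivalence(rng):
    # random flag tables: nomination == direct AND over all TFs
    tfs = [f"tf{i}" for i in range(12)]
    de = _de([(t, "S", rng.choice([-1.0, 1.0]), rng.choice([0.01, 0.5]))
              for t in tfs])
    mt = _motif([(f"{t}_motif", "S", rng.choice([-1.0, 1.0]),
                  rng.choice([0.01, 0.5])) for t in tfs])
    rg = _reg([(t, "S", rng.choice([-0.1, 0.1]), rng.choice([0.01, 0.5]))
               for t in tfs])
    ev = nominate_regulators(de, mt, rg, "S")
    expected = set()
    for t in tfs:
        ok = all(
            float(tab.loc[tab[key] == k, "adj_p"].iloc[0]) < 0.05
            and float(tab.loc[tab[key] == k, eff].iloc[0]) > 0
            for tab, key, eff, k in (
                (de, "feature", "log2fc", t),
                (mt, "set", "mean_z_diff", f"{t}_motif"),
                (rg, "tf", "mean_auc_diff", t),
            )
        )
        if ok:
            expected.add(t)
    assert set(ev.nominated) == expected
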