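"""Three-axis TF regulator nomination.

A transcription factor is nominated as a regulator of a state when it is
significantly up in that state on all three evidence axes: its own
expression (differential expression), its motif accessibility (deviation
z-score enrichment), and its target set expression (regulon activity
enrichment).  Venn counts report all seven regions of the three axis sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EvidenceTable", "nominate_regulators", "venn_counts"]

VENN_REGIONS = (
    "de_only",
    "motif_only",
    "regulon_only",
    "de_motif",
    "de_regulon",
    "motif_regulon",
    "all_three",
)


@dataclass
class EvidenceTable:
    """Per-TF evidence flags for one state plus the nomination result."""

    table: pd.DataFrame          # tf, de_up, de_adj_p, motif_up, motif_adj_p,
    #                              regulon_up, regulon_adj_p, nominated
    state: object = None
    nominated: list = field(default_factory=list)
    venn: dict = field(default_factory=dict)
    unmapped_motifs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        agree = t["nominated"] == (t["de_up"] & t["motif_up"] & t["regulon_up"])
        if not agree.all():
            raise ValueError("nominated flag must equal the three-axis AND")


def _axis_sets(table: pd.DataFrame, key_col: str, p_col: str,
               effect_col: str, alpha: float):
    """Up-set and adj-p lookup for one evidence axis restricted to a state."""
    up = set()
    pmap = {}
    for _, row in table.iterrows():
        k = row[key_col]
        pmap[k] = min(float(row[p_col]), pmap.get(k, np.inf))
        if float(row[p_col]) < alpha and float(row[effect_col]) > 0:
            up.add(k)
    return up, pmap


def venn_counts(set_a: set, set_b: set, set_c: set) -> dict:
    """Sizes of the 7 regions of a three-set Venn diagram (a=DE, b=motif, c=regulon)."""
    return {
        "de_only": len(set_a - set_b - set_c),
        "motif_only": len(set_b - set_a - set_c),
        "regulon_only": len(set_c - set_a - set_b),
        "de_motif": len((set_a & set_b) - set_c),
        "de_regulon": len((set_a & set_c) - set_b),
        "motif_regulon": len((set_b & set_c) - set_a),
        "all_three": len(set_a & set_b & set_c),
    }


def nominate_regulators(
    de_table: pd.DataFrame,
    motif_table: pd.DataFrame,
    regulon_table: pd.DataFrame,
    state,
    tf_list=None,
    motif_to_tf: dict | None = None,
    alpha: float = 0.05,
) -> EvidenceTable:
    """Intersect the three evidence axes for one state.

    ``de_table`` is a per-state DE table with columns (feature, group,
    log2fc, adj_p) where ``group`` names the state; ``motif_table`` and
    ``regulon_table`` come from the motif/regulon enrichment functions with
    columns (set|tf, state, mean-effect, adj_p).  ``motif_to_tf`` maps motif
    ids to TF symbols (default strips a ``_motif`` suffix); unmappable motif
    ids are excluded with a warning.  ``tf_list`` restricts the DE axis to
    known TFs (otherwise every DE feature is a candidate).
    """
    de = de_table[de_table["group"] == state] if "group" in de_table else de_table
    if tf_list is not None:
        keep = set(tf_list)
        de = de[de["feature"].isin(keep)]
    de_up, de_p = _axis_sets(de, "feature", "adj_p", "log2fc", alpha)

    mt = motif_table[motif_table["state"] == state]
    unmapped = []
    mapped_rows = []
    for _, row in mt.iterrows():
        m = row["set"]
        if motif_to_tf is not None:
            tf = motif_to_tf.get(m)
        else:
            tf = m[: -len("_motif")] if str(m).endswith("_motif") else None
        if tf is None:
            unmapped.append(m)
            continue
        mapped_rows.append({"tf": tf, "adj_p": row["adj_p"],
                            "effect": row["mean_z_diff"]})
    if unmapped:
        warnings.warn(f"{len(unmapped)} motif ids could not be mapped to TFs")
    mt_mapped = pd.DataFrame(mapped_rows, columns=["tf", "adj_p", "effect"])
    motif_up, motif_p = _axis_sets(mt_mapped, "tf", "adj_p", "effect", alpha)

    rt = regulon_table[regulon_table["state"] == state]
    reg_up, reg_p = _axis_sets(rt, "tf", "adj_p", "mean_auc_diff", alpha)

    all_tfs = sorted(set(de_p) | set(motif_p) | set(reg_p))
    rows = []
    for tf in all_tfs:
        rows.append(
            {
                "tf": tf,
                "de_up": tf in de_up,
                "de_adj_p": de_p.get(tf, np.nan),
                "motif_up": tf in motif_up,
                "motif_adj_p": motif_p.get(tf, np.nan),
                "regulon_up": tf in reg_up,
                "regulon_adj_p": reg_p.get(tf, np.nan),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["tf", "de_up", "de_adj_p", "motif_up", "motif_adj_p",
                 "regulon_up", "regulon_adj_p"],
    )
    if table.empty:
        table["nominated"] = pd.Series(dtype=bool)
    else:
        table["nominated"] = table["de_up"] & table["motif_up"] & table["regulon_up"]
        # deterministic ordering by the expression axis's adjusted p
        table = table.sort_values(
            ["de_adj_p", "tf"], kind="stable", na_position="last"
        ).reset_index(drop=True)
    nominated = table.loc[table["nominated"], "tf"].tolist()
    return EvidenceTable(
        table=table,
        state=state,
        nominated=nominated,
        venn=venn_counts(de_up, motif_up, reg_up),
        unmapped_motifs=unmapped,
    )
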