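"""Generator contracts: determinism, planted structure, null calibration."""

import numpy as np
import pytest

from scmultistate.io_qc import QCThresholds, compute_qc_metrics
from scmultistate.synthetic_multiome import (
    HMGA2_TFS,
    SPC_TFS,
    SimConfig,
    generate_truth,
    simulate_atac,
    simulate_dataset,
    simulate_rna,
)

SMALL = dict(n_cells=700, n_genes=2000, n_peaks=10000, seed=3)


def _null_config(**kw):
    """All planted effect sizes zeroed."""
    return SimConfig(
        state_logfc=0.0,
        marker_logfc_multiplier=0.0,
        program_logfc_multiplier=0.0,
        tf_gain_mean=0.0,
        tf_logfc_multiplier=0.0,
        peak_accessibility_shift=0.0,
        **kw,
    )


# ---------------------------------------------------------------------------
# determinism and counts
# ---------------------------------------------------------------------------

def test_simulate_dataset_bit_identical():
    a_ds, a_tr = simulate_dataset(SimConfig(**SMALL))
    b_ds, b_tr = simulate_dataset(SimConfig(**SMALL))
    assert (a_ds.rna != b_ds.rna).nnz == 0
    assert (a_ds.atac != b_ds.atac).nnz == 0
    np.testing.assert_array_equal(a_tr.state_label, b_tr.state_label)
    np.testing.assert_array_equal(a_tr.latent_time, b_tr.latent_time)
    np.testing.assert_array_equal(a_tr.base_expr, b_tr.base_expr)
    assert a_tr.planted_regulons == b_tr.planted_regulons
    assert a_ds.cell_ids == b_ds.cell_ids


def test_exact_counts_reproduce_design_sizes():
    truth = generate_truth(SimConfig(exact_counts=True))
    sizes = [int((truth.state_label == s).sum()) for s in ("G1", "G2", "G3", "G4")]
    assert sizes == [773, 2514, 4367, 769]


def test_multinomial_counts_within_four_sigma():
    cfg = SimConfig(**SMALL)
    truth = generate_truth(cfg)
    props = np.asarray(cfg.state_proportions)
    n = cfg.n_cells
    for s, p in zip(("G1", "G2", "G3", "G4"), props):
        got = (truth.state_label == s).sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(got - n * p) <= 4 * sd


def test_zero_planted_regulators_ok():
    truth = generate_truth(
        SimConfig(n_planted_regulators_per_superstate=0, **SMALL)
    )
    assert truth.planted_regulons == {}


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(state_proportions=(0.5, 0.5, 0.1, 0.0))
    with pytest.raises(ValueError):
        SimConfig(n_genes=500)  # gene plan cannot fit
    with pytest.raises(ValueError):
        SimConfig(nb_dispersion=0.0)
    with pytest.raises(ValueError):
        SimConfig(preset="nonsense")
    with pytest.raises(ValueError):
        SimConfig(n_peaks=100)  # fewer peaks than genes


# ---------------------------------------------------------------------------
# planted structure
# ---------------------------------------------------------------------------

def test_truth_layout_and_latent_time():
    truth = generate_truth(SimConfig(**SMALL))
    assert set(truth.planted_regulons) == set(SPC_TFS) | set(HMGA2_TFS)
    # regulons are disjoint and of the configured size
    all_targets = [g for t in truth.planted_regulons.values() for g in t]
    assert len(all_targets) == len(set(all_targets)) == 50 * 10
    assert truth.planted_marker_gene == "Cd44"
    assert (truth.latent_time >= 0).all() and (truth.latent_time <= 1).all()
    # branch ids follow the sub-state lineage layout
    for s, br in (("G1", "trunk"), ("G2", "spc"), ("G3", "hmga2"), ("G4", "hmga2")):
        assert set(truth.branch_id[truth.state_label == s]) == {br}
    # trunk cells precede the split; branch cells follow it
    split = 0.3
    assert truth.latent_time[truth.branch_id == "trunk"].max() <= split
    assert truth.latent_time[truth.branch_id != "trunk"].min() >= split


def test_marker_direction_over_seeds():
    for seed in (0, 1, 2):
        cfg = SimConfig(n_cells=700, seed=seed)
        ds, truth = simulate_dataset(cfg)
        col = int(np.flatnonzero(ds.gene_symbols == "Cd44")[0])
        expr = np.asarray(ds.rna[:, col].todense()).ravel()
        hm = truth.superstate_label == "Hmga2-high"
        assert expr[hm].mean() > expr[~hm].mean()


def test_motif_peaks_more_accessible_in_superstate():
    cfg = SimConfig(**SMALL)
    truth = generate_truth(cfg)
    atac, *_ = simulate_atac(truth, cfg)
    X = np.asarray(atac.todense(), dtype=float)
    X /= X.sum(axis=1, keepdims=True)  # depth-normalized
    for tf in ("Cebpa", "Tcf12"):
        pk = truth.motif_peak_sets[tf]
        m = truth.superstate_label == truth.tf_superstate[tf]
        assert X[np.ix_(m, pk)].mean() > X[np.ix_(~m, pk)].mean()


def test_ky_preset_depletes_g4_and_shares_features():
    kpy_ds, kpy_tr = simulate_dataset(SimConfig(**SMALL))
    ky_ds, ky_tr = simulate_dataset(SimConfig(preset="ky", **SMALL))
    assert (ky_tr.state_label == "G4").sum() == 0
    np.testing.assert_array_equal(kpy_tr.gene_names, ky_tr.gene_names)
    assert kpy_tr.peaks.equals(ky_tr.peaks)
    assert (kpy_tr.motif_annotation != ky_tr.motif_annotation).nnz == 0
    assert kpy_tr.planted_regulons == ky_tr.planted_regulons
    # only the cell draws differ
    assert ky_ds.rna.shape == (700, 2000)


def test_lowquality_cells_violate_a_qc_threshold():
    ds, truth = simulate_dataset(SimConfig(**SMALL))
    meta = ds.cell_meta
    thr = QCThresholds()
    fails = (
        (meta["n_genes"] <= thr.min_genes)
        | (meta["n_counts"] <= thr.min_counts)
        | (meta["pct_mito"] >= thr.max_pct_mito)
        | (meta["n_fragments"] < thr.min_fragments)
        | (meta["tss_enrichment"] < thr.min_tss_enrichment)
    ).to_numpy()
    assert fails[truth.lowquality_flags].all()
    # and good cells overwhelmingly pass
    assert fails[~truth.lowquality_flags].mean() < 0.05


def test_rna_atac_share_cell_ordering():
    ds, truth = simulate_dataset(SimConfig(**SMALL))
    assert ds.rna.shape[0] == ds.atac.shape[0] == len(ds.cell_ids)
    meta = compute_qc_metrics(ds)
    np.testing.assert_array_equal(meta.index.to_numpy(), np.array(ds.cell_ids))


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def test_null_model_wilcoxon_false_positive_rate():
    from scmultistate.differential import wilcoxon_de
    from scmultistate.embeddings import normalize_log1p

    cfg = _null_config(n_cells=1200, seed=5, frac_lowquality_cells=0.0)
    ds, truth = simulate_dataset(cfg)
    normed = normalize_log1p(ds.rna)
    ga = np.isin(truth.state_label, ("G1", "G2"))
    de = wilcoxon_de(normed, ds.gene_symbols, ga, ~ga,
                     min_pct=0.0, lfc_threshold=0.0)
    fp = (de["p_value"] < 0.05).mean()
    n = len(de)
    assert n >= 2000
    # within 4 binomial standard errors of the nominal rate
    assert abs(fp - 0.05) <= 4 * np.sqrt(0.05 * 0.95 / n)
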