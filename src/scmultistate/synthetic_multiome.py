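"""Paired RNA+ATAC simulator with planted ground truth.

Emulates the statistical structure of a tumor-organoid multiome experiment:
four sub-states (G1..G4) forming two super-states (SPC-high = {G1, G2},
Hmga2-high = {G3, G4}), planted transcription-factor regulators whose motifs
open chromatin and whose targets co-express, a planted surface marker
separating the super-states, and a branching latent time (a trunk rooted in
the most AT2-like sub-state that forks into an SPC lineage and an Hmga2/EMT
lineage).

RNA counts are negative-binomial with lognormal library sizes; ATAC peak
counts are Poisson with per-peak logistic accessibility.  The generator
returns both the dataset and a :class:`SyntheticTruth` ledger that every
downstream recovery test reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logit

from .io_qc import MultiomeDataset, compute_qc_metrics, write_bed, write_mtx_triplet

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SPC_TFS",
    "HMGA2_TFS",
    "generate_truth",
    "simulate_rna",
    "simulate_atac",
    "simulate_dataset",
    "simulate_fragments",
    "write_dataset",
]

SPC_TFS = ("Cebpa", "Foxa2", "Nkx2-1", "Stat3")
HMGA2_TFS = ("Tcf12", "Tcf4", "Sox4", "Rel", "Nfkb1", "Hivep2")

STATES = ("G1", "G2", "G3", "G4")
DEFAULT_PROPORTIONS = (773 / 8423, 2514 / 8423, 4367 / 8423, 769 / 8423)
# KY (Kras-only) organoids: Group 4 depleted and the composition shifted
# toward the SPC-high super-state.
KY_PROPORTIONS = (0.25, 0.55, 0.20, 0.0)
DEFAULT_SUPERSTATE_MAP = {
    "G1": "SPC-high",
    "G2": "SPC-high",
    "G3": "Hmga2-high",
    "G4": "Hmga2-high",
}
# latent-time window per sub-state; G1 occupies the shared trunk
TAU_WINDOWS = {"G1": (0.0, None), "G2": (None, 1.0), "G3": (None, 0.7), "G4": (0.65, 1.0)}
BRANCH_OF_STATE = {"G1": "trunk", "G2": "spc", "G3": "hmga2", "G4": "hmga2"}


@dataclass
class SimConfig:
    """Parameters of the synthetic multiome experiment."""

    n_cells: int = 8423
    state_proportions: tuple = DEFAULT_PROPORTIONS
    superstate_map: dict = field(default_factory=lambda: dict(DEFAULT_SUPERSTATE_MAP))
    n_genes: int = 2000
    n_peaks: int = 10000
    n_tfs: int = 50
    n_planted_regulators_per_superstate: Optional[int] = None
    regulon_size: int = 50
    # effect sizes
    state_logfc: float = 1.0          # log2, sub-/super-state markers
    marker_logfc_multiplier: float = 2.5   # surface marker (FACS-separable)
    program_logfc_multiplier: float = 4.0  # trunk / branch latent-time programs
    branch_onset_max: float = 0.6     # latest switch-on point of branch programs
    tf_target_coupling: float = 0.8   # beta in (1 + beta * activity)
    tf_gain_mean: float = 2.0         # overall scale of the TF activity
    tf_gain_sigma: float = 0.4        # spread of the per-(cell, TF) lognormal gain
    tf_wave_amp: float = 0.95         # amplitude of the activity wave along latent time
    tf_logfc_multiplier: float = 2.0  # extra log2 shift of the TF's own gene
    tf_base_expr_range: tuple = (0.5, 3.0)  # TFs are lowly expressed genes
    target_base_expr_range: tuple = (4.0, 8.0)  # regulon targets are moderately expressed
    peak_accessibility_shift: float = 2.0  # log-odds
    # noise / depth
    nb_dispersion: float = 4.0
    library_size_lognormal: tuple = (np.log(9000.0), 0.25)
    atac_depth_lognormal: tuple = (np.log(15.0), 0.30)
    cc_factor_sigma: float = 0.4
    # composition
    frac_mito_genes: float = 0.02
    frac_lowquality_cells: float = 0.05
    mito_frac_good: float = 0.015
    lowquality_mito_boost: float = 20.0
    lowquality_depth_factor: float = 0.15
    # gene-plan block sizes
    n_state_markers: int = 120
    n_superstate_markers: int = 100
    n_program_genes: int = 120
    n_branch_genes: int = 120
    n_cc_genes: int = 40
    # peak plan
    n_da_peaks_per_state: int = 200
    n_motif_distal_peaks: int = 150
    n_decoy_motif_peaks: int = 200
    # branch structure
    branch_split_time: float = 0.3
    exact_counts: bool = False
    preset: str = "kpy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("kpy", "ky"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset == "ky" and tuple(self.state_proportions) == DEFAULT_PROPORTIONS:
            self.state_proportions = KY_PROPORTIONS
        self.validate()

    def validate(self) -> None:
        props = np.asarray(self.state_proportions, dtype=float)
        if props.shape != (4,):
            raise ValueError("state_proportions must have 4 entries")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"state_proportions sum to {props.sum()!r}, not 1")
        if (props < 0).any():
            raise ValueError("state_proportions must be non-negative")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        n_planted = len(self.planted_tfs()[0]) + len(self.planted_tfs()[1])
        if n_planted > self.n_tfs:
            raise ValueError("more planted regulators than TFs")
        if self._gene_budget() > self.n_genes:
            raise ValueError(
                f"gene plan needs {self._gene_budget()} genes (regulons included) "
                f"but n_genes={self.n_genes}"
            )
        if self.n_peaks < self.n_genes:
            raise ValueError("need at least one promoter peak per gene (n_peaks >= n_genes)")
        if not 0 < self.branch_split_time < 1:
            raise ValueError("branch_split_time must lie in (0, 1)")

    def planted_tfs(self) -> tuple:
        """(SPC-high TF names, Hmga2-high TF names)."""
        k = self.n_planted_regulators_per_superstate
        if k is None:
            return list(SPC_TFS), list(HMGA2_TFS)
        return (
            [f"Tf-spc{i}" for i in range(k)],
            [f"Tf-hmga{i}" for i in range(k)],
        )

    def _gene_budget(self) -> int:
        spc, hm = self.planted_tfs()
        n_mito = int(round(self.frac_mito_genes * self.n_genes))
        return (
            self.n_tfs
            + 4 * self.n_state_markers
            + 2 * self.n_superstate_markers
            + self.n_program_genes
            + 2 * self.n_branch_genes
            + (len(spc) + len(hm)) * self.regulon_size
            + n_mito
            + 2 * self.n_cc_genes
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: the ledger all recovery tests read."""

    # per-cell
    state_label: np.ndarray
    superstate_label: np.ndarray
    latent_time: np.ndarray
    branch_id: np.ndarray
    lowquality_flags: np.ndarray
    cell_ids: list
    # genes
    gene_names: np.ndarray
    gene_roles: pd.DataFrame           # role / role_key per gene
    base_expr: np.ndarray
    mito_flags: np.ndarray
    planted_marker_gene: str
    marker_gene_sets: dict             # sub-/super-state -> gene name list
    program_gene_sets: dict            # origin / spc_branch / hmga2_branch / s / g2m
    planted_regulons: dict             # TF -> list of target gene names
    tf_names: list
    tf_superstate: dict                # planted TF -> super-state
    # peaks
    peaks: pd.DataFrame                # chrom, start, end
    peak_gc: np.ndarray
    peak_base_logit: np.ndarray
    peak_gene_links: pd.DataFrame      # peak_idx, gene
    tss_table: pd.DataFrame            # gene, chrom, pos, strand
    motif_names: list
    motif_annotation: sp.csr_matrix    # peaks x motifs, binary
    da_peak_sets: dict                 # sub-state -> peak index array
    motif_peak_sets: dict              # TF -> peak index array (shifted peaks)

    @property
    def superstates(self) -> list:
        return sorted(set(DEFAULT_SUPERSTATE_MAP.values()))


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def _state_counts(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    props = np.asarray(config.state_proportions, dtype=float)
    if config.exact_counts:
        raw = props * config.n_cells
        base = np.floor(raw).astype(int)
        rem = config.n_cells - base.sum()
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
        return base
    return rng.multinomial(config.n_cells, props)


def generate_truth(config: SimConfig) -> SyntheticTruth:
    """Draw the full latent plan: feature layout and per-cell labels.

    Feature-level structure (gene roles, peak layout, motif annotation,
    regulons) depends only on (seed, feature-plan sizes), so two presets at
    the same seed share genes, peaks and motifs and differ only in the cell
    draws.
    """
    config.validate()
    rng_feat = np.random.default_rng(config.seed)

    # ---- gene plan -------------------------------------------------------
    spc_tfs, hm_tfs = config.planted_tfs()
    planted = list(spc_tfs) + list(hm_tfs)
    n_decoy = config.n_tfs - len(planted)
    tf_names = planted + [f"Tf-decoy{i:02d}" for i in range(n_decoy)]
    n_mito = int(round(config.frac_mito_genes * config.n_genes))

    roles: list = []

    def take(n, role, key):
        start = len(roles)
        roles.extend((role, key) for _ in range(n))
        return np.arange(start, start + n)

    tf_idx = take(config.n_tfs, "tf", "")
    state_marker_idx = {s: take(config.n_state_markers, "state_marker", s) for s in STATES}
    super_marker_idx = {
        ss: take(config.n_superstate_markers, "superstate_marker", ss)
        for ss in ("SPC-high", "Hmga2-high")
    }
    origin_idx = take(config.n_program_genes, "origin_program", "trunk")
    branch_idx = {
        "spc": take(config.n_branch_genes, "branch_program", "spc"),
        "hmga2": take(config.n_branch_genes, "branch_program", "hmga2"),
    }
    regulon_idx = {tf: take(config.regulon_size, "regulon_target", tf) for tf in planted}
    mito_idx = take(n_mito, "mito", "")
    s_idx = take(config.n_cc_genes, "cell_cycle", "s")
    g2m_idx = take(config.n_cc_genes, "cell_cycle", "g2m")
    take(config.n_genes - len(roles), "noise", "")

    gene_roles = pd.DataFrame(roles, columns=["role", "role_key"])
    gene_names = np.array([f"Gene{i:05d}" for i in range(config.n_genes)], dtype=object)
    gene_names[tf_idx] = tf_names
    # the planted surface marker is the first Hmga2-high super-state marker
    marker_gene_pos = int(super_marker_idx["Hmga2-high"][0])
    gene_names[marker_gene_pos] = "Cd44"
    gene_names[mito_idx] = [f"mt-Gene{i:03d}" for i in range(n_mito)]

    base_expr = np.clip(rng_feat.lognormal(0.0, 1.0, config.n_genes), 0.2, 20.0)
    # TF genes (planted and decoy alike) live in a low-expression regime where
    # fold changes survive the log-scale compression of downstream statistics
    lo, hi = config.tf_base_expr_range
    base_expr[tf_idx] = np.clip(base_expr[tf_idx], lo, hi)
    # regulon targets sit in a moderate expression regime where the activity
    # coupling is observable above counting noise
    if planted:
        t_lo, t_hi = config.target_base_expr_range
        all_targets = np.concatenate([regulon_idx[tf] for tf in planted])
        base_expr[all_targets] = np.clip(base_expr[all_targets], t_lo, t_hi)
    mito_flags = np.zeros(config.n_genes, dtype=bool)
    mito_flags[mito_idx] = True
    # calibrate mito share of the per-cell mean to mito_frac_good
    if n_mito:
        non_mito_total = base_expr[~mito_flags].sum()
        target = config.mito_frac_good / (1 - config.mito_frac_good) * non_mito_total
        base_expr[mito_idx] *= target / base_expr[mito_idx].sum()

    # ---- peak plan -------------------------------------------------------
    n_chroms = 5
    genes_per_chrom = -(-config.n_genes // n_chroms)
    gene_chrom = np.array([f"chr{i // genes_per_chrom + 1}" for i in range(config.n_genes)])
    gene_pos_in_chrom = np.arange(config.n_genes) % genes_per_chrom
    gene_spacing = 10000
    tss_pos = 5000 + gene_pos_in_chrom * gene_spacing
    strand = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    tss_table = pd.DataFrame(
        {"gene": gene_names, "chrom": gene_chrom, "pos": tss_pos, "strand": strand}
    )

    peak_rows = [
        (gene_chrom[i], int(tss_pos[i] - 500), int(tss_pos[i] + 500))
        for i in range(config.n_genes)
    ]
    n_distal = config.n_peaks - config.n_genes
    per_gene = -(-n_distal // config.n_genes)
    made = 0
    for i in range(config.n_genes):
        for k in range(per_gene):
            if made >= n_distal:
                break
            start = int(tss_pos[i] + 2600 + 700 * k)
            peak_rows.append((gene_chrom[i], start, start + 400))
            made += 1
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    order = np.lexsort((peaks["start"].to_numpy(), peaks["chrom"].to_numpy()))
    # remap: promoter peak of gene i must be tracked through the sort
    inv = np.empty(len(order), dtype=int)
    inv[order] = np.arange(len(order))
    peaks = peaks.iloc[order].reset_index(drop=True)
    promoter_peak_of_gene = inv[np.arange(config.n_genes)]
    distal_pool = inv[np.arange(config.n_genes, config.n_peaks)]

    peak_gc = rng_feat.beta(10, 10, config.n_peaks)
    peak_base_logit = rng_feat.normal(logit(0.02), 0.5, config.n_peaks)

    peak_gene_links = pd.DataFrame(
        {"peak_idx": promoter_peak_of_gene, "gene": gene_names}
    )

    # sub-state differential-accessibility peak sets (distal, disjoint)
    shuffled = rng_feat.permutation(distal_pool)
    da_peak_sets, pos = {}, 0
    for s in STATES:
        da_peak_sets[s] = np.sort(shuffled[pos : pos + config.n_da_peaks_per_state])
        pos += config.n_da_peaks_per_state
    remaining_distal = np.sort(shuffled[pos:])

    # motif annotation: one motif per TF
    motif_names = [f"{tf}_motif" for tf in tf_names]
    tf_superstate = {tf: "SPC-high" for tf in spc_tfs}
    tf_superstate.update({tf: "Hmga2-high" for tf in hm_tfs})
    ann_rows, ann_cols = [], []
    motif_peak_sets = {}
    for j, tf in enumerate(tf_names):
        if tf in regulon_idx:
            promoters = promoter_peak_of_gene[regulon_idx[tf]]
            distal = rng_feat.choice(
                remaining_distal, size=min(config.n_motif_distal_peaks, remaining_distal.size),
                replace=False,
            )
            pk = np.unique(np.concatenate([promoters, distal]))
            motif_peak_sets[tf] = pk
        else:
            pk = np.unique(
                rng_feat.choice(
                    remaining_distal,
                    size=min(config.n_decoy_motif_peaks, remaining_distal.size),
                    replace=False,
                )
            )
        ann_rows.extend(pk.tolist())
        ann_cols.extend([j] * pk.size)
    motif_annotation = sp.csr_matrix(
        (np.ones(len(ann_rows), dtype=np.int8), (ann_rows, ann_cols)),
        shape=(config.n_peaks, config.n_tfs),
    )

    planted_regulons = {
        tf: [gene_names[g] for g in regulon_idx[tf]] for tf in planted
    }
    marker_gene_sets = {s: [gene_names[g] for g in state_marker_idx[s]] for s in STATES}
    marker_gene_sets.update(
        {ss: [gene_names[g] for g in super_marker_idx[ss]] for ss in super_marker_idx}
    )
    program_gene_sets = {
        "origin": [gene_names[g] for g in origin_idx],
        "spc_branch": [gene_names[g] for g in branch_idx["spc"]],
        "hmga2_branch": [gene_names[g] for g in branch_idx["hmga2"]],
        "s_genes": [gene_names[g] for g in s_idx],
        "g2m_genes": [gene_names[g] for g in g2m_idx],
    }

    # ---- cell plan -------------------------------------------------------
    rng_cell = np.random.default_rng([config.seed, 1])
    counts = _state_counts(config, rng_cell)
    state_label = np.repeat(np.array(STATES, dtype=object), counts)
    perm = rng_cell.permutation(config.n_cells)
    state_label = state_label[perm]
    superstate_label = np.array(
        [config.superstate_map[s] for s in state_label], dtype=object
    )
    branch_id = np.array([BRANCH_OF_STATE[s] for s in state_label], dtype=object)

    t0 = config.branch_split_time
    windows = {
        "G1": (0.0, t0),
        "G2": (t0, 1.0),
        "G3": (t0, 0.7),
        "G4": (0.65, 1.0),
    }
    latent_time = np.empty(config.n_cells)
    for s in STATES:
        m = state_label == s
        lo, hi = windows[s]
        latent_time[m] = rng_cell.uniform(lo, hi, m.sum())

    n_low = int(round(config.frac_lowquality_cells * config.n_cells))
    lowquality_flags = np.zeros(config.n_cells, dtype=bool)
    lowquality_flags[rng_cell.choice(config.n_cells, n_low, replace=False)] = True

    cell_ids = [f"{config.preset.upper()}-{i:05d}" for i in range(config.n_cells)]

    return SyntheticTruth(
        state_label=state_label,
        superstate_label=superstate_label,
        latent_time=latent_time,
        branch_id=branch_id,
        lowquality_flags=lowquality_flags,
        cell_ids=cell_ids,
        gene_names=gene_names,
        gene_roles=gene_roles,
        base_expr=base_expr,
        mito_flags=mito_flags,
        planted_marker_gene="Cd44",
        marker_gene_sets=marker_gene_sets,
        program_gene_sets=program_gene_sets,
        planted_regulons=planted_regulons,
        tf_names=tf_names,
        tf_superstate=tf_superstate,
        peaks=peaks,
        peak_gc=peak_gc,
        peak_base_logit=peak_base_logit,
        peak_gene_links=peak_gene_links,
        tss_table=tss_table,
        motif_names=motif_names,
        motif_annotation=motif_annotation,
        da_peak_sets=da_peak_sets,
        motif_peak_sets=motif_peak_sets,
    )


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------

def _gene_index_by_role(truth: SyntheticTruth, role: str, key: str) -> np.ndarray:
    r = truth.gene_roles
    return np.flatnonzero((r["role"] == role) & (r["role_key"] == key)).astype(int)


def _rna_mean_factors(truth: SyntheticTruth, config: SimConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-cell x gene multiplicative effect on the base expression.

    Latent-time programs interpolate linearly in tau between the root and
    terminal factor; markers are constant multiplicative shifts.
    """
    n_cells, n_genes = len(truth.state_label), len(truth.gene_names)
    fac = np.ones((n_cells, n_genes), dtype=np.float64)
    lf = config.state_logfc
    tau = truth.latent_time
    t0 = config.branch_split_time


    # constant sub-/super-state markers
    for s in STATES:
        m = truth.state_label == s
        fac[np.ix_(m, _gene_index_by_role(truth, "state_marker", s))] *= 2.0 ** lf
    for ss in ("SPC-high", "Hmga2-high"):
        m = truth.superstate_label == ss
        fac[np.ix_(m, _gene_index_by_role(truth, "superstate_marker", ss))] *= 2.0 ** lf
    # the surface marker gets a stronger, FACS-like separation
    marker_pos = int(np.flatnonzero(truth.gene_names == truth.planted_marker_gene)[0])
    m = truth.superstate_label == "Hmga2-high"
    fac[m, marker_pos] /= 2.0 ** lf  # undo the generic super-state shift
    fac[m, marker_pos] *= 2.0 ** (config.marker_logfc_multiplier * lf)

    # Latent-time programs: genes switch on (branches) or off (trunk)
    # sequentially along latent time, with geometric (log-linear) ramps.  The
    # staggered onsets spread the latent-time signal across expression space
    # so that pseudotime is resolvable everywhere along the manifold.
    amp = config.program_logfc_multiplier * lf
    origin = _gene_index_by_role(truth, "origin_program", "trunk")
    switch_off = np.linspace(0.35, 1.0, origin.size) * t0
    trunk_ramp = np.clip(1.0 - tau[:, None] / switch_off[None, :], 0.0, 1.0)
    fac[:, origin] *= 2.0 ** (amp * trunk_ramp)
    u_branch = np.clip((tau - t0) / (1.0 - t0), 0.0, 1.0)
    for br in ("spc", "hmga2"):
        genes = _gene_index_by_role(truth, "branch_program", br)
        onset = np.linspace(0.0, config.branch_onset_max, genes.size)
        ramp = np.clip(
            (u_branch[:, None] - onset[None, :]) / (1.0 - onset[None, :]),
            0.0, 1.0,
        ) * (truth.branch_id == br)[:, None]
        fac[:, genes] *= 2.0 ** (amp * ramp)

    # TF activity couples the TF gene and its regulon targets.  Each TF's
    # activity is an exponentiated cosine harmonic of the branch cell-mass
    # coordinate (harmonic order staggered across the TFs of a lineage),
    # gated by an onset envelope so the branch point sits at baseline, and
    # multiplied by a per-cell lognormal gain.  Distinct harmonic orders keep
    # the activities of different TFs near-orthogonal across cells while
    # remaining smooth in latent time.
    beta = config.tf_target_coupling
    ss_branch = {"SPC-high": "spc", "Hmga2-high": "hmga2"}
    u = np.clip((tau - t0) / (1.0 - t0), 0.0, 1.0)
    env = np.clip(u / 0.25, 0.0, 1.0)
    harmonics, amp_scale, mass_q = {}, {}, {}
    from scipy.stats import rankdata as _rankdata
    for ss, br in ss_branch.items():
        members = [t for t in truth.planted_regulons
                   if truth.tf_superstate[t] == ss]
        harmonics.update({t: k for k, t in enumerate(members, start=1)})
        on_br = truth.branch_id == br
        # waves live in the cell-mass coordinate of the branch so that the
        # harmonics are orthogonal across cells regardless of how cells are
        # distributed along latent time
        q = np.zeros(n_cells)
        if on_br.any():
            q[on_br] = _rankdata(u[on_br]) / on_br.sum()
        mass_q[ss] = q
        # equalize the activity's share of total variance across lineages
        frac = max(on_br.mean(), 1e-6)
        amp_scale[ss] = (0.5 / frac) ** 0.75
    for tf, targets in truth.planted_regulons.items():
        tf_pos = int(np.flatnonzero(truth.gene_names == tf)[0])
        tgt_pos = _gene_index_by_role(truth, "regulon_target", tf)
        tf_ss = truth.tf_superstate[tf]
        on = truth.branch_id == ss_branch[tf_ss]
        wave = np.exp(
            config.tf_wave_amp * np.cos(np.pi * harmonics[tf] * mass_q[tf_ss])
        )
        gain = rng.lognormal(0.0, config.tf_gain_sigma, n_cells)
        activity = (config.tf_gain_mean * amp_scale[tf_ss]
                    * env * wave * gain * on)
        coupling = 1.0 + beta * activity
        fac[:, tgt_pos] *= coupling[:, None]
        fac[:, tf_pos] *= coupling * np.where(
            on, 2.0 ** (config.tf_logfc_multiplier * lf), 1.0
        )

    # cell-cycle factors, independent of state
    for key in ("s", "g2m"):
        cc = rng.normal(0.0, config.cc_factor_sigma, n_cells)
        genes = _gene_index_by_role(truth, "cell_cycle", key)
        fac[:, genes] *= (2.0 ** cc)[:, None]

    # low-quality cells: elevated mitochondrial content
    lq = truth.lowquality_flags
    mito = np.flatnonzero(truth.mito_flags)
    if mito.size and lq.any():
        fac[np.ix_(lq, mito)] *= config.lowquality_mito_boost
    return fac


def simulate_rna(truth: SyntheticTruth, config: SimConfig):
    """Negative-binomial RNA counts; returns (csr counts, gene table)."""
    rng = np.random.default_rng([config.seed, 2])
    n_cells, n_genes = len(truth.state_label), len(truth.gene_names)

    mu_lib, sd_lib = config.library_size_lognormal
    lib_target = rng.lognormal(mu_lib, sd_lib, n_cells)
    good = ~truth.lowquality_flags
    lib_target[good] = np.clip(lib_target[good], 5000.0, 50000.0)
    lib_target[~good] = np.clip(
        lib_target[~good] * config.lowquality_depth_factor, 200.0, 1600.0
    )

    fac = _rna_mean_factors(truth, config, rng)
    theta = fac * truth.base_expr[None, :]
    mu = theta * (lib_target / theta.sum(axis=1))[:, None]

    r = config.nb_dispersion
    blocks = []
    for start in range(0, n_cells, 1024):
        sub = mu[start : start + 1024]
        p = r / (r + sub)
        counts = rng.negative_binomial(r, p)
        blocks.append(sp.csr_matrix(counts.astype(np.int32)))
    rna = sp.vstack(blocks, format="csr")
    genes = pd.DataFrame(
        {"mito": truth.mito_flags}, index=pd.Index(truth.gene_names, name="gene")
    )
    return rna, genes


# ---------------------------------------------------------------------------
# ATAC counts
# ---------------------------------------------------------------------------

def _atac_logit_shift(truth: SyntheticTruth, config: SimConfig) -> tuple:
    """Sub-state and motif shifts as (cells x groups bool, group peak lists)."""
    shift_masks, shift_peaks = [], []
    for s in STATES:
        shift_masks.append(truth.state_label == s)
        shift_peaks.append(truth.da_peak_sets[s])
    for tf, pk in truth.motif_peak_sets.items():
        shift_masks.append(truth.superstate_label == truth.tf_superstate[tf])
        shift_peaks.append(pk)
    return shift_masks, shift_peaks


def simulate_atac(truth: SyntheticTruth, config: SimConfig):
    """Poisson ATAC counts; returns (csr counts, peaks, motif annotation, gc)."""
    rng = np.random.default_rng([config.seed, 3])
    n_cells = len(truth.state_label)
    n_peaks = len(truth.peaks)

    mu_d, sd_d = config.atac_depth_lognormal
    depth = rng.lognormal(mu_d, sd_d, n_cells)
    good = ~truth.lowquality_flags
    depth[good] = np.clip(depth[good], 8.0, 60.0)
    depth[~good] = np.clip(depth[~good] * config.lowquality_depth_factor, 0.2, 2.5)

    shift_masks, shift_peaks = _atac_logit_shift(truth, config)
    shift = config.peak_accessibility_shift

    blocks = []
    for start in range(0, n_cells, 512):
        stop = min(start + 512, n_cells)
        logits = np.tile(truth.peak_base_logit, (stop - start, 1))
        for mask, pk in zip(shift_masks, shift_peaks):
            sub = mask[start:stop]
            if sub.any() and pk.size:
                logits[np.ix_(sub, pk)] += shift
        rate = depth[start:stop, None] * expit(logits)
        counts = rng.poisson(rate)
        blocks.append(sp.csr_matrix(counts.astype(np.int32)))
    atac = sp.vstack(blocks, format="csr")
    return atac, truth.peaks.copy(), truth.motif_annotation, truth.peak_gc.copy()


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig):
    """Compose truth, RNA and ATAC into a MultiomeDataset with QC metadata."""
    truth = generate_truth(config)
    rna, genes = simulate_rna(truth, config)
    atac, peaks, _, gc = simulate_atac(truth, config)
    peaks = peaks.assign(gc=gc)

    dataset = MultiomeDataset(
        rna=rna,
        atac=atac,
        genes=genes,
        peaks=peaks,
        cell_ids=truth.cell_ids,
        cell_meta=pd.DataFrame(index=pd.Index(truth.cell_ids, name="cell_id")),
    )
    meta = compute_qc_metrics(dataset)

    rng = np.random.default_rng([config.seed, 4])
    good = ~truth.lowquality_flags
    tss_enr = np.empty(len(truth.cell_ids))
    tss_enr[good] = np.clip(rng.normal(8.0, 2.0, good.sum()), 4.5, 16.0)
    tss_enr[~good] = np.clip(rng.normal(2.0, 1.0, (~good).sum()), 0.1, 3.5)
    meta["tss_enrichment"] = tss_enr
    meta["sample_label"] = config.preset.upper()
    dataset.cell_meta = meta
    return dataset, truth


def simulate_fragments(truth: SyntheticTruth, config: SimConfig,
                       n_cells: int = 30, frags_per_cell: int = 300) -> pd.DataFrame:
    """Small fragments file so the real TSS-enrichment computation can run.

    A fraction of fragments (higher for good cells) centers on TSSs, the
    rest is uniform background over the flanks.
    """
    rng = np.random.default_rng([config.seed, 5])
    idx = np.linspace(0, len(truth.cell_ids) - 1, min(n_cells, len(truth.cell_ids)))
    rows = []
    tss = truth.tss_table
    for i in idx.astype(int):
        frac_tss = 0.1 if truth.lowquality_flags[i] else 0.5
        which = rng.integers(0, len(tss), frags_per_cell)
        at_tss = rng.random(frags_per_cell) < frac_tss
        centers = tss["pos"].to_numpy()[which]
        offs = np.where(
            at_tss,
            rng.normal(0, 30, frags_per_cell),
            rng.uniform(-1990, 1990, frags_per_cell),
        ).astype(int)
        starts = np.maximum(centers + offs - rng.integers(20, 60, frags_per_cell), 0)
        ends = centers + offs + rng.integers(20, 60, frags_per_cell)
        for c, s_, e_ in zip(tss["chrom"].to_numpy()[which], starts, ends):
            rows.append((c, int(s_), int(e_), truth.cell_ids[i], 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])


def write_dataset(dataset: MultiomeDataset, truth: SyntheticTruth, outdir,
                  fragments: pd.DataFrame | None = None) -> None:
    """Write 10x-style triplets, peaks.bed, motifs.tsv and truth tables."""
    from pathlib import Path

    outdir = Path(outdir)
    write_mtx_triplet(outdir / "rna", dataset.rna, dataset.gene_symbols, dataset.cell_ids)
    write_mtx_triplet(
        outdir / "atac",
        dataset.atac,
        [f"peak{i:05d}" for i in range(dataset.atac.shape[1])],
        dataset.cell_ids,
    )
    write_bed(outdir / "peaks.bed", dataset.peaks)
    coo = truth.motif_annotation.tocoo()
    pd.DataFrame(
        {"peak_id": [f"peak{i:05d}" for i in coo.row],
         "motif_id": [truth.motif_names[j] for j in coo.col]}
    ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    dataset.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    pd.DataFrame(
        {
            "cell_id": truth.cell_ids,
            "state": truth.state_label,
            "superstate": truth.superstate_label,
            "latent_time": truth.latent_time,
            "branch": truth.branch_id,
            "lowquality": truth.lowquality_flags,
        }
    ).to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(tf, g) for tf, genes in truth.planted_regulons.items() for g in genes],
        columns=["tf", "target"],
    ).to_csv(outdir / "truth_regulons.tsv", sep="\t", index=False)
    if fragments is not None:
        fragments.to_csv(outdir / "fragments.tsv", sep="\t", header=False, index=False)
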