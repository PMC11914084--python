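"""End-to-end orchestration of the multiome state-analysis stages.

``run_pipeline`` executes, in dependency order: simulate -> qc -> embed ->
states -> diff -> motifs -> regulons -> nominate -> score -> trajectory.
Each stage receives a seed derived from the global seed by a stable hash, so
disabling one stage never changes another stage's random draws.  All tabular
outputs are written as TSV plus a ``run_info.json`` carrying the config hash
and per-stage counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig, config_hash, stage_seed
from .io_qc import QCThresholds, filter_cells
from .synthetic_multiome import SimConfig, simulate_dataset

logger = logging.getLogger("scmultistate")

__all__ = ["PipelineResult", "run_pipeline", "simulate_stage"]


@dataclass
class PipelineResult:
    """All in-memory artifacts produced by one pipeline run."""

    config: PipelineConfig
    dataset: object = None           # QC-filtered MultiomeDataset
    truth: object = None             # SyntheticTruth aligned to the filtered cells
    kept_cells: list = field(default_factory=list)
    normed_rna: object = None
    hvg: np.ndarray | None = None
    rna_pca: object = None
    atac_lsi: object = None
    clusters: object = None
    states: object = None            # StatePartition
    superstate_labels: np.ndarray | None = None
    de_tables: pd.DataFrame | None = None
    da_tables: pd.DataFrame | None = None
    deviations: object = None
    motif_table: pd.DataFrame | None = None
    regulons: object = None
    regulon_activity: pd.DataFrame | None = None
    regulon_table: pd.DataFrame | None = None
    evidence: dict = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    score_flags: pd.DataFrame | None = None
    program_matrix: pd.DataFrame | None = None
    trajectory: object = None
    projection: pd.DataFrame | None = None
    density: pd.DataFrame | None = None
    branch_masses: pd.DataFrame | None = None
    surface_markers: pd.DataFrame | None = None
    stage_log: list = field(default_factory=list)


def _truth_subset(truth, keep_mask: np.ndarray):
    """Restrict the per-cell truth arrays to the kept cells."""
    from dataclasses import replace

    return replace(
        truth,
        state_label=truth.state_label[keep_mask],
        superstate_label=truth.superstate_label[keep_mask],
        latent_time=truth.latent_time[keep_mask],
        branch_id=truth.branch_id[keep_mask],
        lowquality_flags=truth.lowquality_flags[keep_mask],
        cell_ids=[c for c, k in zip(truth.cell_ids, keep_mask) if k],
    )


def simulate_stage(config: PipelineConfig, preset: str | None = None):
    """Simulate a dataset under the pipeline's simulate block."""
    sim = SimConfig(
        preset=preset or config.simulate.preset,
        n_cells=config.simulate.n_cells,
        exact_counts=config.simulate.exact_counts,
        seed=stage_seed(config.seed, "simulate"),
    )
    return simulate_dataset(sim)


def _qc_stage(dataset, truth, config: PipelineConfig):
    thr = QCThresholds(
        min_genes=config.qc.min_genes,
        min_counts=config.qc.min_counts,
        max_pct_mito=config.qc.max_pct_mito,
        min_fragments=config.qc.min_fragments,
        min_tss_enrichment=config.qc.min_tss_enrichment,
    )
    kept = filter_cells(dataset.cell_meta, thr)
    keep_mask = pd.Index(dataset.cell_ids).isin(kept)
    filtered = dataset.subset_cells(kept)
    truth_f = _truth_subset(truth, keep_mask) if truth is not None else None
    return filtered, truth_f, kept


def _embed_stage(dataset, s_genes, g2m_genes, config: PipelineConfig):
    from . import embeddings as emb

    seed = stage_seed(config.seed, "embed")
    normed = emb.normalize_log1p(dataset.rna)
    genes = dataset.gene_symbols
    hvg = emb.select_hvg(normed, n=config.embed.n_hvg,
                         n_bins=config.embed.hvg_bins, gene_ids=genes)
    s_score, g2m_score = emb.cell_cycle_scores(
        normed, genes, s_genes, g2m_genes, seed=seed
    )
    scaled = emb.scale_genes(normed[:, hvg], max_value=config.embed.scale_max)
    resid = emb.regress_out(scaled, np.column_stack([s_score, g2m_score]))
    rna_pca = emb.pca(resid, n=config.embed.n_pcs, seed=seed)
    atac_lsi = emb.iterative_lsi(
        dataset.atac,
        iterations=config.embed.lsi_iterations,
        resolution=config.embed.lsi_resolution,
        var_features=config.embed.lsi_var_features,
        n_dims=config.embed.lsi_dims,
        seed=seed,
        depth_corr_threshold=config.embed.depth_corr_threshold,
    )
    return normed, hvg, rna_pca, atac_lsi


def _states_stage(rna_pca, atac_lsi, config: PipelineConfig):
    from . import state_definition as sd

    seed = stage_seed(config.seed, "states")
    graph = sd.snn_graph(rna_pca.coords, k=config.states.k_neighbors,
                         prune=config.states.snn_prune)
    clusters = sd.cluster_graph(graph, resolution=config.states.resolution,
                                seed=seed)
    mixing = sd.chromatin_similarity(clusters, atac_lsi.coords,
                                     k=config.states.k_neighbors)
    states = sd.merge_clusters_by_chromatin(
        clusters, mixing, threshold=config.states.merge_threshold
    )
    supers = sd.split_superstates(states.labels, rna_pca.coords, n_groups=2)
    return clusters, states, supers


def _diff_stage(normed_rna, dataset, states, config: PipelineConfig):
    from .differential import differential_peaks, wilcoxon_de

    seed = stage_seed(config.seed, "diff")
    labels = states.labels
    genes = dataset.gene_symbols
    peak_ids = np.arange(dataset.atac.shape[1])
    de_all, da_all = [], []
    for s in np.unique(labels):
        m = labels == s
        de = wilcoxon_de(
            normed_rna, genes, m, ~m,
            min_pct=config.diff.min_pct,
            lfc_threshold=config.diff.lfc_threshold,
            group_label=s,
        )
        de_all.append(de)
        da = differential_peaks(
            dataset.atac, peak_ids, m, ~m, dataset.cell_meta,
            n_bins=config.diff.match_bins,
            min_pct=config.diff.min_pct,
            lfc_threshold=config.diff.lfc_threshold,
            seed=seed,
            group_label=s,
        )
        da_all.append(da)
    return pd.concat(de_all, ignore_index=True), pd.concat(da_all, ignore_index=True)


def _motifs_stage(dataset, motif_annotation, motif_names, peak_gc, states,
                  config: PipelineConfig):
    from .chromatin_motifs import (compute_deviations,
                                   differential_motif_scores,
                                   match_background_peaks)

    seed = stage_seed(config.seed, "motifs")
    mean_acc = np.asarray(dataset.atac.mean(axis=0)).ravel()
    backgrounds = match_background_peaks(
        peak_gc, mean_acc, n_bg=config.motifs.n_background,
        n_bins=config.motifs.match_grid_bins, seed=seed,
    )
    dm = compute_deviations(
        dataset.atac, motif_annotation.T.tocsr(), backgrounds,
        set_names=list(motif_names),
    )
    table = differential_motif_scores(
        dm.z, dm.set_names, states.labels, alpha=config.motifs.alpha
    )
    return dm, table


def _regulons_stage(normed_rna, dataset, motif_annotation, motif_names,
                    tss_table, tf_list, states, config: PipelineConfig):
    from . import regulons as reg

    candidates = reg.coexpression_candidates(
        normed_rna, dataset.gene_symbols, tf_list,
        n_candidates=config.regulons.n_candidates,
    )
    links = reg.link_peaks_to_genes(dataset.peaks, tss_table,
                                    window=config.regulons.link_window)
    regset = reg.prune_by_motif(
        candidates, motif_annotation, motif_names, links,
        min_targets=config.regulons.min_targets,
    )
    activity = reg.aucell_scores(
        normed_rna, dataset.gene_symbols, regset,
        top_frac=config.regulons.top_frac,
    )
    regset.activity = activity
    table = reg.differential_regulon(activity, states.labels,
                                     alpha=config.regulons.alpha)
    return regset, activity, table


def _nominate_stage(de_tables, motif_table, regulon_table, tf_list, states,
                    config: PipelineConfig):
    from .evidence_nomination import nominate_regulators

    evidence = {}
    for s in np.unique(states.labels):
        evidence[s] = nominate_regulators(
            de_tables, motif_table, regulon_table, s,
            tf_list=tf_list, alpha=config.nominate.alpha,
        )
    return evidence


def _score_stage(normed_rna, dataset, programs: dict, states,
                 config: PipelineConfig):
    from .signatures_scoring import score_signatures, state_program_matrix

    seed = stage_seed(config.seed, "score")
    scores, flags = score_signatures(
        normed_rna, dataset.gene_symbols, programs,
        n_bins=config.score.n_bins, n_ctrl=config.score.n_ctrl, seed=seed,
    )
    matrix, _ = state_program_matrix(scores, states.labels, scale=True)
    return scores, flags, matrix


def _trajectory_stage(normed_rna, dataset, superstates, states, programs,
                      cc_genes, config: PipelineConfig, root_state=None):
    from . import trajectory as traj
    from .signatures_scoring import module_score

    seed = stage_seed(config.seed, "trajectory")
    genes = dataset.gene_symbols
    traj_genes = traj.select_trajectory_genes(
        normed_rna, genes, superstates, cc_genes=cc_genes,
        top_n=config.trajectory.top_n_genes,
        min_cell_frac=config.trajectory.min_cell_frac,
    )
    if root_state is None:
        # root = the state where the origin program scores highest
        origin = module_score(normed_rna, genes, programs["origin"], seed=seed)
        means = {
            s: origin[states.labels == s].mean() for s in np.unique(states.labels)
        }
        root_state = max(means, key=means.get)
    tree = traj.build_trajectory(
        normed_rna, genes, traj_genes, states.labels, root_state,
        n_nodes_per_state=config.trajectory.n_nodes_per_state,
        n_dims=config.trajectory.n_dims, seed=seed,
    )
    return tree, root_state


def run_pipeline(config: PipelineConfig, outdir=None,
                 dataset=None, truth=None,
                 project_preset: str | None = "ky") -> PipelineResult:
    """Run all enabled stages end to end on a (simulated) multiome dataset.

    When ``dataset``/``truth`` are not given they are simulated from the
    config's simulate block.  ``project_preset`` names a second preset to
    simulate and project onto the trajectory (None disables projection).
    Deterministic given (config, seed).
    """
    t0 = time.time()
    res = PipelineResult(config=config)
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

    def log_stage(name, **counts):
        entry = {"stage": name, "elapsed_s": round(time.time() - t0, 2), **counts}
        res.stage_log.append(entry)
        logger.info("stage %s done: %s", name, counts)

    if dataset is None:
        dataset, truth = simulate_stage(config)
    log_stage("simulate", n_cells=dataset.n_cells,
              n_genes=dataset.rna.shape[1], n_peaks=dataset.atac.shape[1])

    if config.stages.qc:
        dataset, truth, kept = _qc_stage(dataset, truth, config)
        res.kept_cells = kept
        log_stage("qc", n_kept=len(kept))
    res.dataset, res.truth = dataset, truth

    if truth is not None:
        s_genes = truth.program_gene_sets["s_genes"]
        g2m_genes = truth.program_gene_sets["g2m_genes"]
    else:
        s_genes, g2m_genes = [], []

    if not config.stages.embed:
        _write_outputs(res, out, config)
        return res
    res.normed_rna, res.hvg, res.rna_pca, res.atac_lsi = _embed_stage(
        dataset, s_genes, g2m_genes, config
    )
    log_stage("embed", n_hvg=len(res.hvg),
              n_pcs=res.rna_pca.coords.shape[1],
              n_lsi=res.atac_lsi.coords.shape[1])

    if not config.stages.states:
        _write_outputs(res, out, config)
        return res
    res.clusters, res.states, res.superstate_labels = _states_stage(
        res.rna_pca, res.atac_lsi, config
    )
    log_stage("states", n_clusters=res.clusters.n_clusters,
              n_states=res.states.n_states)

    if config.stages.diff:
        res.de_tables, res.da_tables = _diff_stage(
            res.normed_rna, dataset, res.states, config
        )
        log_stage("diff", n_de_rows=len(res.de_tables),
                  n_da_rows=len(res.da_tables))

    tf_list = None
    if truth is not None:
        tf_list = list(truth.tf_names)
        if config.stages.motifs:
            res.deviations, res.motif_table = _motifs_stage(
                dataset, truth.motif_annotation, truth.motif_names,
                truth.peak_gc, res.states, config,
            )
            log_stage("motifs", n_motifs=len(truth.motif_names))
        if config.stages.regulons:
            res.regulons, res.regulon_activity, res.regulon_table = (
                _regulons_stage(
                    res.normed_rna, dataset, truth.motif_annotation,
                    truth.motif_names, truth.tss_table, tf_list,
                    res.states, config,
                )
            )
            log_stage("regulons", n_regulons=len(res.regulons.targets))
        if (config.stages.nominate and res.de_tables is not None
                and res.motif_table is not None
                and res.regulon_table is not None):
            res.evidence = _nominate_stage(
                res.de_tables, res.motif_table, res.regulon_table,
                tf_list, res.states, config,
            )
            log_stage("nominate",
                      n_nominated=sum(len(e.nominated)
                                      for e in res.evidence.values()))
        if config.stages.score:
            programs = {
                **{f"marker_{k}": v for k, v in truth.marker_gene_sets.items()},
                **truth.program_gene_sets,
            }
            res.scores, res.score_flags, res.program_matrix = _score_stage(
                res.normed_rna, dataset, programs, res.states, config
            )
            log_stage("score", n_programs=len(programs))
        # surface marker ranking for the Hmga2-high-style super-state
        from .state_definition import select_surface_marker

        if res.superstate_labels is not None:
            pool = truth.marker_gene_sets.get("Hmga2-high", [])
            surface_pool = [truth.planted_marker_gene] + [
                g for g in pool if g != truth.planted_marker_gene
            ][:20]
            target = _marker_target_superstate(
                res.superstate_labels, truth.superstate_label
            )
            res.surface_markers = select_surface_marker(
                res.superstate_labels, res.normed_rna, dataset.gene_symbols,
                surface_pool, target,
            )

    if config.stages.trajectory and truth is not None:
        tree, root_state = _trajectory_stage(
            res.normed_rna, dataset, res.superstate_labels, res.states,
            truth.program_gene_sets, truth.program_gene_sets["s_genes"]
            + truth.program_gene_sets["g2m_genes"], config,
        )
        res.trajectory = tree
        if project_preset is not None:
            from . import trajectory as traj
            from .embeddings import normalize_log1p

            ds2, truth2 = simulate_stage(config, preset=project_preset)
            ds2, truth2, _ = _qc_stage(ds2, truth2, config)
            proj = traj.project_dataset(
                normalize_log1p(ds2.rna), ds2.gene_symbols, tree,
                k=config.trajectory.k_project,
                ref_labels=res.states.labels if res.states is not None
                else None,
            )
            res.projection = proj
            pt = np.concatenate([tree.cell_pseudotime,
                                 proj["pseudotime"].to_numpy()])
            samples = np.concatenate([
                np.repeat(config.simulate.preset.upper(),
                          len(tree.cell_pseudotime)),
                np.repeat(project_preset.upper(), len(proj)),
            ])
            branches = np.concatenate([
                tree.cell_branch, proj["branch"].to_numpy()
            ])
            res.density = traj.density_along_pseudotime(
                pt, samples, grid=config.trajectory.density_grid
            )
            res.branch_masses = traj.branch_mass(branches, samples)
        log_stage("trajectory",
                  n_nodes=len(tree.nodes),
                  n_branching=len(tree.branching_nodes),
                  root_state=int(root_state))

    _write_outputs(res, out, config)
    return res


def _marker_target_superstate(super_labels: np.ndarray,
                              truth_supers: np.ndarray):
    """Recovered super-state holding most planted Hmga2-high cells."""
    hm = truth_supers == "Hmga2-high"
    if not hm.any():
        return np.unique(super_labels)[0]
    vals, counts = np.unique(super_labels[hm], return_counts=True)
    return vals[np.argmax(counts)]


def _write_outputs(res: PipelineResult, out, config: PipelineConfig) -> None:
    if out is None:
        return
    chash = config_hash(config)
    info = {
        "config_hash": chash,
        "seed": config.seed,
        "stages": res.stage_log,
    }
    config.to_yaml(out / "config.yaml")
    with open(out / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2, default=str)
    if res.states is not None:
        pd.DataFrame(
            {
                "cell_id": res.dataset.cell_ids,
                "cluster": res.clusters.labels,
                "state": res.states.labels,
                "superstate": res.superstate_labels,
            }
        ).to_csv(out / "states.tsv", sep="\t", index=False)
    if res.de_tables is not None:
        res.de_tables.to_csv(out / "de_genes.tsv", sep="\t", index=False)
    if res.da_tables is not None:
        res.da_tables.to_csv(out / "da_peaks.tsv", sep="\t", index=False)
    if res.motif_table is not None:
        res.motif_table.to_csv(out / "motif_enrichment.tsv", sep="\t",
                               index=False)
    if res.regulon_table is not None:
        res.regulon_table.to_csv(out / "regulon_enrichment.tsv", sep="\t",
                                 index=False)
    if res.evidence:
        ev = pd.concat(
            [e.table.assign(state=s) for s, e in res.evidence.items()],
            ignore_index=True,
        )
        ev.to_csv(out / "evidence.tsv", sep="\t", index=False)
        venn = {str(s): e.venn for s, e in res.evidence.items()}
        with open(out / "venn.json", "w") as fh:
            json.dump(venn, fh, indent=2)
        nominated = pd.DataFrame(
            [(s, tf) for s, e in res.evidence.items() for tf in e.nominated],
            columns=["state", "tf"],
        )
        nominated.to_csv(out / "nominated.tsv", sep="\t", index=False)
    if res.scores is not None:
        res.scores.assign(cell_id=res.dataset.cell_ids).to_csv(
            out / "program_scores.tsv", sep="\t", index=False
        )
    if res.program_matrix is not None:
        res.program_matrix.to_csv(out / "state_program_matrix.tsv", sep="\t")
    if res.surface_markers is not None:
        res.surface_markers.to_csv(out / "surface_markers.tsv", sep="\t",
                                   index=False)
    if res.trajectory is not None:
        tree = res.trajectory
        pd.DataFrame(
            {
                "cell_id": res.dataset.cell_ids,
                "pseudotime": tree.cell_pseudotime,
                "branch": tree.cell_branch,
            }
        ).to_csv(out / "pseudotime.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (u, v, tree.edge_branch[(u, v)])
                for u, v in tree.edges
            ],
            columns=["node_a", "node_b", "branch"],
        ).to_csv(out / "tree_edges.tsv", sep="\t", index=False)
    if res.density is not None:
        res.density.to_csv(out / "density.tsv", sep="\t", index=False)
    if res.branch_masses is not None:
        res.branch_masses.to_csv(out / "branch_mass.tsv", sep="\t",
                                 index=False)
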