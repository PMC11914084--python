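"""Pipeline configuration: typed per-stage blocks, YAML round-trip, seeds.

Each stage reads only its own block plus the globals.  Unknown keys are
rejected at load time.  One global seed fans out to per-stage seeds by a
stable hash, so toggling one stage never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "stage_seed", "config_hash"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2 ** 31)


@dataclass
class SimulateBlock:
    preset: str = "kpy"
    n_cells: int = 8423
    exact_counts: bool = True


@dataclass
class QCBlock:
    min_genes: int = 200
    min_counts: int = 2500
    max_pct_mito: float = 10.0
    min_fragments: int = 1000
    min_tss_enrichment: float = 4.0


@dataclass
class EmbedBlock:
    n_hvg: int = 2000
    hvg_bins: int = 20
    n_pcs: int = 60
    scale_max: float = 10.0
    lsi_iterations: int = 3
    lsi_resolution: float = 0.2
    lsi_var_features: int = 50000
    lsi_dims: int = 30
    depth_corr_threshold: float = 0.75


@dataclass
class StatesBlock:
    k_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 1.0
    merge_threshold: float = 0.5
    min_dual_features: int = 10


@dataclass
class DiffBlock:
    min_pct: float = 0.05
    lfc_threshold: float = 0.5
    match_bins: int = 4
    alpha: float = 0.05


@dataclass
class MotifsBlock:
    n_background: int = 50
    match_grid_bins: int = 50
    alpha: float = 0.05


@dataclass
class RegulonsBlock:
    n_candidates: int = 50
    link_window: int = 2000
    min_targets: int = 10
    top_frac: float = 0.05
    alpha: float = 0.05


@dataclass
class NominateBlock:
    alpha: float = 0.05


@dataclass
class ScoreBlock:
    n_bins: int = 24
    n_ctrl: int = 100


@dataclass
class TrajectoryBlock:
    top_n_genes: int = 2000
    min_cell_frac: float = 0.10
    n_nodes_per_state: int = 3
    n_dims: int = 10
    k_project: int = 25
    density_grid: int = 200


@dataclass
class StageToggles:
    qc: bool = True
    embed: bool = True
    states: bool = True
    diff: bool = True
    motifs: bool = True
    regulons: bool = True
    nominate: bool = True
    score: bool = True
    trajectory: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results"
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    qc: QCBlock = field(default_factory=QCBlock)
    embed: EmbedBlock = field(default_factory=EmbedBlock)
    states: StatesBlock = field(default_factory=StatesBlock)
    diff: DiffBlock = field(default_factory=DiffBlock)
    motifs: MotifsBlock = field(default_factory=MotifsBlock)
    regulons: RegulonsBlock = field(default_factory=RegulonsBlock)
    nominate: NominateBlock = field(default_factory=NominateBlock)
    score: ScoreBlock = field(default_factory=ScoreBlock)
    trajectory: TrajectoryBlock = field(default_factory=TrajectoryBlock)
    stages: StageToggles = field(default_factory=StageToggles)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        block_types = {
            f.name: f.default_factory
            for f in fields(cls)
            if f.name not in ("seed", "outdir")
        }
        for key in list(data):
            if key in ("seed", "outdir"):
                kwargs[key] = data.pop(key)
        for name, factory in block_types.items():
            block_cls = type(factory())
            sub = data.pop(name, {}) or {}
            valid = {f.name for f in fields(block_cls)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(
                    f"unknown keys in config block {name!r}: {sorted(unknown)}"
                )
            kwargs[name] = block_cls(**sub)
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the full configuration."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
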