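"""Pipeline configuration: strict, serializable, hashable.

A :class:`PipelineConfig` collects every knob of the simulation and
analysis; unknown keys are rejected so that typos cannot silently fall
back to defaults.  The full resolved configuration (including every
paper-gap decision value such as the distance-pooling mode, TFCE
exponents, cluster connectivity, and quantile convention) is serialized
into each results bundle together with a stable hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = [
    "DecodingOptions",
    "StatsOptions",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


@dataclass
class DecodingOptions:
    pooling: str = "pooled"        # distance z-scoring: 'pooled' | 'within_run'
    C: float = 1.0                 # SVM regularization constant
    accuracy: bool = False         # report classification accuracy instead of CI


@dataclass
class StatsOptions:
    E: float = 0.5                 # TFCE extent exponent
    H: float = 2.0                 # TFCE height exponent
    dh: float | None = None        # TFCE step; None = max |t| / 100
    n_permutations: int = 10_000
    alpha: float = 0.001           # voxelwise cluster-forming threshold
    cluster_min: int = 10
    tfce_null: str = "max"         # 'max' (FWE) | 'pointwise'
    fisher: bool = False           # Fisher-transform coupling correlations
    fwe_alpha: float = 0.05


@dataclass
class PipelineConfig:
    experiment: int = 1
    n_subjects: int = 34
    seed: int = 0
    out_dir: str = "results"
    scale: str = "paper"           # 'paper' | 'scaled' design constants
    design: dict = field(default_factory=dict)      # DesignParams overrides
    truth: dict = field(default_factory=dict)       # TruthParams overrides
    voxels_per_roi: int = 1500     # per ROI and hemisphere
    n_other_voxels: int = 0
    subroi_step: int = 100
    subroi_max: int = 0            # 0 = voxels_per_roi
    rois: tuple = ("EVC", "LVC")
    hemispheres: tuple = ("L", "R")
    decoding: DecodingOptions = field(default_factory=DecodingOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    run_univariate: bool = True
    run_coupling: bool = False
    coupling_seed_sizes: tuple = (500, 600, 700, 800, 900, 1000)
    n_fir_bins: int = 10
    share_design: bool = False     # one trial sequence for the whole cohort
    write_outputs: bool = True

    def __post_init__(self):
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.scale not in ("paper", "scaled"):
            raise ValueError("scale must be 'paper' or 'scaled'")
        if isinstance(self.decoding, dict):
            self.decoding = _strict(DecodingOptions, self.decoding)
        if isinstance(self.stats, dict):
            self.stats = _strict(StatsOptions, self.stats)
        self.rois = tuple(self.rois)
        self.hemispheres = tuple(self.hemispheres)
        self.coupling_seed_sizes = tuple(self.coupling_seed_sizes)
        if self.subroi_max <= 0:
            self.subroi_max = self.voxels_per_roi

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _strict(cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def make_config(data: dict) -> PipelineConfig:
    return _strict(PipelineConfig, data)


def load_config(path: str) -> PipelineConfig:
    """Load a YAML (or JSON, a YAML subset) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return make_config(data)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
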