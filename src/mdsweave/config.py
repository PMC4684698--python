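"""Pipeline configuration: every analysis threshold in one place.

All numeric constants of the analysis are surfaced here with the study's
values as defaults, so sensitivity analyses can override any of them from
YAML without touching code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["Thresholds", "PipelineConfig"]


@dataclass
class Thresholds:
    min_cds_penetration: int = 20    # filter rule 3: shared region must reach this far into a CDS
    dup_identity: float = 0.40       # duplication call: protein identity floor (strict >)
    dup_coverage: float = 0.80       # ... over this fraction of the shorter unique region
    dup_shuffles: int = 200          # shuffle count for the e-value surrogate
    dup_use_similarity: bool = False  # matrix-positive fraction instead of identity
    min_region_nt: int = 150         # rate filter: both regions longer than this (strict)
    ds_min: float = 0.01             # rate filter: dS lower bound (inclusive)
    ds_max: float = 5.0              # rate filter: dS upper bound (inclusive)
    expr_threshold: float = 10.0     # reads/kb total below which a group is dropped
    expr_filter_per_gene: bool = True  # any member below threshold drops the group
    len_cons_bp: int = 50            # shared-length conservation: absolute tolerance
    len_cons_frac: float = 0.10      # ... or relative, whichever is larger
    fold_cutoff_low: float = 2.0     # copy-number guide lines
    fold_cutoff_high: float = 3.0
    max_gap_frac: float = 0.5        # gene-tree column filter
    gc_quantile: float = 0.25        # noncoding-capture GC baseline quantile

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    """Input selection, thresholds and output location for a pipeline run."""

    input_dir: str | None = None     # existing dataset directory ...
    simulate: SimulationConfig | None = None  # ... or a simulation to run
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    out_dir: str = "mdsweave_out"

    def __post_init__(self):
        if self.input_dir is None and self.simulate is None:
            self.simulate = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.get("simulate")
        return cls(
            input_dir=raw.get("input_dir"),
            simulate=SimulationConfig(**sim) if sim is not None else None,
            thresholds=Thresholds(**raw.get("thresholds", {})),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir", "mdsweave_out"),
        )

    def to_yaml(self, path):
        raw = {
            "input_dir": self.input_dir,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "thresholds": self.thresholds.to_dict(),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
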