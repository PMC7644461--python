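"""Pipeline configuration.

Every analysis constant — the 0.05 significance level, 9999 permutation
iterations, 999 random networks, the 2.5/97.5% null thresholds implied by
those networks, the 90% biovolume dominance rule, the bloom rules — is a
configurable default here, never hard-coded in a stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input/output paths
    abundance: str = ""
    taxa: str = ""
    fluorescence: str = ""
    abundance_b: str = ""  # optional second campaign for inter-annual comparison
    outdir: str = "planktonet_out"
    # statistics
    alpha: float = 0.05
    n_permutations: int = 9999
    n_random_networks: int = 999
    seed: int = 0
    # bloom rules
    min_pos_start: int = 2
    min_window: int = 5
    end_neg_run: int = 5
    max_gap_weeks: int = 2
    # size classes / dominance
    pelt_penalty: float | None = None  # None -> 2 log n
    dominance_threshold: float = 0.90
    # reporting
    boundary_precision: int = 0
    min_period_samples: int = 4
    hub_k: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("n_permutations", "n_random_networks", "min_pos_start",
                     "min_window", "end_neg_run", "min_period_samples", "hub_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_gap_weeks < 0:
            raise ValueError("max_gap_weeks must be nonnegative")
        if not 0 < self.dominance_threshold <= 1:
            raise ValueError("dominance_threshold must be in (0, 1]")
        if self.pelt_penalty is not None and self.pelt_penalty <= 0:
            raise ValueError("pelt_penalty must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
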