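"""Analysis configuration: every tunable bin size, threshold, window and
seed of the pipeline in one YAML-serialisable place.

Defaults reproduce the canonical analysis; fields exist so that the
conventions the underlying recordings leave open (classification cutoffs,
shuffle counts, clustering ranges) can be varied without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # PSTH bin sizes (s)
    bin_lr_s: float = 0.025
    bin_qi_s: float = 0.2
    bin_latency_s: float = 0.001
    bin_features_s: float = 0.05

    # light-responsiveness test
    n_shuffles_lr: int = 10_000
    lr_alpha: float = 1e-4

    # exclusion rules
    min_active_bin_fraction: float = 0.10
    min_active_trials: int = 8

    # classification thresholds
    bias_off_threshold: float = -1.0 / 3.0
    bias_on_threshold: float = 1.0 / 3.0
    transience_sustained_threshold: float = 0.5

    # tuning-fit inclusion
    r2_inclusion: float = 0.5
    spread_inclusion: float = 0.51

    # community detection
    n_cluster_repeats: int = 50
    k_max: int = 20
    bayes_factor_threshold: float = 6.0
    min_community_size: int = 5
    n_shuffles_distribution: int = 1000

    # seeds
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
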