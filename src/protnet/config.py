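"""Run configuration with the study's network-analysis defaults.

Defaults reproduce the published analysis settings: soft-threshold power 29
on an unsigned network, TOM with the mean denominator, deepSplit 4, minimum
module size 25, merge cut height 0.07, PAM stage on, module reassignment at
p < 0.05, volcano thresholds p <= 0.05 and |log2 ratio| > log2(1.25), and
sample-connectivity outliers beyond 3 SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

NETWORK_TYPES = ("unsigned", "signed")
CORR_METHODS = ("pearson", "bicor")
TOM_DENOMS = ("min", "mean")


@dataclass
class RunConfig:
    p_threshold: float = 0.05
    log2fc_threshold: float = math.log2(1.25)
    beta: int = 29
    network_type: str = "unsigned"
    corr_method: str = "pearson"        # network construction
    trait_corr_method: str = "bicor"    # module-trait and missing-protein mapping
    tom_denom: str = "mean"
    deep_split: int = 4
    min_module_size: int = 25
    merge_cut_height: float = 0.07
    pam_stage: bool = True
    reassign_threshold: float = 0.05
    outlier_sd: float = 3.0
    drop_outliers: bool = False
    median_center: bool = False
    volcano_p: str = "tukey"            # which p drives volcano classes: "tukey" | "anova"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be positive")
        if not (isinstance(self.beta, int) and self.beta >= 1):
            raise ValueError("beta must be a positive integer")
        if self.network_type not in NETWORK_TYPES:
            raise ValueError(f"network_type must be one of {NETWORK_TYPES}")
        if self.corr_method not in CORR_METHODS:
            raise ValueError(f"corr_method must be one of {CORR_METHODS}")
        if self.trait_corr_method not in CORR_METHODS:
            raise ValueError(f"trait_corr_method must be one of {CORR_METHODS}")
        if self.tom_denom not in TOM_DENOMS:
            raise ValueError(f"tom_denom must be one of {TOM_DENOMS}")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be an integer in 0..4")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be positive")
        if not 0 <= self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in [0, 1)")
        if not 0 <= self.reassign_threshold <= 1:
            raise ValueError("reassign_threshold must be in [0, 1]")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        if self.volcano_p not in ("tukey", "anova"):
            raise ValueError("volcano_p must be 'tukey' or 'anova'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
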