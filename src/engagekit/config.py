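"""Pipeline configuration: every analysis threshold in one place.

Defaults are the thresholds the analysis is built around: a 2-peptide
identification floor, the >3-missing / first-5-present curve filter, the
0.5 +/- 0.05 direct Tm band, a 1.5 deg C shift cutoff at alpha 0.05, a 0.1
CV robustness bound, the 2x-DEAB screen cutoff, and the 0.52 ECFP4
Tanimoto ceiling for diversity picking.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic import TPP_LADDER


@dataclass
class PipelineConfig:
    ladder: tuple = TPP_LADDER
    condition_pair: tuple = ("treated", "vehicle")
    min_peptides: int = 2
    max_missing: int = 3
    first_k_required: int = 5
    tm_tolerance: float = 0.05
    shift_cutoff: float = 1.5
    alpha: float = 0.05
    cv_cutoff: float = 0.1
    screen_multiplier: float = 2.0
    sim_cutoff: float = 0.52
    invert_scaling: bool = False
    test: str = "welch"
    bh_correction: bool = False
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("min_peptides", "max_missing", "first_k_required"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tm_tolerance", "shift_cutoff", "alpha", "cv_cutoff",
                     "screen_multiplier", "sim_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.test not in {"welch", "permutation"}:
            raise ValueError("test must be 'welch' or 'permutation'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ladder"] = list(self.ladder)
        d["condition_pair"] = list(self.condition_pair)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ladder" in data:
            data["ladder"] = tuple(data["ladder"])
        if "condition_pair" in data:
            data["condition_pair"] = tuple(data["condition_pair"])
        return cls(**data)

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
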