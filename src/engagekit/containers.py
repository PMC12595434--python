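"""Core in-memory containers shared across the pipeline.

The melt dataset mirrors the shape of a DIA search-engine protein report:
a wide protein x run abundance matrix, a per-protein peptide count, and a
run manifest carrying condition / replicate / temperature metadata plus the
per-run identified-precursor totals used for depth scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Column order of a run manifest frame.
MANIFEST_COLUMNS = ["run_id", "condition", "replicate", "temperature",
                    "is_reference", "precursor_count"]


@dataclass
class ProteinQuantTable:
    """Protein-level quantities: wide abundance matrix + peptide counts.

    abundance
        DataFrame indexed by protein_id with one float column per run_id;
        missing measurements are NaN, never zero.
    peptide_counts
        Series of identified-peptide counts aligned to ``abundance.index``.
    """

    abundance: pd.DataFrame
    peptide_counts: pd.Series

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.peptide_counts.index):
            self.peptide_counts = self.peptide_counts.reindex(self.abundance.index)
        vals = self.abundance.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("protein abundances must be nonnegative where present")

    @property
    def protein_ids(self) -> pd.Index:
        return self.abundance.index

    def subset(self, protein_ids) -> "ProteinQuantTable":
        return ProteinQuantTable(self.abundance.loc[protein_ids].copy(),
                                 self.peptide_counts.loc[protein_ids].copy())

    def equals(self, other: "ProteinQuantTable") -> bool:
        return (self.abundance.equals(other.abundance)
                and self.peptide_counts.equals(other.peptide_counts))


@dataclass
class MeltDataset:
    """A full thermal-denaturation experiment: quant table + run manifest."""

    manifest: pd.DataFrame
    quant: ProteinQuantTable

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.manifest.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        unknown = set(self.quant.abundance.columns) - set(self.manifest["run_id"])
        if unknown:
            raise ValueError(f"abundance columns not in manifest: {sorted(unknown)}")

    @property
    def ladder(self) -> np.ndarray:
        temps = self.manifest.loc[~self.manifest["is_reference"], "temperature"]
        return np.sort(temps.dropna().unique())

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.manifest["condition"]))


_STAGES = ("raw", "scaled", "median_normalized", "reference_normalized", "filtered")


@dataclass
class NormalizedMeltTable:
    """Abundance matrix tagged with its normalization stage.

    Stages advance strictly in the order
    raw -> scaled -> median_normalized -> reference_normalized -> filtered;
    each stage refuses out-of-order input.  ``audit`` accumulates the
    divisors used and the curves dropped so every filtering decision is
    inspectable downstream.
    """

    abundance: pd.DataFrame
    stage: str = "raw"
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")

    def require_stage(self, expected: str) -> None:
        if self.stage != expected:
            raise ValueError(
                f"normalization stages out of order: expected {expected!r} input, "
                f"got {self.stage!r}")

    def advance(self, new_abundance: pd.DataFrame, new_stage: str,
                **audit_entries) -> "NormalizedMeltTable":
        if _STAGES.index(new_stage) != _STAGES.index(self.stage) + 1:
            raise ValueError(f"cannot advance from {self.stage!r} to {new_stage!r}")
        return replace(self, abundance=new_abundance, stage=new_stage,
                       audit={**self.audit, **audit_entries})
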