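"""Four-stage normalization of a melt dataset.

Stage order is fixed: depth scaling -> per-protein per-condition median
division -> reference-sample division -> missing-pattern filtering.  Each
stage tags its output and refuses out-of-order input, and the audit dict
records every divisor and every dropped curve.

Depth scaling follows the convention of multiplying each run's abundances
by precursor_count(run) / mean(condition precursor counts); the inverse
(conventional depth correction, deeper runs scaled *down*) is available via
``invert_scaling``.  Reference runs are never rescaled and their precursor
counts are excluded from the condition mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MeltDataset, NormalizedMeltTable, ProteinQuantTable


def compute_scaling_factors(manifest: pd.DataFrame,
                            invert: bool = False) -> pd.Series:
    """Per-run depth scaling factors from identified-precursor totals.

    factor(run) = precursor_count(run) / mean over that run's condition
    (denaturation runs only).  With ``invert=True`` the reciprocal is
    returned.  Reference runs get factor 1.0.  Within each condition the
    mean of the denaturation-run factors is 1 by construction.
    """
    counts = manifest.set_index("run_id")["precursor_count"].astype(float)
    if (counts[~manifest.set_index("run_id")["is_reference"]] <= 0).any():
        raise ValueError("precursor counts must be > 0 for denaturation runs")
    factors = pd.Series(1.0, index=counts.index, name="scaling_factor")
    denat = manifest[~manifest["is_reference"]]
    for _, grp in denat.groupby("condition"):
        run_ids = grp["run_id"]
        f = counts[run_ids] / counts[run_ids].mean()
        factors[run_ids] = (1.0 / f) if invert else f
    return factors


def apply_scaling(table: NormalizedMeltTable,
                  factors: pd.Series) -> NormalizedMeltTable:
    """Multiply every run's abundances by that run's scaling factor.

    Missing values stay missing.  Every abundance column must be covered.
    """
    table.require_stage("raw")
    uncovered = [c for c in table.abundance.columns if c not in factors.index]
    if uncovered:
        raise ValueError(f"runs without scaling factors: {uncovered}")
    scaled = table.abundance * factors[table.abundance.columns]
    return table.advance(scaled, "scaled",
                         scaling_factors=factors[table.abundance.columns])


def median_normalize_by_protein(table: NormalizedMeltTable,
                                manifest: pd.DataFrame) -> NormalizedMeltTable:
    """Divide each protein by its per-condition median abundance.

    The median is taken over the condition's denaturation runs (all
    temperatures and replicates, non-missing values only); reference runs
    are excluded from the median but are divided by it, so all runs of a
    condition land on the same per-protein scale.  Proteins with no
    non-missing denaturation value in a condition are left missing there and
    flagged in the audit.
    """
    table.require_stage("scaled")
    out = table.abundance.copy()
    no_median: dict[str, list[str]] = {}
    for cond, grp in manifest.groupby("condition", sort=False):
        denat_cols = list(grp.loc[~grp["is_reference"], "run_id"])
        all_cols = [c for c in grp["run_id"] if c in out.columns]
        med = table.abundance[denat_cols].median(axis=1, skipna=True)
        out[all_cols] = out[all_cols].div(med, axis=0)
        flagged = list(med.index[med.isna()])
        if flagged:
            no_median[cond] = flagged
            out.loc[flagged, all_cols] = np.nan
    return table.advance(out, "median_normalized",
                         proteins_without_condition_median=no_median)


def reference_normalize(table: NormalizedMeltTable,
                        manifest: pd.DataFrame) -> NormalizedMeltTable:
    """Divide each protein by its median across the reference runs.

    Per condition, the divisor is the protein's median over that condition's
    non-denatured reference runs; proteins with no reference-based median
    fall back to the median over proteins of the per-protein reference
    medians.  After this stage a well-behaved curve starts near 1.
    """
    table.require_stage("median_normalized")
    out = table.abundance.copy()
    audit: dict[str, dict] = {}
    for cond, grp in manifest.groupby("condition", sort=False):
        ref_cols = list(grp.loc[grp["is_reference"], "run_id"])
        if not ref_cols:
            raise ValueError(f"condition {cond!r} has no reference runs")
        all_cols = [c for c in grp["run_id"] if c in out.columns]
        ref_med = table.abundance[ref_cols].median(axis=1, skipna=True)
        fallback = float(ref_med.median(skipna=True))
        n_fallback = int(ref_med.isna().sum())
        divisor = ref_med.fillna(fallback)
        out[all_cols] = out[all_cols].div(divisor, axis=0)
        audit[cond] = {"fallback_divisor": fallback,
                       "n_fallback_proteins": n_fallback}
    return table.advance(out, "reference_normalized", reference_divisors=audit)


def filter_missing_pattern(table: NormalizedMeltTable, manifest: pd.DataFrame,
                           max_missing: int = 3,
                           first_k_required: int = 5) -> NormalizedMeltTable:
    """Drop unreliable curves by their missing-value pattern.

    A curve (one protein, one condition, one replicate, across the full
    temperature ladder) is discarded iff it has more than ``max_missing``
    missing values, unless all of the ``first_k_required`` lowest
    temperatures are present — early-melting proteins legitimately vanish
    from the upper half of the ladder.
    """
    table.require_stage("reference_normalized")
    out = table.abundance.copy()
    dropped: list[tuple[str, str, int]] = []
    denat = manifest[~manifest["is_reference"]]
    for (cond, rep), grp in denat.groupby(["condition", "replicate"], sort=False):
        ordered = grp.sort_values("temperature")
        cols = list(ordered["run_id"])
        lowest = cols[:first_k_required]
        missing = out[cols].isna()
        n_missing = missing.sum(axis=1)
        low_complete = ~missing[lowest].any(axis=1)
        drop = (n_missing > max_missing) & ~low_complete
        for pid in out.index[drop]:
            dropped.append((pid, cond, int(rep)))
        out.loc[drop, cols] = np.nan
    dropped_df = pd.DataFrame(dropped,
                              columns=["protein_id", "condition", "replicate"])
    return table.advance(out, "filtered", dropped_curves=dropped_df)


def normalize_dataset(dataset: MeltDataset, invert_scaling: bool = False,
                      max_missing: int = 3,
                      first_k_required: int = 5) -> NormalizedMeltTable:
    """Run the full normalization chain on a melt dataset."""
    table = NormalizedMeltTable(dataset.quant.abundance.copy(), "raw")
    factors = compute_scaling_factors(dataset.manifest, invert=invert_scaling)
    table = apply_scaling(table, factors)
    table = median_normalize_by_protein(table, dataset.manifest)
    table = reference_normalize(table, dataset.manifest)
    return filter_missing_pattern(table, dataset.manifest,
                                  max_missing=max_missing,
                                  first_k_required=first_k_required)


class TPPNormalizer:
    """Estimator-style wrapper around the normalization chain.

    Parameters mirror :func:`normalize_dataset`; ``fit`` computes the per-run
    scaling factors from the manifest, ``transform`` applies the full chain
    to a wide abundance frame.  Fitted attributes: ``scaling_factors_``,
    ``dropped_curves_``, ``audit_``.
    """

    def __init__(self, manifest: pd.DataFrame | None = None,
                 invert_scaling: bool = False, max_missing: int = 3,
                 first_k_required: int = 5):
        self.manifest = manifest
        self.invert_scaling = invert_scaling
        self.max_missing = max_missing
        self.first_k_required = first_k_required

    def get_params(self, deep: bool = True) -> dict:
        return {"manifest": self.manifest,
                "invert_scaling": self.invert_scaling,
                "max_missing": self.max_missing,
                "first_k_required": self.first_k_required}

    def set_params(self, **params) -> "TPPNormalizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "TPPNormalizer":
        if self.manifest is None:
            raise ValueError("a run manifest is required")
        self.scaling_factors_ = compute_scaling_factors(
            self.manifest, invert=self.invert_scaling)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "scaling_factors_"):
            self.fit(X)
        table = NormalizedMeltTable(X.copy(), "raw")
        table = apply_scaling(table, self.scaling_factors_)
        table = median_normalize_by_protein(table, self.manifest)
        table = reference_normalize(table, self.manifest)
        table = filter_missing_pattern(table, self.manifest,
                                       max_missing=self.max_missing,
                                       first_k_required=self.first_k_required)
        self.dropped_curves_ = table.audit["dropped_curves"]
        self.audit_ = table.audit
        return table.abundance

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
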