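"""Melting-temperature estimation and melt-shift hit calling.

Tm is the temperature at which a protein's reference-normalized soluble
abundance falls to 0.5.  Estimation follows a three-branch rule:

direct
    if a measured ladder point already lies within 0.5 +/- tm_tolerance,
    that ladder temperature is the Tm (closest-to-0.5 wins ties, then the
    lower temperature);
spline
    otherwise a natural cubic interpolating spline through the non-missing
    points is evaluated on a fine grid and the lowest grid temperature where
    it crosses 0.5 from above is taken;
fallback
    if no crossing exists, Tm is set to the ladder maximum.

A melt shift (delta Tm, treated minus vehicle, positive = stabilization) is
called a hit when |delta Tm| exceeds the shift cutoff and the replicate-level
test (Welch by default) gives p below alpha; a per-condition coefficient of
variation of the replicate Tm values flags curves robust enough to trust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .containers import NormalizedMeltTable


@dataclass(frozen=True)
class MeltCurve:
    """One protein's melt series in one condition and replicate.

    Holds the non-missing (temperature, relative abundance) points sorted by
    temperature, plus the full ladder the experiment used.
    """

    protein_id: str
    condition: str
    replicate: int
    temperatures: np.ndarray
    abundances: np.ndarray
    ladder: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("curve temperatures must be strictly increasing")


@dataclass(frozen=True)
class TmEstimate:
    protein_id: str
    condition: str
    replicate: int
    tm: float
    method: str  # direct | spline | fallback


def assemble_curves(table: NormalizedMeltTable,
                    manifest: pd.DataFrame) -> list[MeltCurve]:
    """One curve per (protein, condition, replicate) with any data left.

    Point order is sorted by temperature regardless of input column order;
    curves emptied by the missing-pattern filter are absent from the output.
    """
    table.require_stage("filtered")
    denat = manifest[~manifest["is_reference"]]
    ladder = np.sort(denat["temperature"].unique())
    curves: list[MeltCurve] = []
    for (cond, rep), grp in denat.groupby(["condition", "replicate"], sort=False):
        ordered = grp.sort_values("temperature")
        cols = list(ordered["run_id"])
        temps = ordered["temperature"].to_numpy(dtype=float)
        block = table.abundance[cols]
        present = block.notna().to_numpy()
        values = block.to_numpy(dtype=float)
        for i, pid in enumerate(block.index):
            mask = present[i]
            if not mask.any():
                continue
            curves.append(MeltCurve(pid, cond, int(rep),
                                    temps[mask], values[i, mask], ladder))
    return curves


def estimate_tm(curve: MeltCurve, tm_tolerance: float = 0.05,
                grid_step: float = 0.01) -> TmEstimate:
    """Estimate the melting temperature of a single curve.

    See the module docstring for the direct / spline / fallback rule.
    Curves with fewer than two points cannot be estimated; curves with
    fewer than four points (too few for a cubic spline) fall through to
    the fallback unless a direct hit exists.
    """
    t, a = curve.temperatures, curve.abundances
    if len(t) < 2:
        raise ValueError(
            f"{curve.protein_id}/{curve.condition}/r{curve.replicate}: "
            "need at least 2 points to estimate a Tm")
    lo, hi = float(curve.ladder[0]), float(curve.ladder[-1])

    dist = np.abs(a - 0.5)
    in_band = dist <= tm_tolerance
    if in_band.any():
        idx = np.flatnonzero(in_band)
        # closest to 0.5; ties broken toward the lower temperature
        # (distances rounded so 0.5 +/- d pairs tie despite float error)
        best = idx[np.lexsort((t[idx], np.round(dist[idx], 9)))[0]]
        return TmEstimate(curve.protein_id, curve.condition, curve.replicate,
                          float(t[best]), "direct")

    if len(t) >= 4:
        spline = CubicSpline(t, a, bc_type="natural")
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        y = spline(grid)
        above = y >= 0.5
        crossing = above[:-1] & ~above[1:]
        if crossing.any():
            i = int(np.argmax(crossing))
            tm = float(np.clip(grid[i + 1], lo, hi))
            return TmEstimate(curve.protein_id, curve.condition,
                              curve.replicate, tm, "spline")

    return TmEstimate(curve.protein_id, curve.condition, curve.replicate,
                      hi, "fallback")


def estimate_tm_table(curves, tm_tolerance: float = 0.05,
                      grid_step: float = 0.01) -> pd.DataFrame:
    """Tm estimates for a list of curves as a tidy frame."""
    rows = [estimate_tm(c, tm_tolerance, grid_step) for c in curves]
    return pd.DataFrame([r.__dict__ for r in rows])


def compute_delta_tm(tms_treated, tms_vehicle) -> float:
    """Mean treated Tm minus mean vehicle Tm (positive = stabilization)."""
    treated = np.asarray(tms_treated, dtype=float)
    vehicle = np.asarray(tms_vehicle, dtype=float)
    if treated.size == 0 or vehicle.size == 0:
        raise ValueError("both condition sides need at least one Tm estimate")
    return float(treated.mean() - vehicle.mean())


def shift_test(tms_treated, tms_vehicle, method: str = "welch",
               n_permutations: int = 10000, seed: int = 0) -> float:
    """Two-sided p-value for a replicate-level Tm difference.

    ``welch`` runs an unequal-variance t-test on the replicate Tm values.
    When both sides have zero variance the p-value is 1 for equal means and
    0 otherwise.  ``permutation`` tests the mean difference against the
    relabeling null (exact enumeration when feasible, otherwise Monte Carlo).
    """
    treated = np.asarray(tms_treated, dtype=float)
    vehicle = np.asarray(tms_vehicle, dtype=float)
    if treated.size < 2 or vehicle.size < 2:
        raise ValueError("need at least 2 replicates per side")

    if method == "welch":
        if np.ptp(treated) == 0 and np.ptp(vehicle) == 0:
            return 1.0 if treated.mean() == vehicle.mean() else 0.0
        with warnings.catch_warnings():
            # near-identical replicates trip scipy's precision-loss warning
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(treated, vehicle, equal_var=False)
        p = float(res.pvalue)
        return 1.0 if np.isnan(p) else p

    if method == "permutation":
        pooled = np.concatenate([treated, vehicle])
        n, k = pooled.size, treated.size
        observed = abs(treated.mean() - vehicle.mean())
        total = comb(n, k)
        if total <= n_permutations:
            count = 0
            for idx in combinations(range(n), k):
                sel = np.zeros(n, dtype=bool)
                sel[list(idx)] = True
                diff = abs(pooled[sel].mean() - pooled[~sel].mean())
                if diff >= observed - 1e-12:
                    count += 1
            return count / total
        rng = np.random.default_rng(seed)
        count = 1  # identity permutation
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            diff = abs(perm[:k].mean() - perm[k:].mean())
            if diff >= observed - 1e-12:
                count += 1
        return count / (n_permutations + 1)

    raise ValueError(f"unknown test method {method!r}")


def coefficient_of_variation(values) -> float:
    """sd / mean of replicate Tm values (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / v.mean())


def cv_filter(results: pd.DataFrame, cv_cutoff: float = 0.1) -> pd.DataFrame:
    """Flag results whose per-condition CVs are all below the cutoff."""
    cv_cols = [c for c in results.columns if c.startswith("cv_")]
    out = results.copy()
    out["robust"] = (out[cv_cols] < cv_cutoff).all(axis=1)
    return out


def call_hits(tm_table: pd.DataFrame, pair: tuple[str, str],
              shift_cutoff: float = 1.5, alpha: float = 0.05,
              cv_cutoff: float = 0.1, test: str = "welch",
              bh_correction: bool = False) -> pd.DataFrame:
    """Call melt-shift hits between a (treated, vehicle) condition pair.

    A protein is a hit iff |delta Tm| >= ``shift_cutoff`` and the
    replicate-level p-value is below ``alpha``; proteins additionally
    satisfying the per-condition CV cutoff are flagged robust.  Proteins
    lacking two replicate estimates on either side are excluded.  Results
    are sorted by |delta Tm| descending.  ``bh_correction`` optionally
    replaces raw p-values by Benjamini-Hochberg adjusted ones before the
    alpha comparison.
    """
    treated_label, vehicle_label = pair
    rows = []
    for pid, grp in tm_table.groupby("protein_id", sort=False):
        treated = grp.loc[grp["condition"] == treated_label, "tm"].to_numpy()
        vehicle = grp.loc[grp["condition"] == vehicle_label, "tm"].to_numpy()
        if treated.size < 2 or vehicle.size < 2:
            continue
        rows.append({
            "protein_id": pid,
            "delta_tm": compute_delta_tm(treated, vehicle),
            "p_value": shift_test(treated, vehicle, method=test),
            f"cv_{treated_label}": coefficient_of_variation(treated),
            f"cv_{vehicle_label}": coefficient_of_variation(vehicle),
            "n_treated": treated.size,
            "n_vehicle": vehicle.size,
        })
    results = pd.DataFrame(rows)
    if results.empty:
        results = pd.DataFrame(columns=[
            "protein_id", "delta_tm", "p_value", f"cv_{treated_label}",
            f"cv_{vehicle_label}", "n_treated", "n_vehicle"])
    p_for_call = results["p_value"]
    if bh_correction and len(results):
        p_for_call = pd.Series(
            stats.false_discovery_control(results["p_value"], method="bh"),
            index=results.index)
        results["p_adjusted"] = p_for_call
    results["hit"] = ((results["delta_tm"].abs() >= shift_cutoff)
                      & (p_for_call < alpha))
    results = cv_filter(results, cv_cutoff)
    order = results["delta_tm"].abs().sort_values(ascending=False).index
    return results.loc[order].reset_index(drop=True)
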