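"""Biochemical screen analytics.

Covers the full analytic chain of a coupled-fluorescence enzyme screen:
kinetic reaction velocities from plate traces, hit calling anchored to the
full-inhibition (DEAB) control, four-parameter logistic (4PL) dose-response
fitting for IC50s, 1:1-site binding isotherms for thermophoresis K_D
estimates, and Michaelis-Menten / double-reciprocal diagnostics that
classify an inhibitor's competition mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class DegeneratePlateError(ValueError):
    """Control wells do not separate (mean DMSO velocity <= mean DEAB)."""


def compute_velocity(times, fluorescence, window: tuple | None = None) -> float:
    """Reaction velocity (AU/s): OLS slope of fluorescence vs. time.

    ``window`` restricts the fit to a (t_start, t_end) interval; at least
    three samples must remain.  Invariant under adding a constant to the
    fluorescence values.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, f = t[keep], f[keep]
    if t.size < 3:
        raise ValueError("need at least 3 samples inside the window")
    slope, _ = np.polyfit(t, f, 1)
    return float(slope)


def plate_velocities(plate: pd.DataFrame,
                     window: tuple | None = None) -> pd.DataFrame:
    """Velocity per well from a long plate table.

    Expects columns well, role, compound_id, time_s, fluorescence (the
    dialect the plate simulator writes).
    """
    rows = []
    for well, grp in plate.groupby("well", sort=False):
        grp = grp.sort_values("time_s")
        rows.append({
            "well": well,
            "role": grp["role"].iloc[0],
            "compound_id": grp["compound_id"].iloc[0],
            "velocity": compute_velocity(grp["time_s"], grp["fluorescence"],
                                         window=window),
        })
    return pd.DataFrame(rows)


def call_screen_hits(velocities: pd.DataFrame,
                     multiplier: float = 2.0) -> pd.DataFrame:
    """Call screen hits against the DEAB-derived cutoff.

    A compound well is a hit iff its velocity is at or below
    ``multiplier`` x mean(DEAB velocities) — i.e. within 2-fold of the
    full-inhibition control signal.  Percent inhibition is reported on the
    DMSO/DEAB control scale, clipped to [0, 100].
    """
    roles = velocities["role"]
    deab = velocities.loc[roles == "DEAB", "velocity"]
    dmso = velocities.loc[roles == "DMSO", "velocity"]
    if deab.empty or dmso.empty:
        raise DegeneratePlateError("plate needs at least one DEAB and one DMSO well")
    v_deab, v_dmso = float(deab.mean()), float(dmso.mean())
    if v_dmso <= v_deab:
        raise DegeneratePlateError(
            f"controls do not separate: mean DMSO velocity {v_dmso:.4g} <= "
            f"mean DEAB velocity {v_deab:.4g}")
    cutoff = multiplier * v_deab
    out = velocities.loc[roles == "compound"].copy()
    out["hit"] = out["velocity"] <= cutoff
    pct = 100.0 * (1.0 - (out["velocity"] - v_deab) / (v_dmso - v_deab))
    out["percent_inhibition"] = pct.clip(0.0, 100.0)
    out.attrs["cutoff"] = cutoff
    out.attrs["mean_deab"] = v_deab
    out.attrs["mean_dmso"] = v_dmso
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# dose-response (4PL)

def four_pl(conc, bottom, top, ic50, hill):
    """r(c) = bottom + (top - bottom) / (1 + (c / ic50) ** hill)."""
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ic50: float
    hill: float
    residual_sse: float
    converged: bool = True

    def predict(self, conc):
        return four_pl(conc, self.bottom, self.top, self.ic50, self.hill)


def fit_4pl(concentrations, responses, n_starts: int = 5,
            hill_bounds: tuple = (0.2, 10.0)) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    Fitted in log-concentration space (the model is evaluated against
    10**x) to tame the well-known local minima of logistic dose-response
    fitting.  IC50 starting points sweep the measured concentration range;
    the best-SSE solution wins.  The Hill magnitude is bounded to
    ``hill_bounds``; a fitted curve with top < bottom is reported with the
    asymptotes swapped and the Hill sign flipped so top >= bottom always
    holds.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")

    x = np.log10(c)

    def model(logc, bottom, top, log_ic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))

    lo, hi = float(r.min()), float(r.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    starts = np.quantile(x, np.linspace(0.1, 0.9, n_starts))
    bounds = ([lo - 2 * span, lo - 2 * span, x.min() - 3, hill_bounds[0]],
              [hi + 2 * span, hi + 2 * span, x.max() + 3, hill_bounds[1]])

    best: tuple[float, np.ndarray] | None = None
    for log_ic50_0 in starts:
        p0 = [lo, hi, float(log_ic50_0), 1.0]
        try:
            popt, _ = curve_fit(model, x, r, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((model(x, *popt) - r) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError(
            "4PL fit failed to converge from any start; response range "
            f"[{lo:.4g}, {hi:.4g}] over {np.unique(c).size} concentrations")

    sse, (bottom, top, log_ic50, hill) = best
    if top < bottom:
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(float(bottom), float(top), float(10.0 ** log_ic50),
                     float(hill), sse)


def fit_dose_table(doses: pd.DataFrame) -> pd.DataFrame:
    """Fit a 4PL per compound from a long dose table.

    Expects columns compound_id, conc_nM, response; returns the fit-report
    frame (compound, ic50_nM, hill, top, bottom, sse, converged).
    """
    rows = []
    for cid, grp in doses.groupby("compound_id", sort=False):
        try:
            fit = fit_4pl(grp["conc_nM"], grp["response"])
            rows.append({"compound_id": cid, "ic50_nM": fit.ic50,
                         "hill": fit.hill, "top": fit.top,
                         "bottom": fit.bottom, "sse": fit.residual_sse,
                         "converged": True})
        except (RuntimeError, ValueError):
            rows.append({"compound_id": cid, "ic50_nM": np.nan, "hill": np.nan,
                         "top": np.nan, "bottom": np.nan, "sse": np.nan,
                         "converged": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binding isotherm (MST-style ratio readout)

@dataclass
class BindingFit:
    kd: float
    baseline: float
    amplitude: float
    residual_sse: float
    identifiable: bool = True

    def predict(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.baseline + self.amplitude * c / (c + self.kd)


def fit_binding_isotherm(ligand_concs, ratios) -> BindingFit:
    """1:1-site binding isotherm fit: ratio(L) = baseline + amp * L / (L + Kd).

    Suits fluorescence-ratio readouts (e.g. a 670 nm / 650 nm thermophoresis
    ratio) titrated against ligand.  A fit whose amplitude is negligible
    against the measurement spread leaves Kd unidentifiable and is flagged.
    """
    L = np.asarray(ligand_concs, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if np.unique(L).size < 4:
        raise ValueError("need at least 4 distinct ligand concentrations")
    if np.any(L <= 0):
        raise ValueError("ligand concentrations must be > 0")

    def model(conc, baseline, amplitude, log_kd):
        return baseline + amplitude * conc / (conc + 10.0 ** log_kd)

    spread = float(y.max() - y.min())
    p0 = [float(y.min()), spread if spread > 0 else 1.0,
          float(np.log10(np.median(L)))]
    bounds = ([-np.inf, -np.inf, np.log10(L.min()) - 4],
              [np.inf, np.inf, np.log10(L.max()) + 4])
    try:
        popt, _ = curve_fit(model, L, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"binding isotherm fit failed: {err}") from None
    baseline, amplitude, log_kd = popt
    sse = float(np.sum((model(L, *popt) - y) ** 2))
    noise_scale = max(np.sqrt(sse / max(L.size - 3, 1)), 1e-12 * max(abs(y).max(), 1.0))
    identifiable = abs(amplitude) > 10.0 * noise_scale or (
        spread > 0 and abs(amplitude) > 0.05 * spread)
    return BindingFit(float(10.0 ** log_kd), float(baseline),
                      float(amplitude), sse, bool(identifiable))


# ---------------------------------------------------------------------------
# Michaelis-Menten kinetics and inhibition-mode classification

def michaelis_menten(substrate, vmax, km):
    s = np.asarray(substrate, dtype=float)
    return vmax * s / (km + s)


def fit_michaelis_menten(substrate_concs, velocities) -> tuple[float, float]:
    """Nonlinear least-squares (Vmax, Km) from substrate titration."""
    s = np.asarray(substrate_concs, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 substrate levels")
    if np.any(v <= 0):
        raise ValueError("velocities must be positive")
    p0 = [float(v.max()), float(np.median(s))]
    popt, _ = curve_fit(michaelis_menten, s, v, p0=p0,
                        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000)
    return float(popt[0]), float(popt[1])


@dataclass
class KineticsSummary:
    """Apparent MM parameters per inhibitor level plus the mode call."""

    levels: pd.DataFrame = field(repr=False)  # inhibitor, vmax, km, recip slope/intercept
    mode: str = "mixed"  # competitive | noncompetitive | uncompetitive | mixed


def reciprocal_kinetics(substrate_concs, velocities_by_level: dict,
                        tolerance: float = 0.2) -> KineticsSummary:
    """Classify inhibition mode from apparent-parameter trends.

    ``velocities_by_level`` maps inhibitor concentration -> velocities over
    ``substrate_concs``.  Per level a Michaelis-Menten fit gives apparent
    (Vmax, Km); the double-reciprocal line (1/v vs 1/[S]) is reported as a
    diagnostic (slope = Km/Vmax, intercept = 1/Vmax).  Relative to the
    zero-inhibitor level, within ``tolerance`` bands:

    - Km constant, Vmax decreasing -> noncompetitive
    - Vmax constant, Km increasing -> competitive
    - Vmax and Km decreasing in proportion -> uncompetitive
    - anything else -> mixed
    """
    s = np.asarray(substrate_concs, dtype=float)
    inv_s = 1.0 / s
    rows = []
    for level in sorted(velocities_by_level):
        v = np.asarray(velocities_by_level[level], dtype=float)
        vmax, km = fit_michaelis_menten(s, v)
        slope, intercept = np.polyfit(inv_s, 1.0 / v, 1)
        rows.append({"inhibitor": float(level), "vmax": vmax, "km": km,
                     "recip_slope": float(slope),
                     "recip_intercept": float(intercept)})
    levels = pd.DataFrame(rows)
    if len(levels) < 2:
        return KineticsSummary(levels, "mixed")

    base = levels.iloc[0]
    top = levels.iloc[-1]
    km_ratio = top["km"] / base["km"]
    vm_ratio = top["vmax"] / base["vmax"]
    km_const = abs(km_ratio - 1.0) <= tolerance
    vm_const = abs(vm_ratio - 1.0) <= tolerance
    km_up = km_ratio > 1.0 + tolerance
    km_down = km_ratio < 1.0 - tolerance
    vm_down = vm_ratio < 1.0 - tolerance

    if km_const and vm_down:
        mode = "noncompetitive"
    elif vm_const and km_up:
        mode = "competitive"
    elif vm_down and km_down and abs(km_ratio / vm_ratio - 1.0) <= tolerance:
        mode = "uncompetitive"
    else:
        mode = "mixed"
    return KineticsSummary(levels, mode)
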