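"""Synthetic datasets with the statistical structure the analysis assumes.

Every downstream stage (ingest, normalization, Tm estimation, hit calling,
plate analytics, dose-response fitting, chem triage) is testable against
data generated here, with ground truth attached.  The melt simulator
emulates a 10-temperature thermal-denaturation experiment (two conditions,
replicated, with non-denatured reference runs) in which a spiked subset of
proteins is thermally stabilized in the treated condition — the signature
of ligand target engagement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MANIFEST_COLUMNS, MeltDataset, ProteinQuantTable

#: Default 10-point denaturation ladder (deg C), low to high.
TPP_LADDER = (36.9, 40.2, 43.9, 46.6, 48.6, 52.7, 55.3, 58.8, 61.2, 64.0)

#: 7-point ladder of the single-protein (western-blot) thermal shift assay.
CETSA_LADDER = (46.3, 48.6, 52.2, 56.5, 60.1, 62.5, 64.0)


def melt_curve_model(temperature, tm, slope, plateau=0.0):
    """Three-parameter logistic melting curve (upper asymptote fixed at 1).

    relative abundance = plateau + (1 - plateau) / (1 + exp((T - tm) / slope))

    Strictly decreasing in temperature; equals (1 + plateau) / 2 at T = tm.

    Parameters
    ----------
    temperature : array-like, deg C
    tm : float, deg C — midpoint of the transition
    slope : float, deg C — transition width; must be > 0
    plateau : float in [0, 1) — residual non-denatured fraction
    """
    slope = float(slope)
    plateau = float(plateau)
    if slope <= 0:
        raise ValueError("slope must be positive")
    if not 0.0 <= plateau < 1.0:
        raise ValueError("plateau must lie in [0, 1)")
    t = np.asarray(temperature, dtype=float)
    out = plateau + (1.0 - plateau) / (1.0 + np.exp((t - tm) / slope))
    return out if out.shape else float(out)


def inverse_melt_curve(level, tm, slope, plateau=0.0):
    """Analytic temperature at which the logistic melt model equals ``level``.

    Used as an independent oracle for spline-based Tm estimation.
    """
    if not plateau < level < 1.0:
        raise ValueError("level outside the open range (plateau, 1)")
    frac = (1.0 - plateau) / (level - plateau) - 1.0
    return tm + slope * np.log(frac)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated thermal-denaturation experiment.

    Defaults follow the experimental design the analysis targets: a
    10-temperature ladder from 36.9 to 64.0 deg C, vehicle vs. treated,
    three replicates per condition, and a small spiked subset of proteins
    stabilized by ~4 deg C in the treated condition.
    """

    n_proteins: int = 2000
    n_spiked: int = 20
    ladder: tuple = TPP_LADDER
    conditions: tuple = ("vehicle", "treated")
    n_replicates: int = 3
    tm_range: tuple = (44.0, 58.0)
    shift_mean: float = 4.0
    shift_sd: float = 1.0
    plateau_range: tuple = (0.0, 0.2)
    slope_range: tuple = (1.0, 3.0)
    noise_sd: float = 0.03
    missing_rate: float = 0.02
    n_contaminants: int = 5
    depth_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = tuple(float(t) for t in self.ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ladder temperatures must be strictly increasing")
        for name in ("n_proteins", "n_spiked", "n_replicates", "n_contaminants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_spiked > self.n_proteins:
            raise ValueError("n_spiked cannot exceed n_proteins")
        if self.noise_sd < 0 or self.depth_sigma < 0:
            raise ValueError("noise_sd and depth_sigma must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")


def _build_manifest(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    base_precursors = 200_000
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            for temp in config.ladder:
                rows.append((f"{cond}_r{rep}_T{temp:g}", cond, rep, float(temp), False))
            rows.append((f"{cond}_r{rep}_REF", cond, rep, np.nan, True))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS[:5])
    depth = (np.exp(rng.normal(0.0, config.depth_sigma, len(manifest)))
             if config.depth_sigma > 0 else np.ones(len(manifest)))
    manifest["precursor_count"] = np.rint(base_precursors * depth).astype(int)
    manifest["_depth"] = depth
    return manifest


def simulate_melt_dataset(config: SimConfig) -> tuple[MeltDataset, pd.DataFrame]:
    """Simulate a protein x run melt dataset plus its ground truth.

    Per protein: abundance(run) = base * depth(run) * model(T) * lognormal
    noise for denaturation runs, and base * depth(run) * noise for reference
    runs.  Spiked proteins carry ``tm + shift`` in every non-vehicle
    condition (the vehicle Tm is shared).  Missing values are injected
    uniformly at ``missing_rate``; contaminant entries (``CON__`` ids) and a
    fraction of single-peptide proteins are appended so ingest filters have
    something to remove.

    Returns
    -------
    (MeltDataset, ground_truth)
        ground_truth has one row per protein: true Tm per condition,
        true shift, spiked flag, contaminant flag.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))

    n_total = config.n_proteins + config.n_contaminants
    ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    ids += [f"CON__SYN{j:03d}" for j in range(config.n_contaminants)]

    manifest = _build_manifest(config, rng_struct)

    base = np.exp(rng_struct.normal(np.log(1e6), 1.0, n_total))
    tm0 = rng_struct.uniform(*config.tm_range, n_total)
    slope = rng_struct.uniform(*config.slope_range, n_total)
    plateau = rng_struct.uniform(*config.plateau_range, n_total)

    spiked = np.zeros(n_total, dtype=bool)
    if config.n_spiked:
        spiked[rng_struct.choice(config.n_proteins, config.n_spiked,
                                 replace=False)] = True
    shift = np.zeros(n_total)
    shift[spiked] = np.abs(rng_struct.normal(config.shift_mean, config.shift_sd,
                                             spiked.sum()))

    peptide_counts = rng_struct.integers(2, 16, n_total)
    single = rng_struct.random(n_total) < 0.05
    peptide_counts[single] = 1

    vehicle = config.conditions[0]
    tm_by_cond = {c: tm0 + (shift if c != vehicle else 0.0)
                  for c in config.conditions}

    ladder = np.asarray(config.ladder)
    cols = {}
    for _, run in manifest.iterrows():
        tm_run = tm_by_cond[run["condition"]]
        if run["is_reference"]:
            frac = np.ones(n_total)
        else:
            t = run["temperature"]
            frac = plateau + (1.0 - plateau) / (1.0 + np.exp((t - tm_run) / slope))
        noise = (np.exp(rng_noise.normal(0.0, config.noise_sd, n_total))
                 if config.noise_sd > 0 else 1.0)
        cols[run["run_id"]] = base * run["_depth"] * frac * noise
    abundance = pd.DataFrame(cols, index=pd.Index(ids, name="protein_id"))

    if config.missing_rate > 0:
        mask = rng_noise.random(abundance.shape) < config.missing_rate
        abundance = abundance.mask(mask)

    manifest = manifest.drop(columns="_depth")
    quant = ProteinQuantTable(abundance,
                              pd.Series(peptide_counts, index=abundance.index,
                                        name="peptide_count"))
    truth = pd.DataFrame({"protein_id": ids, "shift": shift, "spiked": spiked,
                          "contaminant": [i.startswith("CON__") for i in ids]})
    # true Tm = temperature where the true curve crosses 0.5 (the melting
    # temperature proper), which sits above the logistic midpoint whenever
    # the plateau is nonzero; the midpoint parameter is kept alongside.
    with np.errstate(divide="ignore", invalid="ignore"):
        half_offset = np.where(
            plateau < 0.5,
            slope * np.log((1.0 - plateau) / (0.5 - plateau) - 1.0),
            np.nan)  # curve never reaches 0.5
    for c in config.conditions:
        truth[f"tm_{c}"] = tm_by_cond[c] + half_offset
        truth[f"midpoint_{c}"] = tm_by_cond[c]
    truth["slope"] = slope
    truth["plateau"] = plateau
    truth = truth.set_index("protein_id")
    return MeltDataset(manifest, quant), truth


# ---------------------------------------------------------------------------
# enzymatic screen plate

def simulate_screen_plate(n_compounds: int, hit_fraction: float = 0.02,
                          seed: int = 0, *, noise_sd: float = 0.5,
                          n_controls: int = 8, n_timepoints: int = 11,
                          dt_s: float = 60.0,
                          v_full: float = 1.0,
                          deab_inhibition: float = 0.95
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate kinetic fluorescence traces for a control-anchored screen.

    DMSO wells run at the uninhibited velocity, DEAB wells at a strongly
    inhibited velocity (full-inhibition positive control), and true hits are
    drawn below the 2x-mean-DEAB cutoff the hit caller applies.  Traces are
    linear ramps (slope = velocity, AU/s) plus Gaussian read noise.

    Returns (plate, truth): ``plate`` is the long CSV dialect
    (well, role, compound_id, time_s, fluorescence); ``truth`` has one row
    per compound well with the true velocity and hit label.
    """
    if n_compounds <= 0:
        raise ValueError("n_compounds must be > 0")
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValueError("hit_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    v_deab = v_full * (1.0 - deab_inhibition)
    cutoff = 2.0 * v_deab
    is_hit = rng.random(n_compounds) < hit_fraction
    v_cmpd = rng.uniform(0.6 * v_full, 1.1 * v_full, n_compounds)
    v_cmpd[is_hit] = rng.uniform(0.05, 0.85, is_hit.sum()) * cutoff

    wells, rows = [], []
    times = np.arange(n_timepoints) * dt_s
    f0 = 100.0

    def add_well(well, role, compound_id, v):
        trace = f0 + v * times + rng.normal(0.0, noise_sd, n_timepoints)
        for t, f in zip(times, trace):
            rows.append((well, role, compound_id, t, f))

    w = 1
    for i in range(n_compounds):
        add_well(f"W{w:03d}", "compound", f"CMP{i:04d}", v_cmpd[i]); w += 1
    for role, v in (("DMSO", v_full), ("DEAB", v_deab)):
        for _ in range(n_controls):
            add_well(f"W{w:03d}", role, "", v); w += 1

    plate = pd.DataFrame(rows, columns=["well", "role", "compound_id",
                                        "time_s", "fluorescence"])
    truth = pd.DataFrame({"compound_id": [f"CMP{i:04d}" for i in range(n_compounds)],
                          "true_velocity": v_cmpd, "is_hit": is_hit})
    return plate, truth


def simulate_dose_response(bottom: float, top: float, ic50: float, hill: float,
                           concentrations, noise_sd: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Responses from a 4-parameter logistic plus Gaussian noise.

    response(c) = bottom + (top - bottom) / (1 + (c / ic50) ** hill)
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    resp = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, conc.shape)
    return pd.DataFrame({"conc_nM": conc, "response": resp})


# ---------------------------------------------------------------------------
# compound library

_ACYL_GROUPS = ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "c1ccncc1", "CCc1cnccc1",
                "COc1ccccc1", "Fc1ccccc1", "Clc1ccccc1", "c1ccc2[nH]ccc2c1",
                "C1CCCCC1", "c1ccsc1"]
_AMINE_GROUPS = ["c1ccccc1", "Cc1ccccc1", "c1ccncc1", "c1ccc(OC)cc1",
                 "c1ccc(F)cc1", "c1ccc2ncccc2c1", "C1CCCCC1", "CC(C)",
                 "c1cc2CCC(=O)Nc2cc1F", "c1ccc(C)cc1C"]
_LINKERS = ["{a}C(=O)N{b}", "{a}S(=O)(=O)N{b}", "{a}CN{b}"]


def simulate_compound_library(n_compounds: int = 60, seed: int = 0
                              ) -> pd.DataFrame:
    """Generate a small drug-like SMILES library with synthetic docking ranks.

    Molecules are built combinatorially (amide / sulfonamide / aminomethyl
    linkers between aromatic and aliphatic fragments); hybrid and MOE ranks
    are independent random permutations, standing in for the two docking
    scorers whose outputs the triage stage consumes.
    """
    from rdkit import Chem, RDLogger

    rng = np.random.default_rng(seed)
    pool = []
    RDLogger.DisableLog("rdApp.error")  # invalid combinations are expected
    try:
        for linker in _LINKERS:
            for a in _ACYL_GROUPS:
                for b in _AMINE_GROUPS:
                    smi = linker.format(a=a, b=b)
                    if Chem.MolFromSmiles(smi) is not None:
                        pool.append(Chem.CanonSmiles(smi))
    finally:
        RDLogger.EnableLog("rdApp.error")
    pool = sorted(set(pool))
    if n_compounds > len(pool):
        raise ValueError(f"at most {len(pool)} distinct compounds available")
    picks = rng.choice(len(pool), n_compounds, replace=False)
    return pd.DataFrame({
        "compound_id": [f"VS{i:04d}" for i in range(n_compounds)],
        "smiles": [pool[i] for i in picks],
        "hybrid_rank": rng.permutation(n_compounds) + 1,
        "moe_rank": rng.permutation(n_compounds) + 1,
    })


# ---------------------------------------------------------------------------
# fixture bundle I/O

def write_fixture_bundle(dataset: MeltDataset, path,
                         contaminant_ids=()) -> dict[str, Path]:
    """Write a melt dataset as the TSV fixture bundle the ingest module reads.

    Emits ``runs.tsv`` (run manifest; temperature column carries ``REF`` for
    reference runs), ``proteins.tsv`` (protein report: protein_id,
    peptide_count, one column per run) and ``contaminants.txt``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    runs = dataset.manifest.copy()
    runs["temperature_or_REF"] = [
        "REF" if ref else f"{t:g}"
        for t, ref in zip(runs["temperature"], runs["is_reference"])]
    runs_path = path / "runs.tsv"
    runs[["run_id", "condition", "replicate", "temperature_or_REF",
          "precursor_count"]].to_csv(runs_path, sep="\t", index=False)

    report = dataset.quant.abundance.copy()
    report.insert(0, "peptide_count", dataset.quant.peptide_counts)
    proteins_path = path / "proteins.tsv"
    report.to_csv(proteins_path, sep="\t", index=True, na_rep="")

    contam_path = path / "contaminants.txt"
    contam_path.write_text("".join(f"{c}\n" for c in contaminant_ids))
    return {"runs": runs_path, "proteins": proteins_path,
            "contaminants": contam_path}
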