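import numpy as np
import pandas as pd
import pytest

from engagekit.containers import MeltDataset, NormalizedMeltTable, ProteinQuantTable
from engagekit.synthetic import SimConfig, simulate_melt_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulation shared across tests (read-only)."""
    config = SimConfig(n_proteins=150, n_spiked=8, seed=11)
    dataset, truth = simulate_melt_dataset(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free, complete simulation: curves equal the analytic model."""
    config = SimConfig(n_proteins=40, n_spiked=4, noise_sd=0.0,
                       missing_rate=0.0, n_contaminants=0, seed=3)
    dataset, truth = simulate_melt_dataset(config)
    return config, dataset, truth


def make_table(abundance: dict, run_ids, stage="raw") -> NormalizedMeltTable:
    """Tiny hand-built abundance table keyed by protein id."""
    df = pd.DataFrame.from_dict(abundance, orient="index", columns=run_ids,
                                dtype=float)
    df.index.name = "protein_id"
    return NormalizedMeltTable(df, stage)


def make_manifest(conditions=("vehicle", "treated"), n_replicates=1,
                  ladder=(40.0, 50.0, 60.0), n_refs=1,
                  precursor_counts=None) -> pd.DataFrame:
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for t in ladder:
                rows.append((f"{cond}_r{rep}_T{t:g}", cond, rep, t, False))
            for j in range(n_refs):
                rows.append((f"{cond}_r{rep}_REF{j}", cond, rep, np.nan, True))
    df = pd.DataFrame(rows, columns=["run_id", "condition", "replicate",
                                     "temperature", "is_reference"])
    if precursor_counts is None:
        df["precursor_count"] = 100000
    else:
        df["precursor_count"] = [precursor_counts[r] for r in df["run_id"]]
    return df
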