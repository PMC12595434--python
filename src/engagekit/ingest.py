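"""Parsing of run manifests and search-engine-style protein reports,
plus the pre-normalization filters (peptide-count floor, contaminant removal).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MeltDataset, ProteinQuantTable

_MANIFEST_HEADER = ["run_id", "condition", "replicate", "temperature_or_REF",
                    "precursor_count"]


class ParseError(ValueError):
    """Malformed input file; message names the offending line or column."""


def read_run_manifest(path) -> pd.DataFrame:
    """Read a run manifest TSV into a validated manifest frame.

    The ``temperature_or_REF`` column must hold either a numeric temperature
    (deg C) or the token ``REF`` marking a non-denatured reference run.

    Returns a frame with columns
    run_id, condition, replicate, temperature, is_reference, precursor_count.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_HEADER if c not in raw.columns]
    if missing:
        raise ParseError(f"{path.name}: missing manifest columns {missing}")

    temps, refs = [], []
    for lineno, token in enumerate(raw["temperature_or_REF"], start=2):
        token = str(token).strip()
        if token.upper() in {"REF", "REFERENCE"}:
            temps.append(np.nan)
            refs.append(True)
            continue
        try:
            temps.append(float(token))
        except ValueError:
            raise ParseError(
                f"{path.name}, line {lineno}: unrecognized temperature token "
                f"{token!r} (expected a number or 'REF')") from None
        refs.append(False)

    counts = pd.to_numeric(raw["precursor_count"], errors="coerce")
    if counts.isna().any() or (counts < 0).any():
        bad = int(np.where(counts.isna() | (counts < 0))[0][0]) + 2
        raise ParseError(f"{path.name}, line {bad}: invalid precursor_count")

    return pd.DataFrame({
        "run_id": raw["run_id"].astype(str),
        "condition": raw["condition"].astype(str),
        "replicate": pd.to_numeric(raw["replicate"]).astype(int),
        "temperature": temps,
        "is_reference": refs,
        "precursor_count": counts.astype(int),
    })


def read_protein_report(path, manifest: pd.DataFrame) -> ProteinQuantTable:
    """Read a wide protein report TSV against a run manifest.

    Requires a ``protein_id`` index column, a ``peptide_count`` column, and
    one abundance column per manifest run.  Empty cells and ``NA`` are kept
    as missing (NaN), never coerced to zero.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="protein_id",
                     na_values=["", "NA", "NaN", "nan"])
    if "peptide_count" not in df.columns:
        raise ParseError(f"{path.name}: missing 'peptide_count' column")
    absent = [r for r in manifest["run_id"] if r not in df.columns]
    if absent:
        raise ParseError(f"{path.name}: missing run columns {absent}")
    abundance = df[list(manifest["run_id"])].astype(float)
    if (abundance.to_numpy() < 0).any():
        raise ParseError(f"{path.name}: negative abundance values present")
    peptide_counts = pd.to_numeric(df["peptide_count"]).astype(int)
    peptide_counts.name = "peptide_count"
    return ProteinQuantTable(abundance, peptide_counts)


def read_melt_dataset(runs_path, proteins_path) -> MeltDataset:
    """Convenience: manifest + report -> MeltDataset."""
    manifest = read_run_manifest(runs_path)
    return MeltDataset(manifest, read_protein_report(proteins_path, manifest))


def read_contaminant_list(path) -> list[str]:
    """One protein id per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def filter_low_peptide_proteins(table: ProteinQuantTable,
                                min_peptides: int = 2) -> ProteinQuantTable:
    """Discard proteins identified by fewer than ``min_peptides`` peptides.

    Single-peptide identifications are too unreliable to anchor a melting
    curve; the default floor of 2 keeps only multi-peptide proteins.
    Row order is preserved.
    """
    keep = table.peptide_counts >= min_peptides
    return table.subset(table.protein_ids[keep])


def remove_contaminants(table: ProteinQuantTable,
                        contaminant_ids) -> ProteinQuantTable:
    """Drop known contaminant proteins by exact id match.

    The common ``CON__`` prefix convention is honored on both sides: an id
    matches whether or not either copy carries the prefix.  An empty list is
    the identity.
    """
    expanded = set()
    for cid in contaminant_ids:
        expanded.add(cid)
        if cid.startswith("CON__"):
            expanded.add(cid[len("CON__"):])
        else:
            expanded.add("CON__" + cid)
    keep = [pid for pid in table.protein_ids if pid not in expanded]
    return table.subset(keep)
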