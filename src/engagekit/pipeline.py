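"""End-to-end orchestration: ingest -> normalize -> Tm -> hit table."""

from __future__ import annotations

import pandas as pd

from . import ingest, melting, normalize
from .config import PipelineConfig
from .containers import MeltDataset, ProteinQuantTable


def run_tpp_pipeline(dataset: MeltDataset, contaminant_ids=(),
                     config: PipelineConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full melt-shift analysis of a melt dataset.

    Applies the peptide-count and contaminant filters, the four-stage
    normalization, per-curve Tm estimation and hit calling for the
    configured condition pair.

    Returns (tm_table, shift_table, audit).
    """
    config = config or PipelineConfig()
    quant = ingest.filter_low_peptide_proteins(dataset.quant,
                                               config.min_peptides)
    n_after_peptide = len(quant.protein_ids)
    quant = ingest.remove_contaminants(quant, contaminant_ids)
    audit = {
        "n_input_proteins": len(dataset.quant.protein_ids),
        "n_after_peptide_filter": n_after_peptide,
        "n_after_contaminant_filter": len(quant.protein_ids),
    }

    filtered_dataset = MeltDataset(dataset.manifest,
                                   ProteinQuantTable(quant.abundance,
                                                     quant.peptide_counts))
    table = normalize.normalize_dataset(
        filtered_dataset, invert_scaling=config.invert_scaling,
        max_missing=config.max_missing,
        first_k_required=config.first_k_required)
    audit.update(table.audit)
    audit["n_dropped_curves"] = len(table.audit["dropped_curves"])

    curves = melting.assemble_curves(table, dataset.manifest)
    tm_table = melting.estimate_tm_table(curves, config.tm_tolerance)
    shift_table = melting.call_hits(
        tm_table, config.condition_pair, shift_cutoff=config.shift_cutoff,
        alpha=config.alpha, cv_cutoff=config.cv_cutoff, test=config.test,
        bh_correction=config.bh_correction)
    audit["n_proteins_tested"] = len(shift_table)
    audit["n_hits"] = int(shift_table["hit"].sum()) if len(shift_table) else 0
    return tm_table, shift_table, audit
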