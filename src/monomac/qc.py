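"""Cell- and gene-level quality control.

Cells are kept when log10 library size >= 2.8 (smallest admissible integer
library 631), log10 detected features >= 2.6 (smallest admissible feature
count 399), mitochondrial UMI fraction <= 5%, and zero hemoglobin UMIs.
After cell QC, low-abundance genes with log2 of the mean CPM below 0.005 are
dropped.  Boundary conventions: exclusion is for values strictly below the
log10 cutoffs and strictly above the 5% mitochondrial fraction, so equality
passes in all three cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, CountMatrix

QC_REASONS = ("low_libsize", "few_features", "high_mito", "hemoglobin")


def compute_qc_metrics(counts: CountMatrix, gene_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell QC metrics: libsize, n_features, mito_fraction, hemoglobin_umis.

    A zero-count cell has mito_fraction 0 by convention.
    """
    mat = counts.values.tocsc()
    libsize = np.asarray(mat.sum(axis=0)).ravel()
    n_features = np.asarray((mat > 0).sum(axis=0)).ravel()
    mito = np.asarray(mat[gene_table["is_mito"].to_numpy(), :].sum(axis=0)).ravel()
    hb = np.asarray(mat[gene_table["is_hemoglobin"].to_numpy(), :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(libsize > 0, mito / np.maximum(libsize, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "libsize": libsize.astype(np.int64),
            "n_features": n_features.astype(np.int64),
            "mito_fraction": mito_frac,
            "hemoglobin_umis": hb.astype(np.int64),
        }
    )


def cell_qc_mask(metrics: pd.DataFrame, config: AnalysisConfig | None = None):
    """Boolean keep-mask plus an exclusion-reason table.

    Every excluded cell appears in the reason table with all of its failed
    checks (reasons are exhaustive, one row per cell x reason).
    """
    config = config or AnalysisConfig()
    with np.errstate(divide="ignore"):
        log_lib = np.log10(np.maximum(metrics["libsize"].to_numpy(), 1e-300))
        log_feat = np.log10(np.maximum(metrics["n_features"].to_numpy(), 1e-300))
    fails = {
        "low_libsize": (log_lib < config.min_log10_libsize) | (metrics["libsize"].to_numpy() == 0),
        "few_features": (log_feat < config.min_log10_features) | (metrics["n_features"].to_numpy() == 0),
        "high_mito": metrics["mito_fraction"].to_numpy() > config.max_mito_fraction,
        "hemoglobin": metrics["hemoglobin_umis"].to_numpy() > config.max_hemoglobin_umis,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    rows = []
    for reason, mask in fails.items():
        for cid in metrics["cell_id"].to_numpy()[mask]:
            rows.append({"cell_id": cid, "reason": reason})
    reasons = pd.DataFrame(rows, columns=["cell_id", "reason"])
    return keep, reasons


def gene_abundance_filter(
    counts: CountMatrix, config: AnalysisConfig | None = None
) -> np.ndarray:
    """Keep-mask over genes: log2 of the mean CPM across cells >= 0.005.

    CPM is count / cell library size * 1e6; cell QC must already have removed
    zero-library cells.
    """
    config = config or AnalysisConfig()
    mat = counts.values
    libsize = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    if np.any(libsize == 0):
        raise ValueError("cells with zero library size present; run cell QC first")
    cpm = mat.multiply(1e6 / libsize[None, :])
    mean_cpm = np.asarray(cpm.mean(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        avg_log2_cpm = np.log2(mean_cpm)
    return avg_log2_cpm >= config.min_avg_log2_cpm


def apply_qc(counts, cell_table, gene_table, config: AnalysisConfig | None = None):
    """Run cell QC then the gene abundance filter; returns filtered data and a report."""
    config = config or AnalysisConfig()
    metrics = compute_qc_metrics(counts, gene_table)
    keep_cells, reasons = cell_qc_mask(metrics, config)
    counts_c = counts.subset_cells(keep_cells)
    cell_table_c = cell_table.loc[keep_cells].reset_index(drop=True)
    keep_genes = gene_abundance_filter(counts_c, config)
    counts_f = counts_c.subset_genes(keep_genes)
    gene_table_f = gene_table.loc[keep_genes].reset_index(drop=True)
    report = metrics.assign(kept=keep_cells)
    return counts_f, cell_table_c, gene_table_f, report, reasons
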