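"""End-to-end orchestration: merge -> QC -> normalize -> variance/PCA ->
cluster/annotate -> SOM/density -> pseudo-bulk DE/GSEA, with a run manifest.

Every stage writes TSV outputs into the run directory and records its
surviving cell/gene counts and an output hash in the manifest, so a rerun
with the same inputs, config and seed is byte-identical.  A single global
seed is fanned out to per-stage child seeds via a counter scheme, so stages
can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_annotate as ca
from . import pseudobulk_de as pbde
from . import topology_density as td
from .io_model import (
    CKO,
    CONTROL,
    AnalysisConfig,
    read_10x_mtx,
    read_sample_sheet,
)
from .normalize import lognormalize, pool_size_factors
from .qc import apply_qc
from .variance_dimred import (
    decompose_variance,
    denoised_pca,
    fit_mean_variance_trend,
    select_hvg,
    tsne_embed,
)

log = logging.getLogger("monomac")

_STAGE_SEEDS = {"tsne": 1, "som": 2, "binarize": 3, "pca": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    return (int(seed) * 1000 + _STAGE_SEEDS.get(stage, 99)) % (2 ** 31)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, outdir: Path, name: str, manifest: dict) -> None:
    path = outdir / name
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][name] = _hash_df(df)


def load_samples(sample_sheet: pd.DataFrame):
    """Read and merge the per-sample 10x directories of a sample sheet."""
    from .io_model import make_cell_table, merge_samples

    samples = []
    gene_table = None
    for row in sample_sheet.itertuples():
        counts, gtab = read_10x_mtx(row.path)
        gene_table = gtab if gene_table is None else gene_table
        ct = make_cell_table(counts.cell_ids, row.sample_id, row.condition)
        samples.append((counts, ct))
    merged, cell_table = merge_samples(samples)
    return merged, cell_table, gene_table


def run_pipeline(
    sample_sheet: str | os.PathLike | pd.DataFrame,
    config: AnalysisConfig | None = None,
    outdir: str | os.PathLike = "monomac_run",
    gene_sets: dict | None = None,
    reference_binary: pd.DataFrame | None = None,
    with_tsne: bool = True,
) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    manifest: dict = {"seed": seed, "config": json.loads(json.dumps(vars(config), default=list)),
                      "stages": {}, "outputs": {}}

    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    counts, cell_table, gene_table = load_samples(sample_sheet)
    manifest["stages"]["merge"] = {
        "n_samples": int(sample_sheet.shape[0]),
        "n_genes": counts.n_genes, "n_cells": counts.n_cells,
    }
    log.info("merged %d samples: %d genes x %d cells",
             sample_sheet.shape[0], counts.n_genes, counts.n_cells)

    counts, cell_table, gene_table, qc_report, qc_reasons = apply_qc(
        counts, cell_table, gene_table, config
    )
    n_ctrl = int((cell_table["condition"] == CONTROL).sum())
    n_cko = int((cell_table["condition"] == CKO).sum())
    manifest["stages"]["qc"] = {
        "n_genes": counts.n_genes, "n_cells": counts.n_cells,
        "n_control": n_ctrl, "n_cko": n_cko,
    }
    log.info("after QC: %d genes x %d cells (%d control, %d cKO)",
             counts.n_genes, counts.n_cells, n_ctrl, n_cko)
    _write(qc_report, outdir, "qc_metrics.tsv", manifest)
    _write(qc_reasons, outdir, "qc_exclusions.tsv", manifest)

    one_condition = min(n_ctrl, n_cko) == 0

    factors = pool_size_factors(counts, config.pool_sizes)
    logcounts = lognormalize(counts, factors)
    _write(pd.DataFrame({"cell_id": counts.cell_ids, "size_factor": factors}),
           outdir, "size_factors.tsv", manifest)

    trend = fit_mean_variance_trend(logcounts, config.loess_span)
    decomp = decompose_variance(logcounts, trend)
    pca = denoised_pca(logcounts, decomp, seed=stage_seed(seed, "pca"))
    hvg = select_hvg(decomp, counts.gene_ids, config.n_hvg)
    manifest["stages"]["dimred"] = {"n_pcs": pca.d, "n_hvg": len(hvg)}
    _write(decomp.assign(gene=counts.gene_ids), outdir, "variance_decomposition.tsv", manifest)
    _write(pd.DataFrame(pca.scores, columns=[f"PC{i+1}" for i in range(pca.d)])
           .assign(cell_id=counts.cell_ids), outdir, "pc_scores.tsv", manifest)

    if with_tsne and counts.n_cells >= 3 * config.tsne_perplexity:
        coords = tsne_embed(pca.scores, config.tsne_perplexity, stage_seed(seed, "tsne"))
        _write(pd.DataFrame(coords, columns=["tsne1", "tsne2"])
               .assign(cell_id=counts.cell_ids), outdir, "tsne.tsv", manifest)

    linkage = ca.ward_cluster(logcounts)
    clusters = ca.dynamic_cut(linkage, logcounts, config.min_cluster_size)
    manifest["stages"]["cluster"] = {"n_clusters": clusters.n_clusters}
    log.info("dynamic tree cut: %d clusters", clusters.n_clusters)
    _write(pd.DataFrame({"cell_id": counts.cell_ids, "cluster": clusters.labels}),
           outdir, "clusters.tsv", manifest)

    markers = ca.find_markers(logcounts, clusters.labels, counts.gene_ids,
                              config.top_markers_per_pair)
    marker_rows = [
        {"cluster": k, "rank": i + 1, "gene": g}
        for k, genes in markers.top_sets.items() for i, g in enumerate(genes)
    ]
    _write(pd.DataFrame(marker_rows), outdir, "marker_top_sets.tsv", manifest)

    if reference_binary is not None and not one_condition:
        profiles = ca.pseudobulk_by_cluster(counts, clusters.labels, cell_table, CONTROL)
        symbols = gene_table.set_index("gene_id").loc[profiles.index, "symbol"]
        profiles.index = symbols.to_numpy()
        expressed, thr = ca.binarize_expression(profiles, stage_seed(seed, "binarize"))
        annotation = ca.fisher_annotation(expressed, reference_binary, config.fdr_threshold)
        ann_rows = [
            {"cluster": cl, **row}
            for cl, tab in annotation.items() for row in tab.to_dict("records")
        ]
        _write(pd.DataFrame(ann_rows), outdir, "annotation.tsv", manifest)
        manifest["stages"]["annotate"] = {"binarization_threshold": thr}

    som_input = pca.scores[:, : min(config.n_som_pcs, pca.d)]
    if counts.n_cells >= config.som_grid[0] * config.som_grid[1]:
        som = td.train_som(som_input, config.som_grid, stage_seed(seed, "som"))
        enrich = td.node_condition_enrichment(
            som.assignments, cell_table, config.som_grid[0] * config.som_grid[1]
        )
        _write(enrich, outdir, "som_node_enrichment.tsv", manifest)
        _write(pd.DataFrame(som.mst_edges, columns=["node_i", "node_j", "weight"]),
               outdir, "som_mst_edges.tsv", manifest)
        _write(pd.DataFrame({"cell_id": counts.cell_ids, "node": som.assignments}),
               outdir, "som_assignments.tsv", manifest)

    if not one_condition:
        is_cko = cell_table["condition"].to_numpy() == CKO
        pc12 = pca.scores[:, :2]
        lims = td.shared_grid_limits(pc12[is_cko], pc12[~is_cko])
        map_cko = td.kde2d(pc12[is_cko], limits=lims)
        map_ctrl = td.kde2d(pc12[~is_cko], limits=lims)
        diff = td.differential_density(map_cko, map_ctrl, config.density_prior)
        dd = pd.DataFrame(diff, index=map_cko.x, columns=map_cko.y)
        dd.index.name = "PC1"
        path = outdir / "differential_density_pc12.tsv"
        dd.to_csv(path, sep="\t")
        manifest["outputs"]["differential_density_pc12.tsv"] = hashlib.sha256(
            dd.to_csv().encode()
        ).hexdigest()[:16]
    else:
        log.info("single-condition sample sheet: density and DE stages skipped")
        manifest["stages"]["skipped"] = ["density", "de", "gsea"]

    if not one_condition:
        pb = pbde.aggregate(counts, clusters.labels, cell_table, config.min_cells_aggregate)
        manifest["stages"]["aggregate"] = {
            "n_aggregates": int(pb.counts.shape[1]),
            "analyzable_clusters": [int(c) for c in pb.analyzable_clusters(config.de_min_samples)],
        }
        _write(pb.meta, outdir, "pseudobulk_meta.tsv", manifest)
        if pb.counts.shape[1] >= 2:
            tmm = pbde.tmm_factors(pb.counts)
            de_frames, gsea_frames = [], []
            symbols = gene_table.set_index("gene_id")["symbol"]
            for cl in pb.analyzable_clusters(config.de_min_samples):
                cols = pb.columns_for(cl)
                cl_cells = counts.subset_cells(clusters.labels == cl)
                mask = pbde.filter_de_genes(
                    pb.counts[:, cols], cl_cells.values,
                    config.de_min_cpm, config.de_min_samples, config.de_min_cells_detected,
                )
                if mask.sum() < 10:
                    continue
                de = pbde.nbglm_de(pb, tmm, cl, mask, config.fdr_threshold)
                de.insert(0, "cluster", cl)
                de_frames.append(de)
                if gene_sets:
                    gsea = pbde.camera_test(
                        pbde.de_z_scores(de), gene_sets, config.camera_rho,
                        config.min_set_size, symbols,
                    )
                    gsea.insert(0, "cluster", cl)
                    gsea_frames.append(gsea)
            if de_frames:
                _write(pd.concat(de_frames, ignore_index=True), outdir, "de_results.tsv", manifest)
            if gsea_frames:
                _write(pd.concat(gsea_frames, ignore_index=True), outdir, "gsea_results.tsv", manifest)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
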