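"""Synthetic genotype-contrasted "monocyte waterfall" data with known truth.

The generator emulates the structure of the real experiment: eight Chromium
samples (four control, four conditional-knockout), five trajectory-ordered
cell populations spanning Ly6C-high monocytes through MHCII+ mature
macrophages, negative-binomially distributed UMI counts with cell-specific
size factors, mitochondrial and hemoglobin genes plus planted low-quality
cells to exercise QC, a planted apoptosis gene module upregulated in cKO
monocytes, and a composition shift (cKO enriched in the early-monocyte
population, depleted in the mature MHCII+ macrophage population).

Counts are drawn as NB(mean = s_c * mu[g, pop(c)], dispersion phi_g) with
variance mu + phi*mu^2; s_c is lognormal; phi_g follows a decreasing trend
in the gene mean (0.05-0.5, typical of UMI data).  Non-marker "gradient"
genes interpolate their log-means linearly along the trajectory so the
populations form a continuum rather than disjoint islands.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_model import (
    CKO,
    CONTROL,
    CountMatrix,
    make_cell_table,
    make_gene_table,
    merge_samples,
    write_10x_mtx,
    write_gmt,
)

#: published marker genes used as readable symbols for the planted modules
MONOCYTE_MARKERS = ["Ccr2", "Ly6c2", "Cd14"]
MACROPHAGE_MARKERS = ["Cx3cr1", "Adgre1", "Cd81", "Cd74", "Cd72", "EYFP", "Cd63"]
APOPTOSIS_GENES = [
    "Bcl2l11", "Casp3", "Casp8", "Osm", "Fos", "Tnf",
    "Fas", "Trp53", "Bax", "Bak1", "Jun", "Gadd45a",
]
MITO_GENES = [f"mt-Nd{i}" for i in range(1, 7)] + ["mt-Co1", "mt-Co2", "mt-Co3", "mt-Cytb", "mt-Atp6", "mt-Atp8", "mt-Nd4l"]
HEMOGLOBIN_GENES = ["Hba-a1", "Hba-a2", "Hbb-bs", "Hbb-bt"]

#: trajectory-ordered populations; early-monocyte is the cKO-enriched stage,
#: the MHCII-high macrophage the cKO-depleted stage
DEFAULT_POPULATIONS = [
    ("mono_ly6c_hi", 0.00),
    ("mono_early", 0.25),
    ("mono_intermediate", 0.50),
    ("mac_mhc2_lo", 0.75),
    ("mac_mhc2_hi", 1.00),
]
EARLY_MONOCYTE = "mono_early"
MATURE_MACROPHAGE = "mac_mhc2_hi"
MONOCYTE_POPULATIONS = ("mono_ly6c_hi", "mono_early", "mono_intermediate")
MACROPHAGE_POPULATIONS = ("mac_mhc2_lo", "mac_mhc2_hi")


@dataclass
class SimulationDesign:
    """Parameters of the synthetic experiment (all defaults invented)."""

    n_samples_per_condition: int = 4
    cells_per_sample: int = 400
    n_genes: int = 2000
    populations: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_POPULATIONS)
    )
    composition_control: tuple[float, ...] = (0.16, 0.14, 0.20, 0.24, 0.26)
    composition_cko: tuple[float, ...] = (0.24, 0.28, 0.20, 0.18, 0.10)
    #: per-population distinguishing modules: {name: (n_genes, log2 fold)}
    population_module_genes: int = 15
    population_module_log2fc: float = 3.0
    apoptosis_cko_fold: float = 2.0
    gradient_fraction: float = 0.3
    gradient_slope_sd: float = 1.0
    mean_libsize: float = 5000.0
    size_factor_sigma: float = 0.3
    qc_fail_fraction: float = 0.05
    hemoglobin_cell_fraction: float = 0.01
    dispersion_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.cells_per_sample <= 0 or self.n_samples_per_condition <= 0:
            raise ValueError("degenerate design: zero genes, cells or samples")
        if len(self.populations) < 2:
            raise ValueError("need at least two populations")
        for comp in (self.composition_control, self.composition_cko):
            comp = np.asarray(comp, dtype=float)
            if len(comp) != len(self.populations):
                raise ValueError("composition length != number of populations")
            if np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
                raise ValueError("composition must be nonnegative and sum to 1")
        if self.apoptosis_cko_fold <= 0:
            raise ValueError("fold-changes must be positive")


def _population_means(design: SimulationDesign, rng: np.random.Generator):
    """Build the genes x populations mean-expression matrix and gene symbols.

    Returns (mu, symbols, module_of_gene) where mu[g, p] is the expected UMI
    count for a unit-size-factor cell of population p.
    """
    n_special = (
        len(MONOCYTE_MARKERS) + len(MACROPHAGE_MARKERS) + len(APOPTOSIS_GENES)
        + len(MITO_GENES) + len(HEMOGLOBIN_GENES)
        + design.population_module_genes * len(design.populations)
    )
    if design.n_genes < n_special + 50:
        raise ValueError(f"n_genes must be at least {n_special + 50}")

    pop_names = [p for p, _ in design.populations]
    positions = np.array([t for _, t in design.populations])
    n_pop = len(pop_names)

    symbols: list[str] = []
    module: list[str] = []
    rows: list[np.ndarray] = []

    def base_level() -> float:
        # lognormal baseline expression on the raw-count scale
        return float(2.0 ** rng.normal(0.0, 1.2))

    def add_gene(symbol: str, mod: str, levels: np.ndarray) -> None:
        symbols.append(symbol)
        module.append(mod)
        rows.append(np.asarray(levels, dtype=float))

    is_mono = np.array([p in MONOCYTE_POPULATIONS for p in pop_names])
    is_mac = np.array([p in MACROPHAGE_POPULATIONS for p in pop_names])

    # marker genes are effectively off outside their lineage, giving the
    # bimodal on/off expression structure real cell types show
    for sym in MONOCYTE_MARKERS:
        hi = base_level() * 2 ** 3.0
        add_gene(sym, "monocyte_marker", np.where(is_mono, hi, hi / 100.0))
    for sym in MACROPHAGE_MARKERS:
        hi = base_level() * 2 ** 3.0
        add_gene(sym, "macrophage_marker", np.where(is_mac, hi, hi / 100.0))
    for sym in APOPTOSIS_GENES:
        # moderately expressed everywhere; the cKO fold is applied per cell
        add_gene(sym, "apoptosis", np.full(n_pop, base_level() * 2.0))
    for sym in MITO_GENES:
        add_gene(sym, "mito", np.full(n_pop, base_level() * 2.0))
    for sym in HEMOGLOBIN_GENES:
        add_gene(sym, "hemoglobin", np.zeros(n_pop))

    for p_idx, pname in enumerate(pop_names):
        for i in range(design.population_module_genes):
            on = base_level() * 2 ** design.population_module_log2fc
            levels = np.full(n_pop, on / 100.0)  # off outside the stage
            levels[p_idx] = on
            # neighbors on the trajectory get an intermediate level (continuum)
            for q in (p_idx - 1, p_idx + 1):
                if 0 <= q < n_pop:
                    levels[q] = on / 10.0
            add_gene(f"Mod_{pname}_{i}", f"module_{pname}", levels)

    n_rest = design.n_genes - len(symbols)
    n_gradient = int(round(design.gradient_fraction * n_rest))
    n_silent = int(round(0.25 * n_rest))
    for i in range(n_rest):
        lo = base_level()
        if i < n_gradient:
            slope = rng.normal(0.0, design.gradient_slope_sd)
            levels = lo * 2 ** (slope * positions)
            mod = "gradient"
        elif i < n_gradient + n_silent:
            levels = np.full(n_pop, lo / 100.0)  # not expressed in this tissue
            mod = "silent"
        else:
            levels = np.full(n_pop, lo)
            mod = "flat"
        add_gene(f"Gene_{i}", mod, levels)

    mu = np.vstack(rows)
    # rescale so a unit-size-factor cell has the designed expected library size
    mu *= design.mean_libsize / mu.sum(axis=0).mean()
    return mu, np.array(symbols, dtype=object), np.array(module, dtype=object)


def _gene_dispersions(mu: np.ndarray, rng: np.random.Generator,
                      lo: float, hi: float) -> np.ndarray:
    """Per-gene NB dispersion on a decreasing trend in the gene mean."""
    mean_g = mu.mean(axis=1)
    order = np.argsort(np.argsort(-mean_g))  # 0 for the most expressed gene
    frac = order / max(len(mean_g) - 1, 1)
    phi = lo + (hi - lo) * frac
    phi *= np.exp(rng.normal(0.0, 0.1, size=phi.shape))
    return np.clip(phi, lo * 0.5, hi * 2)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + phi*mean^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        shape = 1.0 / phi[pos]
        lam = rng.gamma(shape, mean[pos] * phi[pos])
        out[pos] = rng.poisson(lam)
    return out


def simulate_waterfall(design: SimulationDesign):
    """Draw the full synthetic experiment.

    Returns (counts, cell_table, gene_table, truth) where truth is a
    DataFrame with cell_id, truth_label (population), and planted QC flags.
    Deterministic for a fixed ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    mu, symbols, module = _population_means(design, rng)
    lo, hi = design.dispersion_range
    phi = _gene_dispersions(mu, rng, lo, hi)
    gene_ids = np.array([f"ENSMUSG{i:08d}" for i in range(len(symbols))], dtype=object)
    gene_table = make_gene_table(gene_ids, symbols)
    gene_table["module"] = module

    pop_names = [p for p, _ in design.populations]
    apop_rows = np.flatnonzero(module == "apoptosis")
    mito_rows = np.flatnonzero(module == "mito")
    hb_rows = np.flatnonzero(module == "hemoglobin")
    mono_pop_idx = {i for i, p in enumerate(pop_names) if p in MONOCYTE_POPULATIONS}

    per_sample = []
    truth_frames = []
    sample_defs = [
        (f"ctrl{k + 1}", CONTROL, np.asarray(design.composition_control, float))
        for k in range(design.n_samples_per_condition)
    ] + [
        (f"cko{k + 1}", CKO, np.asarray(design.composition_cko, float))
        for k in range(design.n_samples_per_condition)
    ]

    for sample_id, condition, comp in sample_defs:
        n = design.cells_per_sample
        pop_idx = rng.choice(len(pop_names), size=n, p=comp)
        s = np.exp(rng.normal(0.0, design.size_factor_sigma, size=n))

        mean = mu[:, pop_idx] * s[None, :]
        if condition == CKO and design.apoptosis_cko_fold != 1.0:
            in_mono = np.isin(pop_idx, list(mono_pop_idx))
            mean[np.ix_(apop_rows, np.flatnonzero(in_mono))] *= design.apoptosis_cko_fold

        qc_fail = rng.random(n) < design.qc_fail_fraction
        fail_mode = rng.random(n) < 0.5  # True: tiny library, False: high mito
        tiny = qc_fail & fail_mode
        mean[:, tiny] *= 300.0 / design.mean_libsize / s[None, tiny]
        high_mito = qc_fail & ~fail_mode
        if np.any(high_mito):
            cols = np.flatnonzero(high_mito)
            lib = mean[:, cols].sum(axis=0)
            mito_tot = mean[np.ix_(mito_rows, cols)].sum(axis=0)
            # boost mito genes so the expected mito fraction is ~15%
            target = 0.15 * lib
            boost = np.maximum(target / np.maximum(mito_tot, 1e-9), 1.0)
            mean[np.ix_(mito_rows, cols)] *= boost[None, :]

        counts = _nb_sample(rng, mean, np.broadcast_to(phi[:, None], mean.shape))

        hb_cell = rng.random(n) < design.hemoglobin_cell_fraction
        if np.any(hb_cell):
            cols = np.flatnonzero(hb_cell)
            rows = rng.choice(hb_rows, size=len(cols))
            counts[rows, cols] += rng.poisson(2.0, size=len(cols)) + 1

        cell_ids = np.array([f"{sample_id}_cell{j:04d}" for j in range(n)], dtype=object)
        labels = np.array([pop_names[i] for i in pop_idx], dtype=object)
        cm = CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids)
        ct = make_cell_table(cell_ids, sample_id, condition, truth_label=labels)
        per_sample.append((cm, ct))
        truth_frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids,
                    "truth_label": labels,
                    "planted_qc_fail": qc_fail,
                    "planted_hemoglobin": hb_cell,
                }
            )
        )

    counts, cell_table = merge_samples(per_sample)
    truth = pd.concat(truth_frames, ignore_index=True)
    truth["cell_id"] = cell_table["cell_id"].to_numpy()  # suffixed ids
    return counts, cell_table, gene_table, truth


# ---------------------------------------------------------------------------
# reference profiles for the annotation stage
# ---------------------------------------------------------------------------

REFERENCE_TYPES = ["monocyte", "macrophage", "DC", "lymphoid", "stromal"]


def simulate_reference(design: SimulationDesign):
    """Bulk-style reference profiles emulating a sorted-cell-type compendium.

    Monocyte and macrophage references reuse the simulated population mean
    profiles (so they share their expressed markers with the matching
    populations); DC / lymphoid / stromal get their own marker structure over
    the same gene universe.  Returns (mean_profiles, expressed, labels):
    genes x types DataFrames plus the type labels.
    """
    design.validate()
    rng = np.random.default_rng(design.seed + 10_000)
    mu, symbols, module = _population_means(design, rng)
    pop_names = [p for p, _ in design.populations]

    profiles = {}
    profiles["monocyte"] = mu[:, pop_names.index(EARLY_MONOCYTE)].copy()
    profiles["macrophage"] = mu[:, pop_names.index(MATURE_MACROPHAGE)].copy()

    myeloid = np.isin(
        module,
        ["monocyte_marker", "macrophage_marker"]
        + [f"module_{p}" for p in pop_names],
    )
    for ref in ("DC", "lymphoid", "stromal"):
        prof = mu.mean(axis=1).copy()
        prof[myeloid] /= 100.0  # not a waterfall type: planted modules off
        own = rng.choice(np.flatnonzero(module == "flat"), size=30, replace=False)
        prof[own] *= 8.0
        profiles[ref] = prof

    mean_df = pd.DataFrame(profiles, index=symbols)
    # binarize with the same mixture-threshold rule the annotation stage
    # applies to pseudo-bulk queries, so "expressed" is comparable
    from .cluster_annotate import binarize_expression

    expressed, _ = binarize_expression(mean_df, seed=design.seed)
    return mean_df, expressed, list(mean_df.columns)


def export_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_synthetic_dataset(design: SimulationDesign, outdir: str | os.PathLike):
    """Write the synthetic experiment as per-sample 10x triplet directories
    plus a sample sheet and truth TSV (the on-disk form of the demo data)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, cell_table, gene_table, truth = simulate_waterfall(design)
    rows = []
    for sample_id, sub in cell_table.groupby("sample_id", sort=False):
        mask = cell_table["sample_id"].to_numpy() == sample_id
        cm = counts.subset_cells(mask)
        # strip the merge suffix so re-merging reproduces the same ids
        stripped = np.array([c.rsplit("-", 1)[0] for c in cm.cell_ids], dtype=object)
        cm = CountMatrix(cm.values, cm.gene_ids, stripped)
        sdir = outdir / sample_id
        write_10x_mtx(cm, gene_table, sdir)
        rows.append({"sample_id": sample_id, "path": str(sdir),
                     "condition": sub["condition"].iloc[0]})
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    export_truth(truth, outdir / "truth.tsv")
    # gene sets for the enrichment stage: the planted apoptosis module plus
    # size-matched random control sets from the simulated universe
    rng = np.random.default_rng(design.seed + 77)
    flat = gene_table.loc[gene_table["module"] == "flat", "symbol"].to_numpy()
    sets = {"APOPTOSIS_SET": list(APOPTOSIS_GENES)}
    for k in range(1, 5):
        sets[f"RANDOM_SET_{k}"] = list(rng.choice(flat, size=40, replace=False))
    write_gmt(sets, outdir / "sets.gmt")
    return sheet
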