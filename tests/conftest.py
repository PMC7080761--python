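import numpy as np
import pytest

import monomac as mm


@pytest.fixture(scope="session")
def default_run():
    """One full analysis of the synthetic experiment at default design
    (seed 1), shared across tests that inspect different stages."""
    design = mm.SimulationDesign(seed=1)
    counts, cell_table, gene_table, truth = mm.simulate_waterfall(design)
    counts, cell_table, gene_table, qc_report, reasons = mm.apply_qc(
        counts, cell_table, gene_table
    )
    truth = truth[qc_report["kept"].to_numpy()].reset_index(drop=True)
    factors = mm.pool_size_factors(counts)
    logcounts = mm.lognormalize(counts, factors)
    linkage = mm.ward_cluster(logcounts)
    clusters = mm.dynamic_cut(linkage, logcounts)
    trend = mm.fit_mean_variance_trend(logcounts)
    decomp = mm.decompose_variance(logcounts, trend)
    pca = mm.denoised_pca(logcounts, decomp)
    return {
        "design": design,
        "counts": counts,
        "cell_table": cell_table,
        "gene_table": gene_table,
        "truth": truth,
        "factors": factors,
        "logcounts": logcounts,
        "clusters": clusters,
        "decomp": decomp,
        "pca": pca,
    }


@pytest.fixture()
def small_design():
    """A fast, reduced synthetic design for unit tests."""
    return mm.SimulationDesign(
        seed=0, cells_per_sample=100, n_genes=300, population_module_genes=8
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
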