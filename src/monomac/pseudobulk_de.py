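"""Cluster-stratified pseudo-bulk differential expression and gene-set tests.

UMI counts of cells from each sample in each cluster are summed when at
least 20 cells can be aggregated; clusters keeping at least 3 replicates
per condition are analyzed as bulk RNA-seq.  Genes are filtered (CPM > 1 in
>= 3 aggregates, detected in >= 20 cells), libraries are TMM-normalized,
and each gene is tested with a negative-binomial GLM (log link, condition
design, common dispersion per cluster estimated by profile likelihood,
likelihood-ratio test against the intercept-only model).  Genes at BH FDR
< 5% are called differentially expressed.  Competitive gene-set enrichment
uses a camera-style two-sample test on per-gene signed z-statistics with a
variance inflation factor 1 + (m-1)*rho for intra-set correlation rho
(default 0.01), on sets with more than ten tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.special import gammaln

from .io_model import CKO, CONTROL, CountMatrix

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------------

@dataclass
class PseudoBulkMatrix:
    counts: np.ndarray      # genes x aggregates, integer sums
    meta: pd.DataFrame      # sample_id, cluster, condition, n_cells
    gene_ids: np.ndarray

    def columns_for(self, cluster) -> np.ndarray:
        return np.flatnonzero(self.meta["cluster"].to_numpy() == cluster)

    def analyzable_clusters(self, min_replicates: int = 3) -> list:
        """Clusters with at least ``min_replicates`` aggregates per condition."""
        out = []
        for cl, sub in self.meta.groupby("cluster", sort=True):
            counts = sub["condition"].value_counts()
            if counts.get(CONTROL, 0) >= min_replicates and counts.get(CKO, 0) >= min_replicates:
                out.append(cl)
        return out


def aggregate(
    counts: CountMatrix,
    labels: np.ndarray,
    cell_table: pd.DataFrame,
    min_cells: int = 20,
) -> PseudoBulkMatrix:
    """Sum UMI counts per (sample, cluster), keeping aggregates of >= min_cells."""
    labels = np.asarray(labels)
    samples = cell_table["sample_id"].to_numpy()
    conditions = cell_table["condition"].to_numpy()
    cols, meta = [], []
    for sample in pd.unique(samples):
        cond = conditions[samples == sample][0]
        for cl in np.unique(labels):
            idx = np.flatnonzero((samples == sample) & (labels == cl))
            if len(idx) < min_cells:
                continue
            cols.append(np.asarray(counts.values[:, idx].sum(axis=1)).ravel())
            meta.append({"sample_id": sample, "cluster": cl,
                         "condition": cond, "n_cells": len(idx)})
    if not cols:
        warnings.warn("no (sample, cluster) aggregate reached the cell minimum")
        return PseudoBulkMatrix(
            np.zeros((counts.n_genes, 0), dtype=np.int64),
            pd.DataFrame(columns=["sample_id", "cluster", "condition", "n_cells"]),
            counts.gene_ids,
        )
    return PseudoBulkMatrix(
        np.column_stack(cols).astype(np.int64), pd.DataFrame(meta), counts.gene_ids
    )


def filter_de_genes(
    pb_counts: np.ndarray,
    cell_counts,
    min_cpm: float = 1.0,
    min_samples: int = 3,
    min_cells: int = 20,
) -> np.ndarray:
    """Gene keep-mask: CPM > min_cpm in >= min_samples aggregates AND detected
    (count > 0) in >= min_cells of the supplied single cells."""
    pb_counts = np.asarray(pb_counts, dtype=float)
    lib = pb_counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("aggregate with zero library size")
    cpm = pb_counts / lib[None, :] * 1e6
    enough_samples = (cpm > min_cpm).sum(axis=1) >= min_samples
    if isinstance(cell_counts, CountMatrix):
        cell_counts = cell_counts.values
    if sp.issparse(cell_counts):
        det = np.asarray((cell_counts > 0).sum(axis=1)).ravel()
    else:
        det = (np.asarray(cell_counts) > 0).sum(axis=1)
    return enough_samples & (det >= min_cells)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    pb_counts: np.ndarray,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference column is the library whose upper-quartile CPM is closest
    to the mean upper quartile.  M (log2 ratio) and A (average log2
    abundance) are computed on genes nonzero in both libraries, the extreme
    30% of M and 5% of A are trimmed on both sides, and the factor is two to
    the inverse-asymptotic-variance weighted mean of the remaining M values.
    """
    y = np.asarray(pb_counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need at least two columns")
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("column with all zero counts")
    f75 = np.array([np.quantile(y[:, j] / lib[j] * 1e6, 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    r, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        x, nx = y[:, j], lib[j]
        both = (x > 0) & (r > 0)
        if not np.any(both):
            continue
        xp, rp = x[both] / nx, r[both] / nr
        M = np.log2(xp / rp)
        A = 0.5 * np.log2(xp * rp)
        w = (nx - x[both]) / (nx * x[both]) + (nr - r[both]) / (nr * r[both])
        n = len(M)
        loL = np.floor(n * logratio_trim) + 1
        hiL = n + 1 - loL
        loS = np.floor(n * abundance_trim) + 1
        hiS = n + 1 - loS
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[j] = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = np.where(np.isfinite(factors) & (factors > 0), factors, 1.0)
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# NB GLM with likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Row-wise NB log-likelihood (variance mu + phi mu^2)."""
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    # log1p keeps the Poisson limit (phi -> 0) numerically exact
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        - (r + y) * np.log1p(mu / r) + y * np.log(mu / r)
    ).sum(axis=1)


def _irls_nb(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float,
    max_iter: int = 60, tol: float = 1e-10,
):
    """Vectorized per-gene IRLS for an NB GLM with log link and fixed dispersion.

    y: genes x n counts; X: n x p design; offset: n log effective library
    sizes.  Returns (beta genes x p, mu genes x n, converged mask).
    """
    y = np.asarray(y, dtype=float)
    g, n = y.shape
    p = X.shape[1]
    beta = np.zeros((g, p))
    beta[:, 0] = np.log(np.maximum((y / np.exp(offset)[None, :]).mean(axis=1), 1e-8))
    converged = np.zeros(g, dtype=bool)
    mu_prev = np.exp(np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP))
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + phi * mu)                    # working weights
        z = (eta - offset[None, :]) + (y - mu) / mu  # working response (offset removed)
        # normal equations per gene: (X' W X) beta = X' W z
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
        XtWz = np.einsum("ni,gn->gi", X, W * z)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        # clamp coefficients so separated genes (all-zero group) settle on
        # the boundary instead of diverging
        new = np.clip(new, -_ETA_CLIP, _ETA_CLIP)
        beta = new
        mu_new = np.exp(np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP))
        # convergence on the fitted means: for separated genes the boundary
        # coefficients keep creeping while the fit itself is stable
        step = (np.abs(mu_new - mu_prev) / (1.0 + mu_prev)).max(axis=1)
        mu_prev = mu_new
        converged |= step < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
    return beta, np.exp(eta), converged


def _profile_neg_loglik(log_phi, y, X, offset):
    """Negative aggregate Cox-Reid adjusted profile likelihood at one phi.

    The adjustment (-0.5 log det X'WX per gene) removes the downward bias of
    the plain profile likelihood caused by estimating the per-gene means,
    which would otherwise inflate the type-I error of the LRT.
    """
    phi = float(np.exp(log_phi))
    _, mu, _ = _irls_nb(y, X, offset, phi)
    ll = _nb_loglik(y, mu, phi)
    W = mu / (1.0 + phi * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
    _, logdet = np.linalg.slogdet(XtWX)
    return -float((ll - 0.5 * logdet).sum())


def estimate_common_dispersion(y, X, offset) -> float:
    """Common NB dispersion maximizing the aggregate (Cox-Reid adjusted)
    profile likelihood by a 1-D bounded search."""
    res = optimize.minimize_scalar(
        _profile_neg_loglik,
        bounds=(np.log(1e-6), np.log(5.0)),
        args=(y, X, offset),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-tolerant)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def nbglm_de(
    pb: PseudoBulkMatrix,
    factors: np.ndarray,
    cluster,
    gene_mask: np.ndarray | None = None,
    fdr_threshold: float = 0.05,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """NB-GLM likelihood-ratio differential expression for one cluster.

    The design is intercept + condition (cKO vs control) with offsets
    log(library size x TMM factor).  Returns a per-gene table with log2
    fold-change, LRT statistic, p, BH q and the DE flag at the given FDR.
    """
    cols = pb.columns_for(cluster)
    if len(cols) == 0:
        raise ValueError(f"no aggregates for cluster {cluster!r}")
    meta = pb.meta.iloc[cols]
    for cond in (CONTROL, CKO):
        if (meta["condition"] == cond).sum() < 3:
            raise ValueError(f"cluster {cluster!r}: fewer than 3 {cond} replicates")
    y = pb.counts[:, cols].astype(float)
    gene_ids = pb.gene_ids
    if gene_mask is not None:
        y = y[gene_mask]
        gene_ids = gene_ids[gene_mask]
    lib = pb.counts[:, cols].sum(axis=0).astype(float)
    offset = np.log(lib * np.asarray(factors, dtype=float)[cols])
    x_cond = (meta["condition"].to_numpy() == CKO).astype(float)
    X_full = np.column_stack([np.ones_like(x_cond), x_cond])
    X_null = X_full[:, :1]

    phi = estimate_common_dispersion(y, X_full, offset) if dispersion is None else dispersion
    beta_f, mu_f, conv_f = _irls_nb(y, X_full, offset, phi)
    _, mu_n, conv_n = _irls_nb(y, X_null, offset, phi)
    ll_f = _nb_loglik(y, mu_f, phi)
    ll_n = _nb_loglik(y, mu_n, phi)
    lrt = np.maximum(2.0 * (ll_f - ll_n), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    bad = ~(conv_f & conv_n)
    p[bad] = np.nan
    tab = pd.DataFrame(
        {
            "gene": gene_ids,
            "log2fc": beta_f[:, 1] / np.log(2.0),
            "lrt": lrt,
            "p": p,
            "q": bh_fdr(p),
            "converged": conv_f & conv_n,
        }
    )
    tab["de"] = tab["q"] < fdr_threshold
    tab.attrs["dispersion"] = phi
    tab.attrs["cluster"] = cluster
    return tab


# ---------------------------------------------------------------------------
# camera-style competitive gene-set test
# ---------------------------------------------------------------------------

def camera_test(
    gene_stats: pd.DataFrame,
    sets: dict,
    rho: float = 0.01,
    min_set_size: int = 11,
    symbols: pd.Series | None = None,
) -> pd.DataFrame:
    """Competitive gene-set test with a variance inflation factor.

    ``gene_stats`` must have columns gene and z (signed per-gene statistic,
    e.g. sign(log2fc) * sqrt(LRT)).  For a set of m of the G tested genes,
    delta = mean z inside - mean z outside is compared with sd =
    sqrt((1/m + 1/(G-m)) * var(z) * VIF), VIF = 1 + (m-1)*rho; two-sided
    normal p, BH across sets.  Sets with <= min_set_size - 1 tested genes
    are skipped.
    """
    z = gene_stats["z"].to_numpy(dtype=float)
    names = gene_stats["gene"].astype(str)
    keys = symbols.loc[gene_stats["gene"]].astype(str).to_numpy() if symbols is not None else names.to_numpy()
    G = len(z)
    sigma2 = float(np.var(z, ddof=1))
    rows = []
    for set_name, members in sets.items():
        mask = np.isin(keys, np.asarray(members, dtype=str))
        m = int(mask.sum())
        if m < min_set_size or G - m < 1:
            continue
        delta = z[mask].mean() - z[~mask].mean()
        vif = 1.0 + (m - 1) * rho
        sd = np.sqrt((1.0 / m + 1.0 / (G - m)) * sigma2 * vif)
        p = 2.0 * stats.norm.sf(abs(delta) / sd) if sd > 0 else 1.0
        rows.append(
            {"set": set_name, "n_genes": m,
             "direction": "Up" if delta > 0 else "Down", "delta": delta, "p": p}
        )
    tab = pd.DataFrame(rows, columns=["set", "n_genes", "direction", "delta", "p"])
    tab["q"] = bh_fdr(tab["p"].to_numpy()) if len(tab) else np.nan
    return tab


def de_z_scores(de_table: pd.DataFrame) -> pd.DataFrame:
    """Signed z-statistics for camera: sign(log2fc) * sqrt(LRT)."""
    z = np.sign(de_table["log2fc"].to_numpy()) * np.sqrt(de_table["lrt"].to_numpy())
    return pd.DataFrame({"gene": de_table["gene"], "z": z})
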