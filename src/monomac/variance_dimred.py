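"""Mean-variance trend, technical/biological variance decomposition,
denoised PCA, highly-variable-gene selection and the t-SNE contract.

A loess (local linear, tricube weights) trend with span 0.05 is fitted to
the per-gene variance of log-expression as a function of the mean; the
fitted value is interpreted as the technical component and the residual as
biological.  PCA retains the smallest number of components whose discarded
variance fits under the summed technical variance (with a floor of two
components), which denoises the embedding used by clustering-adjacent
stages.  t-SNE itself is delegated to scikit-learn's Barnes-Hut
implementation; only its parameters (perplexity 30, fixed seed) are part of
the contract here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from statsmodels.nonparametric.smoothers_lowess import lowess


def fit_mean_variance_trend(logcounts: np.ndarray, span: float = 0.05):
    """Fit the variance-vs-mean loess trend; returns a nonnegative callable.

    Evaluation outside the fitted mean range clamps to the nearest fitted
    value.  A small floor on the effective span keeps the local fits
    well-posed on tiny gene sets.
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    logcounts = np.asarray(logcounts, dtype=float)
    if logcounts.shape[0] < 10:
        raise ValueError("need at least 10 genes to fit a trend")
    means = logcounts.mean(axis=1)
    variances = logcounts.var(axis=1, ddof=1)
    n = len(means)
    frac = max(span, min(1.0, 5.0 / n))
    fitted = lowess(variances, means, frac=frac, it=3, return_sorted=True)
    xs, ys = fitted[:, 0], np.maximum(fitted[:, 1], 0.0)
    # collapse duplicate x for interpolation
    xs_u, idx = np.unique(xs, return_index=True)
    ys_u = ys[idx]

    def trend(x):
        return np.interp(np.asarray(x, dtype=float), xs_u, ys_u)

    trend.means = means
    trend.variances = variances
    return trend


def decompose_variance(logcounts: np.ndarray, trend) -> pd.DataFrame:
    """Per-gene decomposition: total variance = technical (trend) + biological."""
    logcounts = np.asarray(logcounts, dtype=float)
    means = logcounts.mean(axis=1)
    total = logcounts.var(axis=1, ddof=1)
    tech = np.maximum(trend(means), 0.0)
    return pd.DataFrame(
        {"mean": means, "total": total, "technical": tech, "biological": total - tech}
    )


@dataclass
class PCAResult:
    scores: np.ndarray            # cells x d
    component_variances: np.ndarray
    d: int
    components: np.ndarray        # d x genes loadings


def denoised_pca(
    logcounts: np.ndarray,
    decomposition: pd.DataFrame,
    n_max: int = 50,
    seed: int = 0,
) -> PCAResult:
    """PCA keeping the fewest components whose discarded variance is at most
    the summed technical variance (floor of 2 components)."""
    logcounts = np.asarray(logcounts, dtype=float)
    n_genes, n_cells = logcounts.shape
    if n_cells < 3:
        raise ValueError("need at least 3 cells for PCA")
    k = min(n_max, n_cells - 1, n_genes)
    pca = PCA(n_components=k, svd_solver="auto", random_state=seed)
    scores = pca.fit_transform(logcounts.T)  # cells x k
    comp_var = pca.explained_variance_
    total_var = float(decomposition["total"].sum())
    tech_sum = float(decomposition["technical"].sum())
    discarded = total_var - np.cumsum(comp_var)
    ok = np.flatnonzero(discarded <= tech_sum)
    d = int(ok[0]) + 1 if len(ok) else k
    d = max(d, 2)
    d = min(d, k)
    return PCAResult(scores[:, :d], comp_var[:d], d, pca.components_[:d])


def select_hvg(decomposition: pd.DataFrame, gene_ids, n: int = 500) -> np.ndarray:
    """Top-n genes by biological variance; ties broken by gene_id order."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    order = sorted(
        range(len(gene_ids)),
        key=lambda i: (-decomposition["biological"].iloc[i], str(gene_ids[i])),
    )
    return gene_ids[order[: min(n, len(gene_ids))]]


def tsne_embed(pca_scores: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2D Barnes-Hut t-SNE of the PC scores; deterministic for a fixed seed."""
    if perplexity <= 0:
        raise ValueError("perplexity must be positive")
    pca_scores = np.asarray(pca_scores, dtype=float)
    n = pca_scores.shape[0]
    if n < 3 * perplexity:
        raise ValueError(f"need at least {int(3 * perplexity)} cells for perplexity {perplexity}")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        method="barnes_hut",
    )
    return tsne.fit_transform(pca_scores)
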