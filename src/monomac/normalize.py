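"""Pool-based size-factor estimation (deconvolution) and log-normalization.

Cell-specific size factors are estimated from pools of cells to avoid the
dominance of zeros in sparse UMI data: cells are ordered on a ring by
library size, pooled expression profiles are compared with an average
pseudo-cell by a gene-wise median ratio, and the resulting linear system
(pool sums of factors = pooled estimates) is solved in least squares.  When
a pre-clustering is supplied, factors are estimated within clusters and made
comparable across clusters via median ratios of cluster pseudo-cells.
Normalized expression is log2(count / factor + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr

from .io_model import CountMatrix

DEFAULT_POOL_SIZES = (21, 41, 61, 81, 101)
# weight of the rank-stabilizing identity equations in the pool system
_RIDGE_WEIGHT = 0.01


def _deconvolve_cluster(mat: np.ndarray, pool_sizes) -> np.ndarray:
    """Size factors for one cluster's genes x cells dense count matrix."""
    n = mat.shape[1]
    libsize = mat.sum(axis=0)
    if np.any(libsize == 0):
        raise ValueError("zero-library cells present; run QC first")
    t = libsize / libsize.mean()
    V = mat / t[None, :]  # libsize-scaled profiles
    A = V.mean(axis=1)
    use = A > 0

    order = np.argsort(libsize, kind="stable")
    # ring ordering: interleave low/high so pools mix library sizes
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2:][::-1]

    sizes = sorted({min(int(s), n) for s in pool_sizes})
    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    # sliding-window pool sums over the doubled ring via cumulative sums
    Vr = V[np.ix_(np.flatnonzero(use), ring)]
    Csum = np.concatenate([np.zeros((Vr.shape[0], 1)), np.cumsum(
        np.concatenate([Vr, Vr], axis=1), axis=1)], axis=1)
    Au = A[use][:, None]
    for s in sizes:
        pooled = Csum[:, s:s + n] - Csum[:, :n]      # genes x n, pool starting at each ring pos
        r_all = np.median(pooled / Au, axis=0)
        starts = np.arange(n)
        member_idx = (starts[:, None] + np.arange(s)[None, :]) % n
        rows.extend(np.repeat(np.arange(eq, eq + n), s).tolist())
        cols.extend(ring[member_idx].ravel().tolist())
        vals.extend([1.0] * (n * s))
        rhs.extend(r_all.tolist())
        eq += n
    # low-weight identity rows guarantee full rank without biasing the scale
    for c in range(n):
        rows.append(eq)
        cols.append(c)
        vals.append(_RIDGE_WEIGHT)
        rhs.append(_RIDGE_WEIGHT)
        eq += 1
    design = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    b = np.asarray(rhs)
    # solve the normal equations directly (the ridge rows make A'A full rank)
    ata = np.asarray((design.T @ design).todense())
    atb = design.T @ b
    x = np.linalg.solve(ata, atb)
    if np.any(x <= 0):
        raise ValueError(
            "deconvolution produced non-positive size factors; "
            "use larger pool sizes or pre-cluster the cells"
        )
    return x * t


def pool_size_factors(
    counts: CountMatrix | np.ndarray,
    pool_sizes=DEFAULT_POOL_SIZES,
    clusters: np.ndarray | None = None,
) -> np.ndarray:
    """Deconvolution size factors, scaled to unit mean.

    ``clusters`` optionally pre-stratifies cells; factors are then rescaled
    across clusters by the median ratio of cluster pseudo-cell profiles.
    """
    mat = counts.dense().astype(float) if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    n = mat.shape[1]
    factors = np.empty(n)
    if clusters is None:
        factors[:] = _deconvolve_cluster(mat, pool_sizes)
    else:
        clusters = np.asarray(clusters)
        uniq = pd.unique(clusters)
        pseudo = {}
        for cl in uniq:
            idx = np.flatnonzero(clusters == cl)
            if len(idx) < 2:
                raise ValueError(f"cluster {cl!r} has fewer than 2 cells")
            f = _deconvolve_cluster(mat[:, idx], pool_sizes)
            f = f / f.mean()
            factors[idx] = f
            prof = (mat[:, idx] / f[None, :]).mean(axis=1)
            pseudo[cl] = prof / prof.sum()
        ref = uniq[0]
        for cl in uniq:
            both = (pseudo[cl] > 0) & (pseudo[ref] > 0)
            scale = np.median(pseudo[ref][both] / pseudo[cl][both])
            factors[clusters == cl] /= scale
    return factors / factors.mean()


def lognormalize(counts: CountMatrix | np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """log2(count / size factor + 1), dense genes x cells."""
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    mat = counts.dense().astype(float) if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    return np.log2(mat / size_factors[None, :] + 1.0)


def library_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Library-size factors scaled to unit mean (baseline comparator)."""
    mat = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts)
    lib = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    return lib / lib.mean()
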