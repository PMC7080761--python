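"""SOM / minimal-spanning-tree topology with per-node condition enrichment,
and differential 2D kernel-density maps over principal-component pairs.

A batch self-organizing map (9x9 rectangular grid, by default trained on the
first 30 denoised principal components) summarizes the differentiation
topology; the minimal spanning tree over its codebook orders the nodes, and
each node's cKO-vs-control composition is expressed as a condition-total
normalized cKO share.  Cell abundance per condition is mapped with a
product-Gaussian KDE on a shared 100x100 grid, and the differential map is
the log2 ratio of cKO over control density after adding a prior count of
1e-3 to both estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree

from .io_model import CKO, CONTROL


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SOMModel:
    codebook: np.ndarray       # nodes x dims
    grid: tuple[int, int]
    grid_coords: np.ndarray    # nodes x 2 integer grid positions
    assignments: np.ndarray    # per-cell node index
    mst_edges: np.ndarray      # (nodes-1) x 3: i, j, weight


def _assign(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def train_som(
    X: np.ndarray,
    grid: tuple[int, int] = (9, 9),
    seed: int = 0,
    epochs: int = 10,
) -> SOMModel:
    """Batch SOM with a Gaussian neighborhood shrinking linearly from the
    grid radius to 1 over the epochs, followed by a best-matching-unit-only
    refinement pass; codebook initialized from seeded random data points.
    Deterministic for a fixed seed."""
    X = np.asarray(X, dtype=float)
    gx, gy = grid
    n_nodes = gx * gy
    if X.shape[0] < n_nodes:
        raise ValueError(
            f"{X.shape[0]} cells < {n_nodes} SOM nodes; use a smaller grid"
        )
    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(X.shape[0], size=n_nodes, replace=False)].copy()
    coords = np.array([(i, j) for i in range(gx) for j in range(gy)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    radius0 = max(gx, gy) / 2.0
    for e in range(epochs):
        sigma = radius0 + (1.0 - radius0) * (e / max(epochs - 1, 1))
        bmu = _assign(X, codebook)
        node_sum = np.zeros_like(codebook)
        np.add.at(node_sum, bmu, X)
        node_cnt = np.bincount(bmu, minlength=n_nodes).astype(float)
        H = np.exp(-grid_d2 / (2.0 * sigma ** 2))
        num = H @ node_sum
        den = (H @ node_cnt)[:, None]
        upd = den[:, 0] > 0
        codebook[upd] = num[upd] / den[upd]
    # convergence pass: each node becomes the mean of its own cells
    bmu = _assign(X, codebook)
    for k in range(n_nodes):
        mask = bmu == k
        if np.any(mask):
            codebook[k] = X[mask].mean(axis=0)
    assignments = _assign(X, codebook)
    edges = som_mst(codebook)
    return SOMModel(codebook, grid, coords.astype(int), assignments, edges)


def som_mst(codebook: np.ndarray) -> np.ndarray:
    """Minimal spanning tree over Euclidean distances between codebook
    vectors; returns an array of (i, j, weight) rows with i < j."""
    cb = np.asarray(codebook, dtype=float)
    n = cb.shape[0]
    d = np.sqrt(((cb[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2))
    # strictly upper-triangular graph; offset keeps zero-weight edges alive
    iu = np.triu_indices(n, k=1)
    graph = sp.csr_matrix((d[iu] + 1.0, iu), shape=(n, n))
    tree = minimum_spanning_tree(graph).tocoo()
    edges = sorted(
        (min(i, j), max(i, j), w - 1.0) for i, j, w in zip(tree.row, tree.col, tree.data)
    )
    return np.array(edges, dtype=float)


def node_condition_enrichment(
    assignments: np.ndarray, cell_table: pd.DataFrame, n_nodes: int | None = None
) -> pd.DataFrame:
    """Per-node condition composition with condition-total normalization.

    The normalized cKO share of a node is (n_cko/N_cko) / (n_cko/N_cko +
    n_ctrl/N_ctrl), so unequal total cell numbers between conditions do not
    bias the share; empty nodes get NaN.
    """
    assignments = np.asarray(assignments)
    cond = cell_table["condition"].to_numpy()
    if n_nodes is None:
        n_nodes = int(assignments.max()) + 1
    n_cko_tot = max(int((cond == CKO).sum()), 1)
    n_ctrl_tot = max(int((cond == CONTROL).sum()), 1)
    rows = []
    for k in range(n_nodes):
        mask = assignments == k
        n_cko = int((mask & (cond == CKO)).sum())
        n_ctrl = int((mask & (cond == CONTROL)).sum())
        fr_cko, fr_ctrl = n_cko / n_cko_tot, n_ctrl / n_ctrl_tot
        share = fr_cko / (fr_cko + fr_ctrl) if (fr_cko + fr_ctrl) > 0 else np.nan
        rows.append({"node": k, "n_control": n_ctrl, "n_cko": n_cko, "cko_share": share})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2D kernel density and differential density
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    x: np.ndarray          # grid axis 1
    y: np.ndarray          # grid axis 2
    density: np.ndarray    # len(x) x len(y), trapezoid-integrates to 1


def _nrd_bandwidth(v: np.ndarray) -> float:
    """Normal-reference bandwidth 1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("zero spread on an axis; cannot form a bandwidth")
    return 1.06 * spread * len(v) ** (-1.0 / 5.0)


def kde2d(
    points: np.ndarray,
    grid: tuple[int, int] = (100, 100),
    bandwidth: str | tuple[float, float] = "normal-reference",
    limits: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> DensityMap:
    """Product-Gaussian 2D KDE on a regular grid spanning the data range +-5%.

    The grid density is renormalized so its trapezoid integral is exactly 1
    (Gaussian tails falling off-grid are folded back proportionally).
    ``limits`` overrides the grid range, e.g. to share a grid between two
    conditions.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if bandwidth == "normal-reference":
        hx, hy = _nrd_bandwidth(pts[:, 0]), _nrd_bandwidth(pts[:, 1])
    else:
        hx, hy = bandwidth
    axes = []
    for dim, npts in zip(range(2), grid):
        if limits is not None:
            lo, hi = limits[dim]
        else:
            lo, hi = pts[:, dim].min(), pts[:, dim].max()
            margin = 0.05 * (hi - lo)
            if margin == 0:
                raise ValueError("zero spread on an axis")
            lo, hi = lo - margin, hi + margin
        axes.append(np.linspace(lo, hi, npts))
    gx, gy = axes
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    dens = (kx @ ky.T) / pts.shape[0]
    integral = np.trapezoid(np.trapezoid(dens, gy, axis=1), gx)
    if integral <= 0:
        raise ValueError("degenerate density")
    return DensityMap(gx, gy, dens / integral)


def shared_grid_limits(points_a: np.ndarray, points_b: np.ndarray):
    """Union data range of two point sets, widened by 5% per axis."""
    allpts = np.vstack([points_a, points_b])
    lims = []
    for dim in range(2):
        lo, hi = allpts[:, dim].min(), allpts[:, dim].max()
        margin = 0.05 * (hi - lo)
        lims.append((lo - margin, hi + margin))
    return tuple(lims)


def differential_density(
    map_cko: DensityMap, map_ctrl: DensityMap, prior: float = 1e-3
) -> np.ndarray:
    """log2((cKO density + prior) / (control density + prior)) on a shared grid."""
    if map_cko.density.shape != map_ctrl.density.shape or not (
        np.array_equal(map_cko.x, map_ctrl.x) and np.array_equal(map_cko.y, map_ctrl.y)
    ):
        raise ValueError("density maps are on different grids")
    # difference of logs keeps condition-swap antisymmetry bit-exact
    return np.log2(map_cko.density + prior) - np.log2(map_ctrl.density + prior)
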