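"""Ward clustering with a dynamic tree cut, cluster markers, and the
pseudo-bulk Fisher-exact reference annotation.

Cells are clustered hierarchically on Euclidean distances between their
normalized log-expression profiles with Ward's criterion.  Clusters are
extracted by an adaptive (dynamic) cut: a branch is split where the merge
height jumps well above the spread of merge heights inside the branch,
subject to a minimum cluster size; cells in undersized branches are rescued
to the nearest cluster centroid.  Markers come from per-gene two-group
Welch comparisons between all ordered cluster pairs.  For annotation,
control cells of each cluster are summed into pseudo-bulk profiles, genes
are binarized as expressed / not-expressed via a two-component Gaussian
mixture on pooled nonzero log expression, and each cluster's expressed set
is tested for overlap against reference cell-type profiles with one-sided
Fisher exact tests (BH-corrected, top 10 by decreasing odds ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from sklearn.mixture import GaussianMixture

from .io_model import CONTROL, CountMatrix
from .pseudobulk_de import bh_fdr

# a branch is split when (parent height - tallest child height) exceeds this
# multiple of the standard deviation of merge heights inside the branch;
# gap/spread stays near 1 for a homogeneous blob and reaches ~10 for genuine
# substructure, so 3 separates the two regimes with margin
DEFAULT_SPLIT_GAP_FACTOR = 3.0


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix
    labels: np.ndarray           # per-cell labels 1..K
    n_clusters: int


def ward_cluster(logcounts: np.ndarray) -> np.ndarray:
    """Ward linkage on Euclidean distances between cells (columns)."""
    X = np.asarray(logcounts, dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in clustering input")
    return sch.linkage(X, method="ward")


def dynamic_cut(
    linkage: np.ndarray,
    logcounts: np.ndarray,
    min_cluster_size: int = 20,
    split_gap_factor: float = DEFAULT_SPLIT_GAP_FACTOR,
) -> ClusterResult:
    """Adaptive top-down cut of a Ward dendrogram.

    Starting at the root, a branch is split into its two children when the
    gap between the branch's merge height and its tallest child merge
    exceeds ``split_gap_factor`` times the branch-internal height spread
    (standard deviation of the merge heights strictly inside the branch);
    children smaller than ``min_cluster_size`` are not clusters — their
    cells are assigned to the nearest retained cluster centroid.
    """
    Z = np.asarray(linkage, dtype=float)
    n = Z.shape[0] + 1
    X = np.asarray(logcounts, dtype=float).T
    if X.shape[0] != n:
        raise ValueError("linkage and data disagree on the number of cells")
    if min_cluster_size > n:
        raise ValueError("min_cluster_size exceeds the number of cells")

    def members(node: int) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((int(Z[v - n, 0]), int(Z[v - n, 1])))
        return np.asarray(out, dtype=int)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def internal_heights(node: int) -> np.ndarray:
        """Merge heights strictly inside subtree(node), excluding node itself."""
        out, stack = [], []
        if node >= n:
            stack.extend((int(Z[node - n, 0]), int(Z[node - n, 1])))
        while stack:
            v = stack.pop()
            if v >= n:
                out.append(Z[v - n, 2])
                stack.extend((int(Z[v - n, 0]), int(Z[v - n, 1])))
        return np.asarray(out)

    clusters: list[np.ndarray] = []
    leftovers: list[np.ndarray] = []
    stack = [2 * n - 2]  # root
    while stack:
        v = stack.pop()
        mem = members(v)
        if v < n or len(mem) < 2 * min_cluster_size:
            (clusters if len(mem) >= min_cluster_size else leftovers).append(mem)
            continue
        left, right = int(Z[v - n, 0]), int(Z[v - n, 1])
        inside = internal_heights(v)
        spread = float(inside.std()) if len(inside) >= 2 else 0.0
        gap = height(v) - max(height(left), height(right))
        if spread > 0 and gap > split_gap_factor * spread:
            stack.extend((left, right))
        else:
            clusters.append(mem)

    if not clusters:  # everything undersized: one cluster of all cells
        clusters = [np.arange(n)]
        leftovers = []

    labels = np.zeros(n, dtype=int)
    # deterministic numbering: by smallest member index
    clusters.sort(key=lambda m: int(m.min()))
    centroids = []
    for k, mem in enumerate(clusters, start=1):
        labels[mem] = k
        centroids.append(X[mem].mean(axis=0))
    centroids = np.vstack(centroids)
    for mem in leftovers:
        d = ((X[mem][:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels[mem] = d.argmin(axis=1) + 1
    return ClusterResult(Z, labels, len(clusters))


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

@dataclass
class MarkerTable:
    pairwise: dict          # (focal, other) -> DataFrame(gene, lfc, p)
    top_sets: dict          # focal cluster -> ordered list of genes


def find_markers(
    logcounts: np.ndarray,
    labels: np.ndarray,
    gene_ids,
    top_n: int = 10,
) -> MarkerTable:
    """Per-gene Welch comparisons for every ordered cluster pair.

    For each focal cluster, genes with positive log-fold-change over the
    other cluster are ranked by p; the cluster's top-set is the union of the
    top ``top_n`` genes over its pairwise comparisons.
    """
    logcounts = np.asarray(logcounts, dtype=float)
    labels = np.asarray(labels)
    gene_ids = np.asarray(gene_ids, dtype=object)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for marker finding")
    groups = {k: logcounts[:, labels == k] for k in uniq}
    pairwise: dict = {}
    top_sets: dict = {}
    for a in uniq:
        chosen: list[str] = []
        for b in uniq:
            if a == b:
                continue
            xa, xb = groups[a], groups[b]
            if xa.shape[1] < 2 or xb.shape[1] < 2:
                warnings.warn(f"cluster pair ({a},{b}) skipped: group of size < 2")
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
            lfc = xa.mean(axis=1) - xb.mean(axis=1)
            p = np.where(np.isnan(p), 1.0, p)
            tab = pd.DataFrame({"gene": gene_ids, "lfc": lfc, "p": p})
            pairwise[(a, b)] = tab
            up = tab[tab["lfc"] > 0].sort_values(["p", "gene"], kind="stable")
            for g in up["gene"].head(top_n):
                if g not in chosen:
                    chosen.append(g)
        top_sets[a] = chosen
    return MarkerTable(pairwise, top_sets)


# ---------------------------------------------------------------------------
# pseudo-bulk Fisher annotation
# ---------------------------------------------------------------------------

def pseudobulk_by_cluster(
    counts: CountMatrix,
    labels: np.ndarray,
    cell_table: pd.DataFrame,
    condition_filter: str | None = CONTROL,
) -> pd.DataFrame:
    """Sum counts over (by default control) cells per cluster.

    Returns a genes x clusters DataFrame; clusters with no eligible cells
    are omitted with a warning.
    """
    labels = np.asarray(labels)
    eligible = np.ones(counts.n_cells, dtype=bool)
    if condition_filter is not None:
        eligible = cell_table["condition"].to_numpy() == condition_filter
    profiles = {}
    for k in np.unique(labels):
        idx = np.flatnonzero((labels == k) & eligible)
        if len(idx) == 0:
            warnings.warn(f"cluster {k}: no {condition_filter} cells; omitted")
            continue
        profiles[k] = np.asarray(counts.values[:, idx].sum(axis=1)).ravel()
    return pd.DataFrame(profiles, index=counts.gene_ids)


def binarize_expression(profiles: pd.DataFrame, seed: int = 0):
    """Classify genes as expressed / not-expressed per pseudo-bulk profile.

    Profiles are converted to log2(CPM+1); a two-component Gaussian mixture
    is fitted to the pooled nonzero values and the threshold is the point of
    equal posterior probability between the components.  If the fit is
    degenerate (components closer than 0.5 log2 units) the pooled median is
    used instead, with a warning.  Returns (expressed bool DataFrame,
    threshold).
    """
    vals = profiles.to_numpy(dtype=float)
    cpm = vals / np.maximum(vals.sum(axis=0), 1)[None, :] * 1e6
    logx = np.log2(cpm + 1.0)
    pooled = logx[vals > 0]
    if pooled.size < 10:
        raise ValueError("too few nonzero values to binarize")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(pooled.reshape(-1, 1))
    m = np.sort(gm.means_.ravel())
    if m[1] - m[0] < 0.5:
        warnings.warn("expression distribution not clearly bimodal; using pooled median")
        thr = float(np.median(pooled))
    else:
        grid = np.linspace(m[0], m[1], 2001)
        post = gm.predict_proba(grid.reshape(-1, 1))
        hi = int(np.argmax(gm.means_.ravel()))
        thr = float(grid[np.argmin(np.abs(post[:, hi] - 0.5))])
    expressed = pd.DataFrame(
        (logx > thr) & (vals > 0), index=profiles.index, columns=profiles.columns
    )
    return expressed, thr


def fisher_annotation(
    query_binary: pd.DataFrame,
    reference_binary: pd.DataFrame,
    fdr: float = 0.05,
    top: int = 10,
) -> dict:
    """One-sided Fisher exact overlap tests of expressed-gene sets.

    For every (cluster, reference type) pair the 2x2 table over the shared
    gene universe {both expressed / query only / reference only / neither}
    is tested for enrichment; p-values are BH-corrected across references
    within each cluster.  Returns {cluster: DataFrame(reference, odds_ratio,
    p, q)} with up to ``top`` significant rows sorted by decreasing odds
    ratio (infinite first, ties by p).
    """
    shared = query_binary.index.intersection(reference_binary.index)
    if len(shared) == 0:
        raise ValueError("empty shared gene universe")
    q = query_binary.loc[shared]
    r = reference_binary.loc[shared]
    out = {}
    for cluster in q.columns:
        qc = q[cluster].to_numpy()
        rows = []
        for ref in r.columns:
            rc = r[ref].to_numpy()
            a = int(np.sum(qc & rc))
            b = int(np.sum(qc & ~rc))
            c = int(np.sum(~qc & rc))
            d = int(np.sum(~qc & ~rc))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            if b * c == 0:
                oratio = np.inf if a * d > 0 else np.nan
            else:
                oratio = (a * d) / (b * c)
            rows.append({"reference": ref, "odds_ratio": oratio, "p": p})
        tab = pd.DataFrame(rows)
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        sig = tab[tab["q"] < fdr].copy()
        sig["_inf"] = ~np.isinf(sig["odds_ratio"].to_numpy())
        sig = sig.sort_values(
            ["_inf", "odds_ratio", "p"], ascending=[True, False, True], kind="stable"
        ).drop(columns="_inf")
        out[cluster] = sig.head(top).reset_index(drop=True)
    return out
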