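"""Core data types and readers/writers for the formats the pipeline touches.

The pipeline operates on droplet scRNA-seq UMI counts stored in the 10x
Genomics MatrixMarket triplet layout (matrix.mtx + features/genes TSV +
barcodes TSV, plain or gzipped), on tab-delimited sample sheets mapping
samples to experimental conditions, and on GMT gene-set files.  Matrices are
held genes-as-rows everywhere inside the package; any transposition happens
at I/O boundaries only.
"""

from __future__ import annotations

import dataclasses
import gzip
import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

CONTROL = "control"
CKO = "cKO"
CONDITIONS = (CONTROL, CKO)

#: default symbol prefixes marking hemoglobin genes (mouse nomenclature)
HEMOGLOBIN_PREFIXES = ("Hba", "Hbb")
#: case-insensitive symbol prefix marking mitochondrial genes
MITO_PREFIX = "mt-"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Genes x cells matrix of nonnegative integer UMI counts.

    ``values`` is a CSR sparse matrix; ``gene_ids`` and ``cell_ids`` are
    ordered, unique identifier arrays matching the rows / columns.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"row count {n_genes} != number of gene ids {len(self.gene_ids)}"
            )
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"column count {n_cells} != number of cell ids {len(self.cell_ids)}"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} identifiers are not unique")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("count matrix contains negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("count matrix contains non-integer entries")
        self.values.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[idx, :], self.gene_ids[idx], self.cell_ids)


def make_cell_table(
    cell_ids: Sequence[str],
    sample_id: str | Sequence[str],
    condition: str | Sequence[str],
    truth_label: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a per-cell metadata table (cell_id, sample_id, condition[, truth_label])."""
    n = len(cell_ids)
    tab = pd.DataFrame(
        {
            "cell_id": np.asarray(cell_ids, dtype=object),
            "sample_id": np.repeat(sample_id, n) if np.isscalar(sample_id) else np.asarray(sample_id, dtype=object),
            "condition": np.repeat(condition, n) if np.isscalar(condition) else np.asarray(condition, dtype=object),
        }
    )
    if truth_label is not None:
        tab["truth_label"] = np.asarray(truth_label, dtype=object)
    validate_cell_table(tab)
    return tab


def validate_cell_table(tab: pd.DataFrame) -> None:
    if tab["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    bad = set(tab["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}; expected {CONDITIONS}")


def make_gene_table(
    gene_ids: Sequence[str],
    symbols: Sequence[str],
    hemoglobin_prefixes: Sequence[str] = HEMOGLOBIN_PREFIXES,
) -> pd.DataFrame:
    """Per-gene table with symbol and the QC flags (mitochondrial / hemoglobin).

    Mitochondrial genes are recognized by the case-insensitive ``mt-`` symbol
    prefix; hemoglobin genes by the configured symbol prefix list.
    """
    symbols = np.asarray(symbols, dtype=object)
    is_mito = np.array([s.lower().startswith(MITO_PREFIX) for s in symbols])
    lowpfx = tuple(p.lower() for p in hemoglobin_prefixes)
    is_hb = np.array([s.lower().startswith(lowpfx) for s in symbols])
    tab = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object),
            "symbol": symbols,
            "is_mito": is_mito,
            "is_hemoglobin": is_hb,
        }
    )
    if tab["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique")
    return tab


@dataclass
class AnalysisConfig:
    """All numeric parameters of the pipeline, one attribute per threshold.

    Defaults are the published analysis settings: QC cutoffs on log10 library
    size / feature count, the 5% mitochondrial and zero-tolerance hemoglobin
    rules, the low-abundance filter at average log2 CPM 0.005, loess span
    0.05, 500 highly variable genes, t-SNE perplexity 30, a 9x9 SOM on 30
    principal components, pseudo-bulk aggregation at >=20 cells, DE gene
    filters (CPM>1 in >=3 samples, detected in >=20 cells), 5% FDR, camera
    inter-gene correlation 0.01, gene sets of >10 members, and a 1e-3 density
    prior.
    """

    min_log10_libsize: float = 2.8
    min_log10_features: float = 2.6
    max_mito_fraction: float = 0.05
    max_hemoglobin_umis: int = 0
    min_avg_log2_cpm: float = 0.005
    loess_span: float = 0.05
    n_hvg: int = 500
    tsne_perplexity: float = 30.0
    n_som_pcs: int = 30
    som_grid: tuple[int, int] = (9, 9)
    min_cells_aggregate: int = 20
    de_min_cpm: float = 1.0
    de_min_samples: int = 3
    de_min_cells_detected: int = 20
    fdr_threshold: float = 0.05
    camera_rho: float = 0.01
    min_set_size: int = 11
    density_prior: float = 1e-3
    top_markers_per_pair: int = 10
    min_cluster_size: int = 20
    pool_sizes: tuple[int, ...] = (21, 41, 61, 81, 101)
    use_preclustering: bool = False
    hemoglobin_prefixes: tuple[str, ...] = HEMOGLOBIN_PREFIXES
    rng_seed: int = 0

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["som_grid"] = list(self.som_grid)
        d["pool_sizes"] = list(self.pool_sizes)
        d["hemoglobin_prefixes"] = list(self.hemoglobin_prefixes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("som_grid", "pool_sizes", "hemoglobin_prefixes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# 10x MatrixMarket triplet I/O
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_triplet_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {list(stems)} (or .gz) found in {directory}"
    )


def read_10x_mtx(
    directory: str | os.PathLike,
    hemoglobin_prefixes: Sequence[str] = HEMOGLOBIN_PREFIXES,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a 10x-style triplet directory into (CountMatrix, gene table).

    Accepts matrix.mtx[.gz] plus features.tsv[.gz] or genes.tsv[.gz]
    (columns: gene_id, symbol[, type]) and barcodes.tsv[.gz].  The matrix is
    validated to be integer and nonnegative with genes as rows.
    """
    directory = Path(directory)
    mtx_path = _find_triplet_file(directory, ["matrix.mtx"])
    feat_path = _find_triplet_file(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find_triplet_file(directory, ["barcodes.tsv"])

    try:
        with _open_maybe_gz(mtx_path) as fh:
            mat = scipy.io.mmread(_io.StringIO(fh.read()))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise FormatError(f"{mtx_path}: malformed MatrixMarket file ({exc})") from exc
    mat = sp.csr_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path}: matrix contains non-integer values")

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        feats[1] = feats[0]
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].to_numpy()

    if mat.shape[0] != len(feats):
        raise FormatError(
            f"{mtx_path}: {mat.shape[0]} rows but {len(feats)} features in {feat_path}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: {mat.shape[1]} columns but {len(barcodes)} barcodes in {bc_path}"
        )

    gene_table = make_gene_table(
        feats[0].to_numpy(), feats[1].to_numpy(), hemoglobin_prefixes
    )
    counts = CountMatrix(mat, gene_table["gene_id"].to_numpy(), barcodes)
    return counts, gene_table


def write_10x_mtx(
    counts: CountMatrix, gene_table: pd.DataFrame, directory: str | os.PathLike
) -> None:
    """Write a CountMatrix as a plain-text 10x triplet (matrix.mtx, features.tsv,
    barcodes.tsv).  Round-trips bit-exactly through :func:`read_10x_mtx`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = counts.values.tocoo()
    with open(directory / "matrix.mtx", "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{counts.n_genes} {counts.n_cells} {coo.nnz}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {int(v)}\n")
    feats = gene_table.set_index("gene_id").loc[counts.gene_ids, "symbol"]
    with open(directory / "features.tsv", "w") as fh:
        for gid, sym in feats.items():
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for bc in counts.cell_ids:
            fh.write(f"{bc}\n")


def merge_samples(
    samples: Sequence[tuple[CountMatrix, pd.DataFrame]],
) -> tuple[CountMatrix, pd.DataFrame]:
    """Concatenate per-sample matrices column-wise without any rescaling.

    Mirrors aggregation of Chromium runs with downsampling disabled: counts
    are untouched, cell ids get a "-<k>" sample-index suffix to stay unique,
    and total UMIs equal the sum over inputs.  All samples must share the
    same gene universe in the same order.
    """
    if not samples:
        raise ValueError("no samples to merge")
    ref_genes = samples[0][0].gene_ids
    mats, tabs = [], []
    for k, (cm, ct) in enumerate(samples, start=1):
        if len(cm.gene_ids) != len(ref_genes) or not np.array_equal(cm.gene_ids, ref_genes):
            raise ValueError(f"sample {k}: gene universe/order mismatch with sample 1")
        new_ids = np.array([f"{cid}-{k}" for cid in cm.cell_ids], dtype=object)
        mats.append(cm.values)
        tab = ct.copy()
        tab["cell_id"] = [f"{cid}-{k}" for cid in ct["cell_id"]]
        tab.index = range(len(tab))
        tabs.append(tab.assign(_new_cell_id=new_ids))
    merged = CountMatrix(
        sp.hstack(mats, format="csr"),
        ref_genes,
        np.concatenate([t["_new_cell_id"].to_numpy() for t in tabs]),
    )
    cell_table = pd.concat([t.drop(columns="_new_cell_id") for t in tabs], ignore_index=True)
    validate_cell_table(cell_table)
    if not np.array_equal(cell_table["cell_id"].to_numpy(), merged.cell_ids):
        raise AssertionError("cell table and matrix column order diverged")
    return merged, cell_table


# ---------------------------------------------------------------------------
# gene sets / sample sheets
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into an ordered {set_name: [symbols]} mapping."""
    sets: dict[str, list[str]] = {}
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            tokens = line.split("\t")
            if len(tokens) < 3:
                raise FormatError(
                    f"{path}:{lineno}: gene set '{tokens[0]}' has no members"
                )
            name = tokens[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            members = [t for t in tokens[2:] if t]
            if not members:
                raise FormatError(
                    f"{path}:{lineno}: gene set '{name}' has no members"
                )
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample_id, path, condition."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "path", "condition"} - set(sheet.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"{path}: unknown conditions {sorted(bad)}")
    return sheet
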