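"""Count-matrix data model and preprocessing.

Ingestion of 10x-style MTX triplets and delimited gene x cell tables,
union-merging of datasets, gene detection filtering, library-size
normalization, binned-dispersion highly-variable-gene selection with
gene-set exclusion, and PCA.

Matrices are stored genes x cells (rows are genes), sparse-friendly via
``scipy.sparse``. All downstream modules consume :class:`NormalizedMatrix`,
whose values are ``ln(1 + count / cell_total * scale_factor)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "CellAnnotation",
    "PCAResult",
    "read_counts",
    "read_metadata",
    "merge_union",
    "filter_genes",
    "normalize",
    "select_hvgs",
    "exclude_gene_set",
    "pca",
    "read_gene_list",
]

REQUIRED_METADATA_COLUMNS = ("cell", "niche", "age_label", "group", "batch")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} identifiers: {dups[:10]}")


@dataclass
class CountMatrix:
    """Raw gene x cell counts with unique gene and cell identifiers."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detection_counts(self) -> np.ndarray:
        """Number of cells in which each gene has a count > 0."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()


@dataclass
class NormalizedMatrix:
    """Log1p library-size-normalized expression, genes x cells.

    For every cell with nonzero raw total,
    ``sum_g(expm1(value[g, c])) == scale_factor`` up to rounding error.
    """

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        self.values = self.values.tocsr()
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape inconsistent with gene/cell lists")
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask: np.ndarray) -> np.ndarray:
        """Dense genes x k block for the masked cells."""
        return np.asarray(self.values[:, mask].todense())


@dataclass
class CellAnnotation:
    """Per-cell niche, age, cell-type group and batch labels.

    Wraps a DataFrame indexed by cell id with columns
    ``niche, age_label, age_days, group, batch`` (``age_days`` optional at
    ingestion; the temporal module fills it from age labels).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate cell ids in annotation")
        missing = [c for c in ("niche", "age_label", "group", "batch") if c not in t.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")

    @property
    def cells(self) -> list[str]:
        return list(self.table.index)

    def reindex(self, cells: Sequence[str]) -> "CellAnnotation":
        absent = [c for c in cells if c not in self.table.index]
        if absent:
            raise ValueError(f"cells absent from annotation: {absent[:10]}")
        return CellAnnotation(self.table.loc[list(cells)].copy())

    def group_mask(self, group: str | Iterable[str]) -> np.ndarray:
        """Boolean mask over rows for one group label or a collection."""
        labels = {group} if isinstance(group, str) else set(group)
        known = set(self.table["group"])
        unknown = labels - known
        if unknown:
            raise KeyError(f"unknown group label(s): {sorted(unknown)}")
        return self.table["group"].isin(labels).to_numpy()


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> CellAnnotation:
    """Read a metadata TSV with columns cell, niche, age_label, group, batch."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    t = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"metadata {path} missing required columns: {missing}")
    t = t.set_index("cell")
    if "age_days" in t.columns:
        t["age_days"] = t["age_days"].astype(int)
    return CellAnnotation(t)


def _read_mtx_10x(path: Path) -> CountMatrix:
    matrix_path = path / "matrix.mtx"
    barcodes_path = path / "barcodes.tsv"
    features_path = path / "features.tsv"
    if not features_path.exists():
        features_path = path / "genes.tsv"
    for p in (matrix_path, barcodes_path, features_path):
        if not p.exists():
            raise FileNotFoundError(p)
    counts = sp.csr_matrix(scipy.io.mmread(matrix_path))
    genes = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return CountMatrix(genes=genes, cells=cells, counts=counts)


def _read_delimited(path: Path) -> CountMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    t = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        genes=[str(g) for g in t.index],
        cells=[str(c) for c in t.columns],
        counts=sp.csr_matrix(t.to_numpy()),
    )


def read_counts(
    path: str | Path,
    format: str = "mtx_10x",
    metadata_path: str | Path | None = None,
) -> tuple[CountMatrix, CellAnnotation]:
    """Read a count matrix plus cell metadata.

    ``format`` is ``"mtx_10x"`` (directory with matrix.mtx, features/genes.tsv,
    barcodes.tsv; genes as rows) or ``"delimited"`` (TSV/CSV gene x cell table
    with a header row of cell ids). Metadata must cover every cell; the
    returned annotation is reordered to the matrix's cell order.
    """
    path = Path(path)
    if format == "mtx_10x":
        mat = _read_mtx_10x(path)
    elif format == "delimited":
        mat = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx_10x' or 'delimited'")
    if metadata_path is None:
        raise ValueError("metadata_path is required")
    ann = read_metadata(metadata_path)
    missing = [c for c in mat.cells if c not in ann.table.index]
    if missing:
        raise ValueError(f"cells in matrix missing from metadata: {missing[:10]}")
    return mat, ann.reindex(mat.cells)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line TSV/TXT gene list (first column used)."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            genes.append(line.split("\t")[0])
    _check_unique(genes, "gene")
    return genes


# ---------------------------------------------------------------------------
# Merging and filtering
# ---------------------------------------------------------------------------

def merge_union(matrices: Sequence[CountMatrix]) -> CountMatrix:
    """Merge datasets on the union of all detected genes.

    Genes absent from a source dataset are zero in its cells, so the total
    count mass is conserved exactly. Cell ids must be disjoint across inputs.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    if len(matrices) == 1:
        m = matrices[0]
        return CountMatrix(list(m.genes), list(m.cells), m.counts.copy())
    all_cells: list[str] = []
    for m in matrices:
        all_cells.extend(m.cells)
    _check_unique(all_cells, "cell")

    union: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for g in m.genes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    gene_pos = {g: i for i, g in enumerate(union)}

    blocks = []
    for m in matrices:
        rows = np.array([gene_pos[g] for g in m.genes])
        coo = m.counts.tocoo()
        blocks.append(
            sp.coo_matrix(
                (coo.data, (rows[coo.row], coo.col)),
                shape=(len(union), len(m.cells)),
            )
        )
    merged = sp.hstack(blocks).tocsr()
    return CountMatrix(genes=union, cells=all_cells, counts=merged)


def filter_genes(mat: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Drop genes detected (count > 0) in fewer than ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    keep = mat.detection_counts() >= min_cells
    if not keep.any():
        warnings.warn("filter_genes removed every gene", stacklevel=2)
    return CountMatrix(
        genes=[g for g, k in zip(mat.genes, keep) if k],
        cells=list(mat.cells),
        counts=mat.counts[keep],
    )


def normalize(mat: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize then natural log1p.

    ``value(g, c) = ln(1 + count(g, c) / total(c) * scale_factor)``.
    Cells with zero total are rejected by name rather than dropped.
    """
    totals = mat.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [mat.cells[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total count: {names}")
    x = mat.counts.tocsc().astype(float)
    x = x.multiply(scale_factor / totals[np.newaxis, :]).tocsr()
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        genes=list(mat.genes), cells=list(mat.cells), values=x, scale_factor=scale_factor
    )


# ---------------------------------------------------------------------------
# HVG selection, gene-set exclusion, PCA
# ---------------------------------------------------------------------------

def _row_mean_var(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    mean = np.asarray(values.mean(axis=1)).ravel()
    sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    # cancellation in sq - mean^2 leaves O(eps * sq) residue on constant rows
    var[var <= sq * 1e-12] = 0.0
    return mean, np.maximum(var, 0.0)


def select_hvgs(norm: NormalizedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Rank genes by mean-binned standardized dispersion; return the top ``n``.

    Dispersion is variance/mean of the log-normalized values, z-scored within
    quantile bins of the gene mean so that highly expressed genes do not
    dominate. Constant genes are never selected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mean, var = _row_mean_var(norm.values)
    expressed = var > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    z = np.full(len(mean), -np.inf)
    idx = np.flatnonzero(expressed)
    if idx.size:
        bins = pd.qcut(mean[idx], q=min(n_bins, idx.size), duplicates="drop", labels=False)
        d = pd.Series(disp[idx])
        grouped = d.groupby(bins)
        mu = grouped.transform("mean")
        sd = grouped.transform("std").fillna(0.0)
        z[idx] = np.where(sd > 0, (d - mu) / sd, 0.0)
    order = np.argsort(-z, kind="stable")
    ranked = [norm.genes[i] for i in order if expressed[i]]
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} non-constant genes available (requested {n})",
            stacklevel=2,
        )
    return ranked[:n]


def exclude_gene_set(genes: Sequence[str], excluded: Iterable[str]) -> list[str]:
    """Order-preserving set difference; errors if nothing remains."""
    excl = set(excluded)
    out = [g for g in genes if g not in excl]
    if not out:
        raise ValueError("exclusion removed every gene; nothing left to embed on")
    n_removed = len(genes) - len(out)
    if n_removed:
        warnings.warn(f"excluded {n_removed} gene(s) from feature list", stacklevel=2)
    return out


@dataclass
class PCAResult:
    """Cell x k embedding with per-component explained variance."""

    embedding: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # k x genes, orthonormal rows
    genes: list[str] = field(default_factory=list)


def pca(norm: NormalizedMatrix, genes: Sequence[str], k: int = 30) -> PCAResult:
    """PCA of cells on the given feature genes (centered per gene)."""
    gene_pos = {g: i for i, g in enumerate(norm.genes)}
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise KeyError(f"feature genes absent from matrix: {missing[:10]}")
    rows = [gene_pos[g] for g in genes]
    x = np.asarray(norm.values[rows].todense()).T  # cells x genes
    max_k = min(x.shape)
    if not (1 <= k <= max_k):
        raise ValueError(f"k={k} out of range [1, {max_k}]")
    from sklearn.decomposition import PCA as _PCA

    model = _PCA(n_components=k, svd_solver="full")
    emb = model.fit_transform(x)
    return PCAResult(
        embedding=emb,
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
        components=model.components_,
        genes=list(genes),
    )
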