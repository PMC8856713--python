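"""Centroid Pearson correlation and the single-cell correlation projection.

A group centroid is the per-gene arithmetic mean of log-normalized
expression over the group's cells, computed over the full merged gene
universe. Centroid-vs-centroid Pearson matrices reproduce the heatmap
comparisons between niche/age populations, and the 2D single-cell
projection places each cell at

    x = r(cell, A1) - r(cell, A2),   y = r(cell, B1) - r(cell, B2)

against four reference centroids (e.g., adult dormant NSCs vs embryonic
RPs on each axis). Values are intentionally not batch-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .count_matrix import CellAnnotation, NormalizedMatrix

__all__ = [
    "CentroidProfile",
    "ProjectionCoordinates",
    "pearson_r",
    "group_centroid",
    "centroid_correlation_matrix",
    "single_cell_projection",
]


@dataclass
class CentroidProfile:
    """Per-gene mean expression of a cell group over a fixed gene universe."""

    group: str
    values: pd.Series  # indexed by gene
    n_cells: int

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class ProjectionCoordinates:
    """Per-cell correlation-difference coordinates against four centroids."""

    coords: pd.DataFrame  # columns x, y; indexed by cell
    references: dict[str, str] = field(default_factory=dict)  # A1/A2/B1/B2 -> group
    excluded_cells: list[str] = field(default_factory=list)  # constant profiles


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 1-D vectors (both must be non-constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _pearson_matrix_vs_vector(mat: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``mat`` (genes x cells) with vector ``v``.

    Columns with zero variance yield NaN.
    """
    v = np.asarray(v, dtype=float)
    vc = v - v.mean()
    vn = np.sqrt(vc @ vc)
    mc = mat - mat.mean(axis=0, keepdims=True)
    norms = np.sqrt((mc * mc).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mc.T @ vc) / (norms * vn)
    r[norms == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def group_centroid(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    group: str | Iterable[str],
) -> CentroidProfile:
    """Average the expression of each gene over the group's cells."""
    mask = ann.reindex(norm.cells).group_mask(group)
    if not mask.any():
        raise ValueError(f"group {group!r} is empty")
    mean = np.asarray(norm.values[:, mask].mean(axis=1)).ravel()
    label = group if isinstance(group, str) else "+".join(group)
    return CentroidProfile(
        group=label,
        values=pd.Series(mean, index=pd.Index(norm.genes, name="gene")),
        n_cells=int(mask.sum()),
    )


def centroid_correlation_matrix(centroids: Sequence[CentroidProfile]) -> pd.DataFrame:
    """Symmetric Pearson-r matrix between centroids, input order preserved."""
    if len(centroids) < 2:
        raise ValueError("need at least two centroids")
    universe = centroids[0].genes
    for c in centroids[1:]:
        if not c.genes.equals(universe):
            raise ValueError(
                f"centroid {c.group!r} uses a different gene universe; "
                "compute all centroids on the same merged matrix"
            )
    for c in centroids:
        if np.ptp(c.values.to_numpy()) == 0:
            raise ValueError(f"centroid {c.group!r} is constant; correlation undefined")
    stack = np.vstack([c.values.to_numpy() for c in centroids])
    r = np.corrcoef(stack)
    np.fill_diagonal(r, 1.0)
    labels = [c.group for c in centroids]
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=labels, columns=labels)


def single_cell_projection(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    refA1: str | Iterable[str],
    refA2: str | Iterable[str],
    refB1: str | Iterable[str],
    refB2: str | Iterable[str],
) -> ProjectionCoordinates:
    """Project every cell onto correlation-difference coordinates.

    ``x = r(cell, centroid(refA1)) - r(cell, centroid(refA2))`` and likewise
    ``y`` from the B pair, so both coordinates lie in [-2, 2]. Cells in the
    reference groups are themselves projected. Constant cell profiles have
    undefined correlation; they are excluded and reported.
    """
    cents = {
        "A1": group_centroid(norm, ann, refA1),
        "A2": group_centroid(norm, ann, refA2),
        "B1": group_centroid(norm, ann, refB1),
        "B2": group_centroid(norm, ann, refB2),
    }
    dense = np.asarray(norm.values.todense())  # genes x cells
    r = {k: _pearson_matrix_vs_vector(dense, c.values.to_numpy()) for k, c in cents.items()}
    x = r["A1"] - r["A2"]
    y = r["B1"] - r["B2"]
    bad = ~(np.isfinite(x) & np.isfinite(y))
    coords = pd.DataFrame(
        {"x": x, "y": y}, index=pd.Index(norm.cells, name="cell")
    ).loc[~bad]
    return ProjectionCoordinates(
        coords=coords,
        references={k: c.group for k, c in cents.items()},
        excluded_cells=[c for c, b in zip(norm.cells, bad) if b],
    )
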