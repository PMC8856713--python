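"""Per-gene correlation of expression with developmental time.

Developmental ages are mapped to integer days with birth at zero
(``P<n> -> n``; embryonic ``E<x> -> round(x - gestation_length)``, banker's
rounding, mouse gestation 19.5 d by default). Per gene, the Spearman rank
correlation of log-normalized expression with age in days is computed with
average ranks for ties; constant genes are flagged undefined and excluded
downstream. A gene set (e.g., a quiescence program) is tested for being
more correlated with time than all other detected genes via a one-sided
Wilcoxon rank-sum test on the correlation coefficients. The ranking can be
exported as a GSEA-preranked ``.rnk`` file for external enrichment tools.

Because Spearman's rho only sees the ordering of ages, the embryonic
integer mapping (and hence the gestation-length choice) cannot change any
coefficient as long as it preserves age order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .count_matrix import CellAnnotation, NormalizedMatrix
from .diffexp import EXACT_MAX_N, exact_ranksum_p
from .signatures import GeneSignature

__all__ = [
    "AgeMap",
    "ShiftTestResult",
    "age_to_days",
    "spearman_with_time",
    "gene_set_shift_test",
    "export_preranked",
    "read_preranked",
]

_LABEL_RE = re.compile(r"^([EP])(\d+(?:\.\d+)?)$")


@dataclass
class AgeMap:
    """Age-label to age-in-days mapping with birth at zero.

    Explicit entries in ``overrides`` win; otherwise labels are parsed as
    ``P<n>`` (postnatal day n) or ``E<x>`` (embryonic day x, mapped to
    ``round(x - gestation_length)``, round-half-even).
    """

    gestation_length: float = 19.5
    overrides: Mapping[str, int] = field(default_factory=dict)

    def __call__(self, label: str) -> int:
        return age_to_days(label, self)


def age_to_days(label: str, age_map: AgeMap | None = None) -> int:
    """Convert an age label such as "P34" or "E16.5" to integer days."""
    age_map = age_map or AgeMap()
    if label in age_map.overrides:
        return int(age_map.overrides[label])
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparseable age label {label!r}; expected E<x> or P<n>")
    stage, value = m.group(1), float(m.group(2))
    if stage == "P":
        if value != int(value):
            raise ValueError(f"postnatal label {label!r} must be an integer day")
        return int(value)
    # numpy rounds half to even, matching Python's round()
    return int(np.round(value - age_map.gestation_length))


def _ensure_age_days(ann: CellAnnotation, age_map: AgeMap | None) -> pd.Series:
    if "age_days" in ann.table.columns:
        return ann.table["age_days"].astype(int)
    labels = ann.table["age_label"]
    mapping = {lab: age_to_days(lab, age_map) for lab in labels.unique()}
    return labels.map(mapping).astype(int)


def spearman_with_time(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    cells_subset: Iterable[str] | None = None,
    age_map: AgeMap | None = None,
) -> pd.DataFrame:
    """Spearman rho of each gene's expression with age in days across cells.

    Returns a DataFrame indexed by gene with columns ``rho`` (NaN where
    undefined) and ``defined`` (False for constant genes). Ties receive
    average ranks. Requires at least two distinct ages among the cells.
    """
    aligned = ann.reindex(norm.cells)
    age_days = _ensure_age_days(aligned, age_map).to_numpy()
    if cells_subset is not None:
        wanted = set(cells_subset)
        mask = np.array([c in wanted for c in norm.cells])
    else:
        mask = np.ones(len(norm.cells), dtype=bool)
    ages = age_days[mask]
    if np.unique(ages).size < 2:
        raise ValueError("need at least two distinct ages to correlate with time")

    x = norm.subset_cells(mask)  # genes x n
    age_ranks = rankdata(ages)
    ar = age_ranks - age_ranks.mean()
    ar_norm = np.sqrt(ar @ ar)

    expr_ranks = rankdata(x, axis=1)
    er = expr_ranks - expr_ranks.mean(axis=1, keepdims=True)
    er_norms = np.sqrt((er * er).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (er @ ar) / (er_norms * ar_norm)
    defined = er_norms > 0
    rho[~defined] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    out = pd.DataFrame(
        {"rho": rho, "defined": defined}, index=pd.Index(norm.genes, name="gene")
    )
    out.attrs["n_cells"] = int(mask.sum())
    return out


@dataclass
class ShiftTestResult:
    """Wilcoxon rank-sum comparison of a gene set's rhos vs the background."""

    p_value: float
    direction: str  # "greater" or "less": where the set's rhos lie
    median_set: float
    median_background: float
    median_shift: float
    n_set: int
    n_background: int
    alternative: str = "greater"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def gene_set_shift_test(
    table: pd.DataFrame,
    gene_set: GeneSignature | Iterable[str],
    alternative: str = "greater",
) -> ShiftTestResult:
    """Test whether a gene set is more correlated with time than the rest.

    One-sided by default ("set rhos greater than all other detected genes'
    rhos"); ``alternative`` may be "greater", "less" or "two-sided".
    Genes with undefined rho are excluded from both the set and background.
    """
    genes = list(gene_set.genes if isinstance(gene_set, GeneSignature) else gene_set)
    defined = table[table["defined"]]
    in_set = defined.index.isin(set(genes))
    set_rhos = defined.loc[in_set, "rho"].to_numpy()
    bg_rhos = defined.loc[~in_set, "rho"].to_numpy()
    if set_rhos.size == 0:
        raise ValueError("no defined-rho genes in the set")
    if bg_rhos.size == 0:
        raise ValueError("gene set covers all defined genes; background is empty")
    if max(set_rhos.size, bg_rhos.size) <= EXACT_MAX_N:
        p = exact_ranksum_p(set_rhos, bg_rhos, alternative=alternative)
    else:
        p = float(
            mannwhitneyu(
                set_rhos, bg_rhos, alternative=alternative, method="asymptotic"
            ).pvalue
        )
    med_set = float(np.median(set_rhos))
    med_bg = float(np.median(bg_rhos))
    return ShiftTestResult(
        p_value=min(p, 1.0),
        direction="greater" if med_set >= med_bg else "less",
        median_set=med_set,
        median_background=med_bg,
        median_shift=med_set - med_bg,
        n_set=int(set_rhos.size),
        n_background=int(bg_rhos.size),
        alternative=alternative,
    )


def export_preranked(table: pd.DataFrame, path: str | Path) -> None:
    """Write a two-column GSEA-preranked .rnk file sorted by decreasing rho.

    Undefined (constant) genes are omitted; an all-undefined table is an
    error.
    """
    defined = table[table["defined"]].sort_values("rho", ascending=False)
    if defined.empty:
        raise ValueError("no defined correlations to export")
    defined["rho"].to_csv(path, sep="\t", header=False, float_format="%.10g")


def read_preranked(path: str | Path) -> pd.Series:
    """Read a .rnk file back as a gene-indexed Series."""
    t = pd.read_csv(path, sep="\t", header=None, names=["gene", "rho"], index_col=0)
    return t["rho"]
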