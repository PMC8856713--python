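"""Two-group Wilcoxon rank-sum differential expression with Bonferroni FWER.

Per gene, a two-sided Wilcoxon rank-sum (Mann-Whitney) test on the
log-normalized values, an average natural-log fold change computed on
de-logged group means with a pseudocount of 1, and detection fractions per
group. p-values are Bonferroni-adjusted over the genes actually tested in
the contrast (genes expressed in at least one cell of the two groups).

Exact p-values are computed by full enumeration of rank assignments when
both groups have at most ``EXACT_MAX_N`` cells (midranks handle ties); the
tie-corrected normal approximation with continuity correction is used above
that. On top of this sit the enrichment filter (avg logFC > 0.5 and
adjusted p < 0.05 by default, both strict), the dual-contrast cross-niche
shared-dormant-signature derivation, and the NSC-vs-astrocyte cross-niche
overlap percentages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .count_matrix import CellAnnotation, NormalizedMatrix
from .signatures import GeneSignature

__all__ = [
    "EnrichmentCriteria",
    "SharedSignatureResult",
    "OverlapResult",
    "EXACT_MAX_N",
    "wilcoxon_de",
    "filter_enriched",
    "shared_dormant_signature",
    "cross_niche_overlap",
    "exact_ranksum_p",
]

#: Largest per-group size for which the exact enumeration p-value is used.
EXACT_MAX_N = 8

_LOGFC_PSEUDOCOUNT = 1.0


@dataclass
class EnrichmentCriteria:
    """Strict thresholds for calling a gene enriched in group 1."""

    min_logFC: float = 0.5
    max_padj: float = 0.05

    def __post_init__(self) -> None:
        if self.min_logFC < 0:
            raise ValueError("min_logFC must be >= 0")
        if not (0 < self.max_padj <= 1):
            raise ValueError("max_padj must be in (0, 1]")


def exact_ranksum_p(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Exact Wilcoxon rank-sum p by enumeration of all rank assignments.

    Uses midranks, so ties are handled exactly. The two-sided p doubles the
    smaller tail (capped at 1); tails include the observed statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    t_obs = ranks[:n1].sum()
    combs = np.array(
        list(itertools.combinations(range(len(pooled)), n1)), dtype=np.intp
    )
    t_all = ranks[combs].sum(axis=1)
    total = len(t_all)
    eps = 1e-9
    p_ge = np.count_nonzero(t_all >= t_obs - eps) / total
    p_le = np.count_nonzero(t_all <= t_obs + eps) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_ge, p_le))
    raise ValueError(f"unknown alternative {alternative!r}")


def _avg_logfc(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """ln(mean(expm1 v) + 1) difference between groups, rows = genes."""
    m1 = np.expm1(x1).mean(axis=1)
    m2 = np.expm1(x2).mean(axis=1)
    return np.log(m1 + _LOGFC_PSEUDOCOUNT) - np.log(m2 + _LOGFC_PSEUDOCOUNT)


def wilcoxon_de(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    group1: str | Iterable[str],
    group2: str | Iterable[str],
    min_pct: float | None = None,
) -> pd.DataFrame:
    """Differential expression of group1 vs group2.

    Returns a DataFrame indexed by gene with columns ``avg_logFC``,
    ``p_raw``, ``p_adj``, ``pct_group1``, ``pct_group2``, ``direction``.
    Only genes expressed in at least one cell of the two groups are tested
    and enter the Bonferroni multiplicity. ``min_pct`` optionally restricts
    testing to genes detected in at least that percentage of cells in either
    group (off by default).
    """
    aligned = ann.reindex(norm.cells)
    mask1 = aligned.group_mask(group1)
    mask2 = aligned.group_mask(group2)
    if not mask1.any() or not mask2.any():
        raise ValueError("both groups must be non-empty")
    if (mask1 & mask2).any():
        raise ValueError("groups overlap; they must be disjoint")

    x1 = norm.subset_cells(mask1)
    x2 = norm.subset_cells(mask2)
    expressed = (x1 > 0).any(axis=1) | (x2 > 0).any(axis=1)
    pct1 = 100.0 * (x1 > 0).mean(axis=1)
    pct2 = 100.0 * (x2 > 0).mean(axis=1)
    if min_pct is not None:
        expressed &= (pct1 >= min_pct) | (pct2 >= min_pct)
    idx = np.flatnonzero(expressed)
    x1, x2 = x1[idx], x2[idx]
    n1, n2 = x1.shape[1], x2.shape[1]

    pooled = np.hstack([x1, x2])
    constant = np.ptp(pooled, axis=1) == 0
    p_raw = np.ones(len(idx))
    var_rows = np.flatnonzero(~constant)
    if var_rows.size:
        if max(n1, n2) <= EXACT_MAX_N:
            for i in var_rows:
                p_raw[i] = exact_ranksum_p(x1[i], x2[i])
        else:
            res = mannwhitneyu(
                x1[var_rows], x2[var_rows], axis=1, alternative="two-sided",
                method="asymptotic",
            )
            p_raw[var_rows] = np.minimum(res.pvalue, 1.0)

    logfc = _avg_logfc(x1, x2)
    n_tested = len(idx)
    table = pd.DataFrame(
        {
            "avg_logFC": logfc,
            "p_raw": p_raw,
            "p_adj": np.minimum(p_raw * n_tested, 1.0),
            "pct_group1": pct1[idx],
            "pct_group2": pct2[idx],
        },
        index=pd.Index([norm.genes[i] for i in idx], name="gene"),
    )
    table["direction"] = np.select(
        [table["avg_logFC"] > 0, table["avg_logFC"] < 0], ["up", "down"], "zero"
    )
    table.attrs["n_tested"] = n_tested
    table.attrs["n_group1"] = n1
    table.attrs["n_group2"] = n2
    table.attrs["logfc_base"] = "natural log, pseudocount 1 on de-logged means"
    return table


def filter_enriched(
    table: pd.DataFrame, crit: EnrichmentCriteria = EnrichmentCriteria()
) -> list[str]:
    """Genes with avg_logFC > min_logFC and p_adj < max_padj (both strict),
    ordered by decreasing avg_logFC."""
    hit = table[(table["avg_logFC"] > crit.min_logFC) & (table["p_adj"] < crit.max_padj)]
    return list(hit.sort_values("avg_logFC", ascending=False).index)


@dataclass
class SharedSignatureResult:
    """Shared dormant-NSC signature plus the per-niche enriched sets."""

    shared: GeneSignature
    per_niche: dict[str, list[str]] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


_REQUIRED_ROLES = ("embryonic_rp", "dormant_nsc", "tap_ip")


def _niche_dormant_set(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    groups: Mapping[str, str | Iterable[str]],
    crit: EnrichmentCriteria,
    niche: str,
    tables: dict[str, pd.DataFrame],
) -> list[str]:
    missing = [r for r in _REQUIRED_ROLES if r not in groups]
    if missing:
        raise ValueError(f"{niche}: missing group definitions for roles {missing}")
    t_emb = wilcoxon_de(norm, ann, groups["dormant_nsc"], groups["embryonic_rp"])
    t_tap = wilcoxon_de(norm, ann, groups["dormant_nsc"], groups["tap_ip"])
    tables[f"{niche}:dormant_vs_embryonic"] = t_emb
    tables[f"{niche}:dormant_vs_tap_ip"] = t_tap
    hits_emb = filter_enriched(t_emb, crit)
    hits_tap = set(filter_enriched(t_tap, crit))
    # both contrasts must pass; keep the vs-embryonic logFC ordering
    return [g for g in hits_emb if g in hits_tap]


def shared_dormant_signature(
    norm_vsvz: NormalizedMatrix,
    ann_vsvz: CellAnnotation,
    norm_sgz: NormalizedMatrix,
    ann_sgz: CellAnnotation,
    crit: EnrichmentCriteria = EnrichmentCriteria(),
    groups_vsvz: Mapping[str, str | Iterable[str]] | None = None,
    groups_sgz: Mapping[str, str | Iterable[str]] | None = None,
) -> SharedSignatureResult:
    """Derive the cross-niche shared adult dormant NSC signature.

    Per niche, genes enriched in juvenile/adult dormant NSCs relative to
    BOTH embryonic RPs and juvenile/adult TAPs/IPs (each contrast passing
    ``crit``); the shared signature is the intersection of the two per-niche
    sets. ``groups_*`` map the roles ``embryonic_rp``, ``dormant_nsc``,
    ``tap_ip`` to group labels in the respective annotations.
    """
    if groups_vsvz is None or groups_sgz is None:
        raise ValueError("group definitions for both niches are required")
    tables: dict[str, pd.DataFrame] = {}
    set_vsvz = _niche_dormant_set(norm_vsvz, ann_vsvz, groups_vsvz, crit, "V-SVZ", tables)
    set_sgz = _niche_dormant_set(norm_sgz, ann_sgz, groups_sgz, crit, "SGZ", tables)
    in_sgz = set(set_sgz)
    shared = [g for g in set_vsvz if g in in_sgz]
    if not shared:
        raise ValueError("no genes pass both contrasts in both niches")
    return SharedSignatureResult(
        shared=GeneSignature(
            name="shared_dormant",
            genes=shared,
            note="enriched in dormant NSCs vs embryonic RPs and vs TAPs/IPs in both niches",
        ),
        per_niche={"V-SVZ": set_vsvz, "SGZ": set_sgz},
        tables=tables,
    )


@dataclass
class OverlapResult:
    """Cross-niche agreement of enriched gene lists, as percentages."""

    pct_up: float
    pct_down: float
    genes_up: list[str] = field(default_factory=list)
    genes_down: list[str] = field(default_factory=list)


def cross_niche_overlap(
    listA_up: Iterable[str],
    listA_down: Iterable[str],
    tableB: pd.DataFrame,
    max_padj: float = 0.05,
) -> OverlapResult:
    """Fraction of one niche's enriched genes replicated in the other niche.

    ``tableB`` must come from the other niche's contrast with the same
    group-1 orientation (e.g., NSCs vs astrocytes in both niches). A gene
    replicates when it is significant in ``tableB`` (p_adj < max_padj,
    strict) with the same fold-change sign.
    """
    listA_up = list(listA_up)
    listA_down = list(listA_down)
    if not listA_up or not listA_down:
        raise ValueError("both input gene lists must be non-empty")

    def _replicated(genes: list[str], sign: int) -> list[str]:
        sub = tableB.reindex(genes).dropna(subset=["p_adj"])
        ok = sub[(sub["p_adj"] < max_padj) & (np.sign(sub["avg_logFC"]) == sign)]
        return list(ok.index)

    up = _replicated(listA_up, +1)
    down = _replicated(listA_down, -1)
    return OverlapResult(
        pct_up=100.0 * len(up) / len(listA_up),
        pct_down=100.0 * len(down) / len(listA_down),
        genes_up=up,
        genes_down=down,
    )
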