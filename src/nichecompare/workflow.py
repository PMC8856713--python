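"""Orchestration of the full cross-niche comparison, plus the CLI.

:func:`run_full_comparison` sequences the pipeline on real or synthetic
inputs — merge, gene filtering, normalization, signature scoring, centroid
correlation, single-cell projection, NSC/astrocyte overlap, shared
dormant-signature derivation and temporal statistics — writing per-stage
TSV tables and a machine-readable JSON summary of the headline quantities.
All randomness flows from the single configured seed, so a repeated run on
the same configuration yields a byte-identical summary.

The CLI (`nichecompare <subcommand>`) is a thin layer over the library:
``simulate``, ``score``, ``correlate``, ``de``, ``signature``,
``temporal`` and ``run``.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import typer
import yaml

from . import count_matrix as cm
from . import correlation as corr
from . import diffexp as de
from . import signatures as sigs
from . import synthetic_data as synth
from . import temporal as temp

__all__ = ["AnalysisConfig", "run_full_comparison", "app", "main"]

log = logging.getLogger("nichecompare")

SUMMARY_SECTIONS = (
    "dataset",
    "preprocessing",
    "signature_scores",
    "centroid_correlations",
    "projection",
    "nsc_astrocyte_overlap",
    "shared_dormant_signature",
    "temporal",
)

_ROLE_KEYS = ("embryonic_rp", "dormant_nsc", "tap_ip", "astrocyte", "nsc_lineage")


@dataclass
class AnalysisConfig:
    """Declarative configuration of a full comparison run.

    Either ``input_dir`` (a dataset directory with matrix.mtx, genes.tsv,
    barcodes.tsv, metadata.tsv) or ``synthetic`` must be set. ``groups``
    maps each niche to role -> group labels (roles: embryonic_rp,
    dormant_nsc, tap_ip, astrocyte, nsc_lineage); it may be omitted for
    synthetic input, where roles derive from the ground truth.
    """

    input_dir: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    groups: dict[str, dict[str, list[str]]] | None = None
    criteria: de.EnrichmentCriteria = field(default_factory=de.EnrichmentCriteria)
    overlay_thresholds: dict[str, float] = field(
        default_factory=lambda: {"core": 0.8, "astrocyte": 0.75, "dormant": 1.5}
    )
    overlap_max_padj: float = 0.05
    min_cells: int = 3
    scale_factor: float = 10_000.0
    gestation_length: float = 19.5
    seed: int = 0
    outdir: str = "nichecompare_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in (
            "input_dir", "groups", "overlay_thresholds", "overlap_max_padj",
            "min_cells", "scale_factor", "gestation_length", "seed", "outdir",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "criteria" in d:
            kwargs["criteria"] = de.EnrichmentCriteria(**d["criteria"])
        if "synthetic" in d and d["synthetic"] is not None:
            syn = dict(d["synthetic"])
            syn.setdefault("seed", d.get("seed", 0))
            if "age_groups" in syn:
                syn["age_groups"] = tuple(
                    synth.AgeGroup(n, l, int(t)) for n, l, t in syn["age_groups"]
                )
            kwargs["synthetic"] = synth.SyntheticConfig(**syn)
        return cls(**kwargs)


def _subset_norm(norm: cm.NormalizedMatrix, mask: np.ndarray) -> cm.NormalizedMatrix:
    cells = [c for c, m in zip(norm.cells, mask) if m]
    return cm.NormalizedMatrix(
        genes=list(norm.genes),
        cells=cells,
        values=norm.values[:, mask],
        scale_factor=norm.scale_factor,
    )


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney rank AUC of positives scoring above negatives."""
    from scipy.stats import rankdata

    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    r1 = ranks[: len(pos)].sum()
    u = r1 - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _derive_groups_from_truth(truth: synth.GroundTruth) -> dict[str, dict[str, list[str]]]:
    cfg = truth.config
    out: dict[str, dict[str, list[str]]] = {}
    for niche in cfg.niches:
        roles = truth.role_groups(niche)
        astro = [
            synth.group_label(niche, a, synth.ASTROCYTE)
            for a in cfg.age_groups
            if a.age_days >= 0
        ]
        lineage = [
            synth.group_label(niche, a, synth.NSC_LINEAGE) for a in cfg.age_groups
        ]
        out[niche] = {**roles, "astrocyte": astro, "nsc_lineage": lineage}
    return out


def _validate_groups(
    groups: Mapping[str, Mapping[str, list[str]]], ann: cm.CellAnnotation
) -> None:
    known = set(ann.table["group"])
    for niche, roles in groups.items():
        for role, labels in roles.items():
            unknown = [l for l in labels if l not in known]
            if unknown:
                raise ValueError(
                    f"config group(s) not present in metadata "
                    f"({niche}/{role}): {unknown}"
                )


def run_full_comparison(config: AnalysisConfig) -> dict:
    """Run the full pipeline and return the summary dict (also written to
    ``<outdir>/summary.json`` along with per-stage TSV tables)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # -- dataset ------------------------------------------------------------
    truth: synth.GroundTruth | None = None
    if config.synthetic is not None:
        syn_cfg = config.synthetic
        mat, ann, truth = synth.generate_dataset(syn_cfg)
        source = f"synthetic(seed={syn_cfg.seed})"
    elif config.input_dir is not None:
        mat, ann = cm.read_counts(
            config.input_dir, format="mtx_10x",
            metadata_path=Path(config.input_dir) / "metadata.tsv",
        )
        source = str(config.input_dir)
    else:
        raise ValueError("config must set input_dir or synthetic")

    groups = config.groups or (
        _derive_groups_from_truth(truth) if truth is not None else None
    )
    if groups is None:
        raise ValueError("group definitions are required for non-synthetic input")
    _validate_groups(groups, ann)  # fail fast before any computation
    niches = list(groups)
    log.info("dataset: %d genes x %d cells from %s", *mat.shape, source)
    summary["dataset"] = {
        "source": source,
        "n_genes": mat.shape[0],
        "n_cells": mat.shape[1],
        "niches": niches,
        "n_groups": int(ann.table["group"].nunique()),
    }

    # -- preprocessing ------------------------------------------------------
    filtered = cm.filter_genes(mat, min_cells=config.min_cells)
    norm = cm.normalize(filtered, scale_factor=config.scale_factor)
    log.info("preprocessing: %d/%d genes retained", filtered.shape[0], mat.shape[0])
    summary["preprocessing"] = {
        "min_cells": config.min_cells,
        "n_genes_retained": filtered.shape[0],
        "scale_factor": config.scale_factor,
    }

    ann_aligned = ann.reindex(norm.cells)
    niche_col = ann_aligned.table["niche"].to_numpy()

    # -- signature scores ---------------------------------------------------
    if truth is not None:
        sig_sets = {
            "core": sigs.GeneSignature("core", truth.programs["core_identity"], "planted"),
            "astrocyte": sigs.GeneSignature("astrocyte", truth.programs["astrocyte"], "planted"),
            "dormant": sigs.GeneSignature("dormant", truth.programs["dormancy"], "planted"),
        }
    else:
        sig_sets = {
            "core": sigs.load_packaged_signature("core_identity_79"),
            "astrocyte": sigs.load_packaged_signature("astrocyte_26"),
            "dormant": sigs.load_packaged_signature("shared_dormant_94"),
        }
    sig_summary: dict = {}
    score_frames = []
    dormant_scores: pd.Series | None = None
    for key, sig in sig_sets.items():
        thr = config.overlay_thresholds.get(key)
        res = sigs.score_signature(norm, sig, threshold=thr)
        frame = res.scores.rename(f"score_{key}")
        score_frames.append(frame)
        if key == "dormant":
            dormant_scores = res.scores
        sig_summary[key] = {
            "n_genes_used": res.n_genes_used,
            "n_missing": len(res.missing_genes),
            "threshold": thr,
            "n_flagged": int(res.flags.sum()) if res.flags is not None else None,
            "mean_score": _round(res.scores.mean()),
        }
    pd.concat(score_frames, axis=1).to_csv(outdir / "signature_scores.tsv", sep="\t")
    if truth is not None and dormant_scores is not None:
        dormant_mask = ann_aligned.group_mask(truth.dormant_nsc_groups())
        auc = _rank_auc(
            dormant_scores.to_numpy()[dormant_mask],
            dormant_scores.to_numpy()[~dormant_mask],
        )
        sig_summary["dormant_score_auc"] = _round(auc)
    summary["signature_scores"] = sig_summary
    log.info("signature scores computed for %d signatures", len(sig_sets))

    # -- centroid correlations ---------------------------------------------
    lineage_labels = [l for n in niches for l in groups[n]["nsc_lineage"]]
    centroids = [corr.group_centroid(norm, ann_aligned, l) for l in lineage_labels]
    cmat = corr.centroid_correlation_matrix(centroids)
    cmat.to_csv(outdir / "centroid_correlations.tsv", sep="\t")
    cent_summary: dict = {}
    if len(niches) == 2:
        emb1 = groups[niches[0]]["embryonic_rp"][0]
        emb2 = groups[niches[1]]["embryonic_rp"][0]
        adult1 = groups[niches[0]]["dormant_nsc"][-1]
        cent_summary["r_embryonic_cross_niche"] = _round(cmat.loc[emb1, emb2])
        cent_summary["r_embryonic_vs_adult_within_niche"] = _round(
            cmat.loc[emb1, adult1]
        )
    cent_summary["n_centroids"] = len(centroids)
    cent_summary["min_r"] = _round(cmat.to_numpy().min())
    summary["centroid_correlations"] = cent_summary
    log.info("centroid correlation matrix: %d x %d", *cmat.shape)

    # -- single-cell projection --------------------------------------------
    nA, nB = niches[0], niches[-1]
    proj = corr.single_cell_projection(
        norm,
        ann_aligned,
        refA1=groups[nA]["dormant_nsc"],
        refA2=groups[nA]["embryonic_rp"],
        refB1=groups[nB]["embryonic_rp"],
        refB2=groups[nB]["dormant_nsc"],
    )
    coords = proj.coords.join(ann_aligned.table[["niche", "group"]])
    coords.to_csv(outdir / "projection.tsv", sep="\t")
    proj_summary = {
        "n_cells": int(len(proj.coords)),
        "n_excluded": len(proj.excluded_cells),
        "references": proj.references,
    }
    emb_labels = [l for n in niches for l in groups[n]["embryonic_rp"]]
    dorm_labels = [l for n in niches for l in groups[n]["dormant_nsc"]]
    in_emb = coords["group"].isin(emb_labels)
    in_dorm = coords["group"].isin(dorm_labels)
    if in_emb.any() and in_dorm.any():
        correct = (coords.loc[in_emb, "x"] < 0).sum() + (coords.loc[in_dorm, "x"] > 0).sum()
        proj_summary["halfplane_accuracy_pct"] = _round(
            100.0 * correct / (in_emb.sum() + in_dorm.sum()), 3
        )
    summary["projection"] = proj_summary
    log.info("projection: %d cells placed", len(proj.coords))

    # -- NSC vs astrocyte overlap ------------------------------------------
    overlap_summary: dict = {}
    if all(groups[n].get("astrocyte") for n in niches[:2]) and len(niches) >= 2:
        tables = {}
        for n in niches[:2]:
            mask = ann_aligned.table["niche"].eq(n).to_numpy()
            sub_norm = _subset_norm(norm, mask)
            sub_ann = ann_aligned.reindex(sub_norm.cells)
            tables[n] = de.wilcoxon_de(
                sub_norm, sub_ann, groups[n]["nsc_lineage"], groups[n]["astrocyte"]
            )
        tA, tB = tables[niches[0]], tables[niches[1]]
        sigA = tA[tA["p_adj"] < config.overlap_max_padj]
        listA_up = list(sigA[sigA["avg_logFC"] > 0].index)
        listA_down = list(sigA[sigA["avg_logFC"] < 0].index)
        tA.to_csv(outdir / f"de_nsc_vs_astro_{niches[0].replace('/', '-')}.tsv", sep="\t")
        tB.to_csv(outdir / f"de_nsc_vs_astro_{niches[1].replace('/', '-')}.tsv", sep="\t")
        overlap_summary = {
            "reference_niche": niches[0],
            "n_nsc_enriched": len(listA_up),
            "n_astro_enriched": len(listA_down),
            "pct_nsc_enriched_replicated": None,
            "pct_astro_enriched_replicated": None,
        }
        if listA_up and listA_down:
            ov = de.cross_niche_overlap(
                listA_up, listA_down, tB, max_padj=config.overlap_max_padj
            )
            overlap_summary["pct_nsc_enriched_replicated"] = _round(ov.pct_up, 3)
            overlap_summary["pct_astro_enriched_replicated"] = _round(ov.pct_down, 3)
            log.info(
                "overlap: %.1f%% NSC-enriched and %.1f%% astro-enriched replicated",
                ov.pct_up, ov.pct_down,
            )
        else:
            log.warning(
                "overlap skipped: no significantly enriched genes in %s", niches[0]
            )
    summary["nsc_astrocyte_overlap"] = overlap_summary

    # -- shared dormant signature ------------------------------------------
    niche_data = {}
    for n in niches[:2]:
        mask = ann_aligned.table["niche"].eq(n).to_numpy()
        sub_norm = _subset_norm(norm, mask)
        niche_data[n] = (sub_norm, ann_aligned.reindex(sub_norm.cells))
    (nv, av), (ns_, as_) = niche_data[niches[0]], niche_data[niches[1]]
    shared = de.shared_dormant_signature(
        nv, av, ns_, as_,
        crit=config.criteria,
        groups_vsvz={k: groups[niches[0]][k] for k in ("embryonic_rp", "dormant_nsc", "tap_ip")},
        groups_sgz={k: groups[niches[1]][k] for k in ("embryonic_rp", "dormant_nsc", "tap_ip")},
    )
    sigs.write_gmt(
        [shared.shared,
         sigs.GeneSignature(f"dormant_{niches[0]}", shared.per_niche[niches[0]]),
         sigs.GeneSignature(f"dormant_{niches[1]}", shared.per_niche[niches[1]])],
        outdir / "shared_dormant_signature.gmt",
    )
    shared_summary = {
        "n_shared": len(shared.shared),
        "n_per_niche": {n: len(g) for n, g in shared.per_niche.items()},
        "min_logFC": config.criteria.min_logFC,
        "max_padj": config.criteria.max_padj,
    }
    if truth is not None:
        planted = set(truth.programs["dormancy"])
        called = set(shared.shared.genes)
        tp = len(called & planted)
        shared_summary["sensitivity"] = _round(tp / len(planted))
        shared_summary["precision"] = _round(tp / len(called)) if called else 0.0
    summary["shared_dormant_signature"] = shared_summary
    log.info("shared dormant signature: %d genes", len(shared.shared))

    # -- temporal -----------------------------------------------------------
    n_temp = niches[-1]
    mask = ann_aligned.table["group"].isin(groups[n_temp]["nsc_lineage"]).to_numpy()
    sub_norm = _subset_norm(norm, mask)
    sub_ann = ann_aligned.reindex(sub_norm.cells)
    rho_table = temp.spearman_with_time(
        sub_norm, sub_ann, age_map=temp.AgeMap(config.gestation_length)
    )
    rho_table.to_csv(outdir / "temporal_rho.tsv", sep="\t")
    temp.export_preranked(rho_table, outdir / "temporal_preranked.rnk")
    quiescence_set = (
        truth.programs["dormancy"] if truth is not None else sig_sets["dormant"].genes
    )
    shift = temp.gene_set_shift_test(rho_table, quiescence_set)
    shift.to_json(outdir / "temporal_shift_test.json")
    summary["temporal"] = {
        "niche": n_temp,
        "n_cells": int(rho_table.attrs["n_cells"]),
        "n_defined": int(rho_table["defined"].sum()),
        "shift_test_p": float(f"{shift.p_value:.6g}"),
        "median_shift": _round(shift.median_shift),
        "direction": shift.direction,
    }
    log.info("temporal: shift-test p = %.3g", shift.p_value)

    assert set(summary) == set(SUMMARY_SECTIONS)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log.info("run complete in %.1f s; summary at %s", time.time() - t0, outdir / "summary.json")
    return summary


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

app = typer.Typer(
    name="nichecompare",
    help="Cross-niche comparison of V-SVZ and SGZ NSC single-cell transcriptomes.",
    add_completion=False,
)


def _setup_logging() -> None:
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO, format="[%(name)s %(levelname)s] %(message)s"
    )


def _load_dataset(data: Path) -> tuple[cm.CountMatrix, cm.CellAnnotation]:
    return cm.read_counts(data, format="mtx_10x", metadata_path=data / "metadata.tsv")


def _normalized(data: Path) -> tuple[cm.NormalizedMatrix, cm.CellAnnotation]:
    mat, ann = _load_dataset(data)
    norm = cm.normalize(cm.filter_genes(mat))
    return norm, ann.reindex(norm.cells)


@app.command()
def simulate(
    config: Optional[Path] = typer.Option(None, help="SyntheticConfig YAML (defaults used if omitted)"),
    out: Path = typer.Option(..., help="Output dataset directory"),
    seed: Optional[int] = typer.Option(None, help="Override the config seed"),
) -> None:
    """Generate a synthetic two-niche dataset (MTX + metadata + truth)."""
    _setup_logging()
    cfg = synth.SyntheticConfig.from_yaml(config) if config else synth.SyntheticConfig()
    if seed is not None:
        cfg.seed = seed
    mat, ann, truth = synth.generate_dataset(cfg)
    synth.write_dataset(mat, ann, truth, out)
    log.info("wrote %d genes x %d cells to %s", *mat.shape, out)


@app.command()
def score(
    data: Path = typer.Option(..., help="Dataset directory"),
    signature: str = typer.Option(..., help="Packaged signature name or GMT path"),
    out: Path = typer.Option(..., help="Output TSV (cell, score, flag)"),
    threshold: Optional[float] = typer.Option(None, help="Overlay threshold (strict >)"),
) -> None:
    """Score a gene signature on every cell."""
    _setup_logging()
    norm, _ = _normalized(data)
    if signature in sigs.PACKAGED_SIGNATURES:
        sig = sigs.load_packaged_signature(signature)
        if threshold is None:
            threshold = sigs.DEFAULT_THRESHOLDS[signature]
    else:
        candidates = {s.name: s for s in sigs.read_gmt(signature)}
        if len(candidates) != 1:
            raise typer.BadParameter("GMT must contain exactly one signature")
        (sig,) = candidates.values()
    res = sigs.score_signature(norm, sig, threshold=threshold)
    frame = res.scores.to_frame("score")
    if res.flags is not None:
        frame["flag"] = res.flags
    frame.to_csv(out, sep="\t")
    log.info("scored %d cells with %s (%d genes)", len(frame), sig.name, res.n_genes_used)


@app.command()
def correlate(
    data: Path = typer.Option(..., help="Dataset directory"),
    groups: str = typer.Option(..., help="Comma-separated group labels"),
    out: Path = typer.Option(..., help="Output TSV correlation matrix"),
) -> None:
    """Pearson correlation heatmap matrix between group centroids."""
    _setup_logging()
    norm, ann = _normalized(data)
    labels = [g.strip() for g in groups.split(",") if g.strip()]
    cents = [corr.group_centroid(norm, ann, l) for l in labels]
    corr.centroid_correlation_matrix(cents).to_csv(out, sep="\t")
    log.info("wrote %d x %d correlation matrix", len(cents), len(cents))


@app.command("de")
def de_command(
    data: Path = typer.Option(..., help="Dataset directory"),
    group1: str = typer.Option(..., help="Comma-separated group-1 labels"),
    group2: str = typer.Option(..., help="Comma-separated group-2 labels"),
    out: Path = typer.Option(..., help="Output TSV DE table"),
) -> None:
    """Wilcoxon differential expression between two cell groups."""
    _setup_logging()
    norm, ann = _normalized(data)
    g1 = [g.strip() for g in group1.split(",") if g.strip()]
    g2 = [g.strip() for g in group2.split(",") if g.strip()]
    table = de.wilcoxon_de(norm, ann, g1, g2)
    table.to_csv(out, sep="\t")
    log.info("tested %d genes", len(table))


@app.command("signature")
def signature_command(
    config: Path = typer.Option(..., help="AnalysisConfig YAML with group roles"),
    out: Path = typer.Option(..., help="Output GMT for the derived signatures"),
) -> None:
    """Derive the cross-niche shared dormant NSC signature."""
    _setup_logging()
    acfg = AnalysisConfig.from_yaml(config)
    acfg.outdir = str(out.parent if out.parent != Path("") else Path("."))
    summary = run_full_comparison(acfg)
    src = Path(acfg.outdir) / "shared_dormant_signature.gmt"
    if src != out:
        out.write_text(src.read_text())
    log.info("shared signature: %d genes", summary["shared_dormant_signature"]["n_shared"])


@app.command()
def temporal(
    data: Path = typer.Option(..., help="Dataset directory"),
    groups: str = typer.Option(..., help="Comma-separated NSC-lineage group labels"),
    out: Path = typer.Option(..., help="Output directory (rho TSV + .rnk)"),
    gene_set: Optional[Path] = typer.Option(None, help="Gene list for the shift test"),
) -> None:
    """Per-gene Spearman correlation with age, preranked export, shift test."""
    _setup_logging()
    norm, ann = _normalized(data)
    labels = [g.strip() for g in groups.split(",") if g.strip()]
    mask = ann.table["group"].isin(labels).to_numpy()
    sub = _subset_norm(norm, mask)
    table = temp.spearman_with_time(sub, ann.reindex(sub.cells))
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "temporal_rho.tsv", sep="\t")
    temp.export_preranked(table, out / "temporal_preranked.rnk")
    if gene_set is not None:
        res = temp.gene_set_shift_test(table, cm.read_gene_list(gene_set))
        res.to_json(out / "shift_test.json")
        log.info("shift test p = %.3g", res.p_value)


@app.command()
def run(
    config: Path = typer.Option(..., help="AnalysisConfig YAML"),
    out: Optional[Path] = typer.Option(None, help="Override output directory"),
    seed: Optional[int] = typer.Option(None, help="Override seed"),
) -> None:
    """Run the full cross-niche comparison and write the summary JSON."""
    _setup_logging()
    acfg = AnalysisConfig.from_yaml(config)
    if out is not None:
        acfg.outdir = str(out)
    if seed is not None:
        acfg.seed = seed
        if acfg.synthetic is not None:
            acfg.synthetic.seed = seed
    run_full_comparison(acfg)


def main() -> None:  # console-script entry point
    app()


if __name__ == "__main__":
    main()
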