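# nichecompare

Tools for comparing the transcriptomes of neural stem cells (NSCs) from the
two adult neurogenic niches of the mouse brain — the ventricular–
subventricular zone (V-SVZ) of the lateral ventricles and the subgranular
zone (SGZ) of the hippocampal dentate gyrus — across development, from
embryonic radial glial precursors (RPs) to dormant adult NSCs.

The package is aimed at analysts who want to reproduce or extend this style
of cross-niche single-cell RNA-seq comparison with a tested, scriptable
pipeline rather than an interactive notebook. Every stage is verifiable
against a built-in synthetic-data generator that plants known gene programs
into negative-binomial counts, so the statistical machinery can be checked
end to end without access to the original datasets.

## What it computes

Given gene × cell count matrices (10x-style MTX triplets or delimited
tables) and per-cell metadata (niche, age, cell-type group, batch):

* **Preprocessing** — union merging of datasets (genes absent from one
  source are zero-filled, count mass conserved), removal of genes detected
  in fewer than 3 cells, library-size normalization
  `v(g,c) = ln(1 + n(g,c)/N(c) · 10⁴)`, binned-dispersion HVG selection
  with optional gene-set (e.g. cell-cycle) exclusion, and PCA.
* **Signature scores** — per-cell mean normalized expression over a gene
  list, with strict threshold overlays and per-group score densities. The
  three published signatures ship as package data: the 79-gene RP/NSC core
  identity, the 26-gene niche-astrocyte signature and the 94-gene shared
  adult dormant NSC signature.
* **Correlation analyses** — Pearson correlation heatmaps between group
  centroids (per-gene mean profiles), and a 2-D single-cell projection
  where `x = r(cell, A₁) − r(cell, A₂)` and `y = r(cell, B₁) − r(cell, B₂)`
  against four reference centroids (adult dormant NSCs vs embryonic RPs of
  each niche). Values are deliberately not batch-corrected.
* **Differential expression** — two-sided Wilcoxon rank-sum per gene
  (exact enumeration for group sizes ≤ 8, tie-corrected normal
  approximation otherwise), natural-log fold changes on de-logged means
  with pseudocount 1, Bonferroni FWER over the genes tested, detection
  fractions; enrichment filtering (avg logFC > 0.5, adjusted p < 0.05,
  both strict); the dual-contrast, cross-niche shared dormant-signature
  derivation; and cross-niche overlap percentages for NSC-vs-astrocyte
  contrasts.
* **Temporal statistics** — per-gene Spearman correlation of expression
  with age in days (birth = 0, `E<x> → round(x − 19.5)`), a one-sided
  Wilcoxon shift test for whether a gene set (e.g. a quiescence program) is
  more correlated with time than the background, and GSEA-preranked `.rnk`
  export.
* **Synthetic data** — a two-niche, five-age design (E14.5 → P60) with
  NSC-lineage, astrocyte and TAP/IP populations and planted programs (core
  identity, astrocyte, age-ramped dormancy, niche markers, proneurogenic
  GABAergic/glutamatergic cohorts, cell cycle) with ground truth for
  parameter-recovery testing.

## Worked example

```python
from nichecompare import AnalysisConfig, SyntheticConfig, run_full_comparison

summary = run_full_comparison(
    AnalysisConfig(synthetic=SyntheticConfig(seed=1), outdir="out")
)
print(summary["shared_dormant_signature"])
print(summary["centroid_correlations"])
```

prints (abridged):

```
{'n_shared': 50, 'n_per_niche': {'V-SVZ': 50, 'SGZ': 50},
 'min_logFC': 0.5, 'max_padj': 0.05, 'sensitivity': 1.0, 'precision': 1.0}
{'r_embryonic_cross_niche': 0.952734, 'r_embryonic_vs_adult_within_niche':
 0.931721, 'n_centroids': 10, 'min_r': 0.884029}
```

All 50 planted dormancy genes — genes enriched in juvenile/adult dormant
NSCs relative to *both* embryonic RPs and adult TAPs/IPs, in *both* niches —
were recovered with no false calls, and embryonic RPs of the two niches
correlate more strongly with each other (r = 0.953) than embryonic
correlates with adult within a niche (r = 0.932), the qualitative ordering
this comparison is designed to expose. `out/summary.json` holds the full
report and the per-stage TSV/GMT tables sit alongside it.

The same pipeline runs from the shell:

```sh
nichecompare simulate --out data/            # synthetic dataset (MTX + metadata)
nichecompare run --config analysis.yaml      # full comparison -> summary.json
nichecompare de --data data/ --group1 "SGZ P60 NSC" --group2 "SGZ E14.5 RP" --out de.tsv
```

For real datasets, point `AnalysisConfig.input_dir` at an MTX directory
with a `metadata.tsv` (columns `cell, niche, age_label, group, batch`) and
declare which metadata groups play each role (embryonic RPs, dormant NSCs,
TAPs/IPs, astrocytes) per niche.

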