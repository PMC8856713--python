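# Methods

This note documents the statistical procedures implemented in
`nichecompare`, the choices made where a convention had to be fixed, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Preprocessing

Counts are stored genes × cells in sparse form. Datasets are merged on the
**union** of their gene sets; a gene absent from one source is zero in that
source's cells, so total count mass is conserved exactly and the merge is
associative up to row/column order. Genes detected (count > 0) in fewer
than `min_cells = 3` cells are removed; "detected" is strictly positive,
with no expression-level threshold.

Normalization is counts-per-scale-factor followed by natural log1p:
`v(g,c) = ln(1 + n(g,c)/N(c) · s)` with `s = 10⁴` by default. The identity
`Σ_g (e^{v(g,c)} − 1) = s` holds for every cell to relative 1e-6 and is
asserted in the tests. Cells with zero total are rejected by name rather
than silently dropped, so data loss is always explicit.

Highly variable genes are ranked by the dispersion (variance/mean) of the
normalized values, z-scored within 20 quantile bins of the gene mean so
that expression level does not dominate the ranking; constant genes are
never selected. The bin count, the number of HVGs (default 2000) and the
number of principal components (default 30) are configuration, since no
single convention is canonical. PCA centers per gene and uses a full SVD
(scikit-learn); components are orthonormal and explained variances
non-increasing.

A gene-set exclusion step (order-preserving set difference) supports
cell-cycle regression by removing a user-supplied cell-cycle list from the
HVGs before embedding. The 678-gene cell-cycle list and the 49-gene
quiescence set used in the original analyses are not printed in any source
table, so they are user inputs; the synthetic generator's planted programs
stand in for them in tests.

## Signature scoring

A cell's score for a gene signature is the arithmetic mean of its
normalized expression over the signature genes present in the matrix;
zeros contribute to the mean, and genes absent from the matrix are dropped
and counted. Scores are therefore on the same natural-log scale as the
normalized values. Overlay flags use a strict inequality (`score >
threshold`); the packaged defaults mirror the figure conventions of the
source study (0.8 core identity, 0.75 astrocyte, 1.5 dormant). Score
densities per group use a Gaussian kernel with Scott's bandwidth and are
presentation artifacts only — no test asserts on a density value.

The three packaged signatures are taken verbatim from the study's printed
tables: the 79-gene embryonic-cortical-RP/V-SVZ-NSC core identity (the 63
enriched genes of its first table plus the 16 companion genes listed in
the text), the 26-gene astrocyte signature, and the 94-gene shared adult
dormant NSC signature. Gene symbols are kept exactly as printed and are
matched case-sensitively.

## Correlation analyses

A group centroid is the per-gene mean of normalized expression over the
group's cells, always on the full merged gene universe. Centroid-centroid
and cell-centroid correlations are plain Pearson; the implementation is
checked against a textbook-formula oracle to 1e-12. The single-cell
projection assigns each cell `x = r(cell, A₁) − r(cell, A₂)` and
`y = r(cell, B₁) − r(cell, B₂)` for two pairs of reference centroids, so
coordinates live in [−2, 2]; swapping a pair negates the corresponding
coordinate exactly, and positive affine transforms of a cell's profile
leave its coordinates unchanged (Pearson invariance). Cells belonging to
reference groups are themselves projected. Constant cell profiles have no
defined correlation; they are excluded and reported. No batch correction
is applied anywhere in this module, matching the uncorrected correlation
analyses it reproduces; log-normalized values are used for both centroids
and cells for internal consistency.

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum test on normalized values. For
group sizes ≤ 8 on both sides the p-value is exact, by full enumeration of
all C(n₁+n₂, n₁) rank assignments with midranks for ties (two-sided =
twice the smaller tail, capped at 1); larger groups use the tie-corrected
normal approximation with continuity correction. The crossover at 8 trades
exactness at test scale for speed at data scale; genes with identical
values in every cell get p = 1 by construction. The fold change is
`ln(mean(e^v − 1) + 1)` difference between groups — natural log on
de-logged means with pseudocount 1 — which is antisymmetric under group
swap. Bonferroni multiplicity is the number of genes actually tested in
that contrast, i.e. genes expressed in at least one cell of the two groups;
no detection prefilter is applied by default (a `min_pct` option exists).

Enrichment filtering keeps genes with avg logFC strictly above 0.5 and
adjusted p strictly below 0.05. The shared dormant signature requires a
gene to pass that filter in two contrasts per niche — dormant NSCs vs
embryonic RPs and dormant NSCs vs TAPs/IPs — and then intersects the two
per-niche sets; the construction is symmetric in the niche order. The
cross-niche overlap statistic reports the percentage of one niche's
significantly enriched genes (per direction) that are significant with the
same fold-change sign in the other niche's table; no fold-change magnitude
threshold is applied there, only significance and direction.

The selection of the 26 "most specific" astrocyte genes was a manual
curation step in the original work; the package takes the printed list as
input and does not try to re-derive it.

## Temporal statistics

Ages map to integer days with birth at zero: `P<n> → n` and
`E<x> → round(x − g)` with mouse gestation `g = 19.5` d (banker's
rounding). Spearman's rho per gene uses average ranks for ties and is
checked against a rank-then-Pearson oracle to 1e-12. Because rho depends
only on the ordering of ages, the embryonic mapping (and hence the choice
of `g`) cannot change any coefficient for a fixed age set — this is
asserted by computing with two different gestation lengths. Constant genes
are flagged undefined and excluded from all downstream use.

The gene-set shift test asks whether a set's rhos are larger than those of
all other defined genes (one-sided Wilcoxon rank-sum, "greater"; two-sided
available), reporting the p-value and the median shift. The ranking can be
exported as a `.rnk` file (gene, rho; decreasing) for external enrichment
tools — enrichment-score computation itself is out of scope here.

## Synthetic data

The generator emulates the *statistical structure* the analyses assume,
not any real dataset's parameters. Design: two niches × five age groups
(E14.5 → P60, age_days −5, 0, 6, 20, 60) × cell types (NSC lineage at all
ages, astrocytes from birth, TAPs/IPs at juvenile/adult), 200 cells per
group and 2000 genes by default. Gene means are
`base · exp(Σ program effects + batch) · library`, with NB sampling at
gene-shared dispersion 0.1 (`var = μ + 0.1 μ²`, gamma–Poisson). Planted
programs and effects (1.0 ln-units each by default):

| program | size | active in |
| --- | --- | --- |
| core identity | 79 | NSC lineage (astrocytes at half effect) |
| astrocyte | 26 | astrocytes |
| dormancy | 50 | NSC lineage, ramping linearly with age_days from 0 (embryonic) to max (adult); absent in TAPs/IPs |
| pallial / subpallial | 30 + 30 | all SGZ / all V-SVZ cells |
| proneurogenic GABA / glut | 20 + 20 | embryonic/perinatal precursors and TAPs/IPs of V-SVZ / SGZ; silent in dormant NSCs |
| cell cycle | 100 | proliferative stages (embryonic/perinatal precursors, TAPs/IPs) |

Program genes draw baseline means from a moderately expressed lognormal
(ln-mean 0.5, ln-sd 0.5) — curated marker genes are detectably expressed —
while background genes use a broader, lower distribution (ln-mean −1,
ln-sd 1). Batch effects are per-niche gene-wise lognormal factors with
ln-sd 0.1, chosen so that uncorrected cross-dataset centroid correlations
sit near the ~0.94 the real comparison reports and the age signal dominates
the batch signal, as observed there; per-cell library factors are
lognormal with ln-sd 0.3. All sampling derives from a single seed and is
bit-reproducible.

What this does **not** emulate: dropout beyond what NB sampling implies,
ambient RNA, doublets, cluster-free continuous heterogeneity within
groups, realistic gene–gene correlation structure, or the real datasets'
cell counts and depth profiles. Passing parameter-recovery tests on this
generator therefore demonstrates the correctness and calibration of the
statistical machinery under its assumed model, not performance on real
data, where batch structure and annotation noise are harsher.

## Orchestration and problem sizes

`run_full_comparison` validates that every configured group label exists
in the metadata before any computation, then runs merge → filter →
normalize → scoring → centroid heatmap → projection → NSC/astrocyte
overlap → shared-signature derivation → temporal statistics, writing one
TSV/GMT per stage and a sorted-key JSON summary; repeated runs with the
same configuration are byte-identical. The test suite exercises most
modules on a reduced design (600 genes, 40 cells/group) and the
full-power checks (parameter recovery, FWER null, score separation,
projection geometry) on the default design above; `scripts/acceptance.py`
re-runs the default design plus a 2000-gene null simulation, which
completes in well under a minute of compute.

## Known limitations

* Wilcoxon p-values for large groups use the normal approximation; exact
  enumeration is only applied up to n = 8 per group.
* Bonferroni FWER is the only multiplicity correction offered, matching
  the procedure reproduced here; no FDR option is provided for DE.
* Harmony-style batch correction, UMAP/clustering, trajectory inference
  and enrichment-score computation are intentionally out of scope; the
  package produces the inputs those external tools consume.
* Real-data headline values (e.g. centroid r = 0.94, 64 %/56 % overlaps,
  the 105/94-gene signature sizes) depend on the original deposited
  datasets and are reproducible only by running the pipeline on them with
  the group definitions described in the configuration documentation.
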