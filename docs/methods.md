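# Methods

`microsig` implements a complete pipeline for deriving a tissue-resident
macrophage (microglial) core transcriptomic signature from bulk RNA-seq
count data, characterizing its regional heterogeneity through
co-expression networks, and comparing signatures across species on
rank-normalized expression. This note documents the models, the parameter
choices and their rationale, the synthetic-data generator that stands in
for deposited sequencing data, and the package's known limitations.

## Differential expression model

Counts are modelled through the precision-weighted limma/voom approach:

1. **Transform.** `y_gs = log2((c_gs + 0.5) / (L_s·f_s + 1) · 1e6)` where
   `c_gs` is the count, `L_s` the library size (column sum) and `f_s` the
   TMM normalization factor. The half-count offset keeps zeros finite; the
   `+1` on the library guards the degenerate one-read library.
2. **Mean–variance trend.** A gene-wise group-means fit yields residual
   standard deviations `σ_g`; `sqrt(σ_g)` is smoothed against average
   log2-count by lowess with span 0.5. The fitted trend is floored at its
   smallest positive value so genes with zero residual spread (duplicate
   samples) still receive finite weights. Each observation's weight is
   `trend(fitted log2-count)^-4`.
3. **Weighted least squares.** Gene-wise WLS on a group-means design; the
   contrast coefficient is the log2 fold change with the convention that a
   positive value means higher expression in the first-named group.
4. **Empirical-Bayes moderation.** Residual variances are shrunk toward a
   scaled-F prior fitted by moment matching on `log s²`: the excess spread
   of `log s²` beyond chi-square sampling noise determines the prior
   degrees of freedom `d0` through the trigamma equation (solved by Newton
   iteration), and the prior variance through the digamma equation. When
   the observed spread does not exceed sampling noise the prior is
   infinite and every posterior variance equals the mean variance — this
   happens routinely for very small gene sets and is the correct limit,
   not an error. Moderated t statistics use `d_g + d0` degrees of freedom.
5. **Multiplicity.** Benjamini–Hochberg step-up within each contrast
   separately; contrasts are reported individually, never pooled.

The whole chain was cross-checked against the Bioconductor reference
implementations: TMM factors agree with edgeR `calcNormFactors` to
machine precision, and moderated t statistics agree with
limma `voom`/`eBayes` to ~1e-3 (residual differences trace to the lowess
smoother implementations). The test suite keeps a dual-route check against
edgeR where an R interpreter is available, plus pure-Python brute-force
oracles that run everywhere.

### TMM details

The reference sample is the one whose upper-quartile library-scaled count
is closest to the mean upper quartile. For each sample, genes with a zero
count in either the sample or the reference are excluded pairwise; the
log-ratios M are trimmed two-sided by rank at 30%, the log-abundances A at
5%; the factor is the precision-weighted mean of the surviving M values
with weights from the delta-method binomial variance, then factors are
centred to geometric mean 1. Factors below `1e-6` in absolute log are
snapped to zero, matching common practice.

## Signature derivation

Thresholds (all strict inequalities, bundled in `Params`):

| parameter | default | role |
|---|---|---|
| `min_cpm` | 10 | expression filter: CPM above this in **every** sample of at least one subgroup |
| `alpha_de` | 0.01 | BH-adjusted significance for every contrast |
| `fc_vs_tissue` | 4 | fold-change gate, microglia vs. whole tissue |
| `fc_vs_macrophage` | 3 | fold-change gate, microglia vs. alveolar macrophage |
| `atlas_expr_thresh` | 2 FPKM | reference-atlas expression gate |
| `atlas_fold_thresh` | 4 | required microglia/other-cell fold in the atlas |
| `regional_contam` | 2 FPKM | regional contamination filter |

The core signature is the intersection of the two upregulated sets,
refined by **atlas exclusion**: a gene is removed iff for some species and
some non-microglial cell type (astrocyte, neuron, oligodendrocyte,
endothelial) the atlas shows more than `atlas_expr_thresh` FPKM *and*
microglia are less than `atlas_fold_thresh`-fold higher. Both conditions
are evaluated per cell type within a species — the conjunction reading of
the rule; a `strict_max` flag instead tests against the maximum
non-microglial value. Genes absent from the atlas cannot be assessed and
are kept. Every filter records its removals (with the triggering atlas
cell) in the signature's provenance, and replaying the recorded steps from
the recorded inputs reproduces the member list exactly — a property the
test suite asserts.

The macrophage counter-signature removes genes appearing in any
non-macrophage immune marker set (supplied as GMT) and then
immunoglobulin-related genes. When no explicit immunoglobulin list is
given, a symbol-prefix heuristic (IGH/IGK/IGL/JCHAIN) is applied and
labelled as such in the provenance; it is a heuristic, not a curated list.

**Regional variation** runs the three pairwise regional contrasts at
`alpha_de` with *no* fold-change gate; the variant set is the union of
genes significant in at least one contrast (per-contrast BH, no omnibus
test — this matches reporting by pairwise comparison). Region means for
the top-region ranking are computed on untransformed FPKM; the log2 scale
is used only inside model fitting.

## Networks and clustering

* **Gene–gene graph:** Pearson `r >= 0.84` between genes with >= 1 FPKM in
  at least one sample; connected components smaller than 10 dropped.
  Zero-variance genes are excluded with a warning since their correlation
  is undefined.
* **MCL:** the flow matrix starts from edge weights with self-loops set to
  each node's maximum incident weight, column-normalized; iterations
  alternate expansion (matrix square) and inflation (elementwise power
  1.8, renormalize) with pruning of entries below `1e-5`, until the
  maximum entry change falls below `1e-8` or 100 iterations. Clusters are
  connected components of the converged flow's support; non-convergence
  returns the current interpretation flagged in the clustering metadata.
  The self-loop rule, pruning threshold, tolerance and tie-breaking are
  implementation choices (exposed as arguments) made to follow common MCL
  practice; cluster ids are contiguous from 1 in descending size order
  with lexical tie-break so outputs diff cleanly.
* **Sample graphs:** regional analysis uses log2(FPKM+1) and `r > 0.94`
  with no neighbour restriction; the cross-species analysis uses RANK01
  values, `r > 0.35` and k-nearest-neighbour 6. The knn rule is the union
  convention — an edge survives if either endpoint nominates the other —
  because union preserves connectivity; a `mutual` flag gives the stricter
  variant.
* **k-means:** scikit-learn, k-means++ initialization, 25 restarts, an
  explicit mandatory seed recorded in the output metadata.
* **ORA:** hypergeometric upper tail with gates overlap >= 3, p < 0.01 and
  fold enrichment >= 1.5 (BH-adjusted p also reported). The same routine
  with `p < 1e-5` and overlap >= 10 serves the stricter annotation-style
  enrichment setting.

## Cross-species comparison

Each species' FPKM matrix is collapsed onto human gene keys by summing the
FPKM of all species genes mapping to the same human gene; genes without a
human match are dropped (and counted). Analysis is restricted to human
genes present in **all** species, and rank-minmax normalization is applied
per sample *after* that restriction, so ranks are computed on the
comparable gene set (a flag allows normalizing first for sensitivity
analysis). Ranks are ascending with average ranks at ties, rescaled so
the observed minimum rank maps to 0 and the maximum to 1; a constant
column carries no ordering information and maps to 0.5 — conventions
chosen for permutation symmetry.

Species relatedness is the Pearson correlation of the two species' mean
rank profiles over genes with mean normalized expression above 0.5 in
*both* species; mean-profile correlation (rather than averaging
sample-level correlations) was chosen as the cleaner population-level
summary, with the per-sample matrix available for the alternative.
Conservation clustering runs k-means (k = 5) on the signature genes' RANK01
rows; a cluster is flagged *conserved* when its minimum per-species mean
expression is >= 0.5 — a quantification of "expressed in all species" that
is deliberately exposed as a parameter since it is a judgement call.

## Synthetic data generator

The count simulator emulates the target study design: 31 samples — 3
alveolar macrophages, 8 microglia from each of cerebellum, frontal cortex
and hippocampus, 4 whole-tissue hippocampus samples — over 12,000 genes by
default. Counts are negative binomial via gamma–Poisson mixing with
mean `L_s·q_gs`, where relative abundances `q` renormalize per sample
after planted log2 shifts, and gene dispersion follows the standard bulk
RNA-seq trend `φ_g = (a/μ_g + b)·e_g` (defaults a=3, b=0.05, lognormal
noise sd 0.25). Library sizes are lognormal around 5e6. Planted classes:

* **core** (250): +3 log2 in all microglia — enriched against both
  comparators, atlas-clean; the 8-fold effect puts them clearly above the
  FC gates.
* **contaminated** (200): identical count profile to core but with an
  atlas profile violating the exclusion rule (non-microglial FPKM 20,
  microglial 0.5), so they must be caught by the atlas filter, not by DE.
* **tissue_shared** (150): elevated in microglia *and* tissue — enriched
  vs. macrophage only, so the intersection must exclude them.
* **macrophage** (200): +3 log2 in macrophages.
* **regional** (150): log2 shifts cycling through 1.2/1.6/2.0 in one
  region (region weights 0.55/0.35/0.10 toward cerebellum), with 30% of
  the shift leaking into the rostro-caudally adjacent region so that
  hippocampus is intermediate and cerebellum most distinct. The 2.3–4-fold
  effects deliberately sit near the detection boundary at n = 8.

Planted-gene baselines are drawn higher (truncated normal, log2 mean 5)
so planted genes survive the CPM filter; the per-sample renormalization of
`q` introduces a realistic composition effect (a raw CPM ratio of a
planted 8-fold gene is compressed to ~5.5×), which is exactly the
distortion TMM normalization corrects — tests of the planted fold change
therefore measure TMM-normalized ratios.

The multi-species simulator draws a shared latent log2 expression per
human gene with per-species deviations; conserved signature genes get a
high shared level and small deviations, species-specific genes a +5 log2
boost in their home species and −4 elsewhere, and 10% of human genes are
represented by two species genes that split the FPKM (exercising the
orthologue-summing rule), plus 5% orphan species genes with no human
match.

What the generator does **not** emulate: batch effects, GC/length bias,
isoform switching, correlated gene–gene noise outside the planted classes,
outlier samples, and real orthology complexity (paralog families,
one-to-many human-to-species maps). Passing recovery tests therefore
demonstrates the pipeline's logic and statistical calibration under its
stated noise model, not robustness to every artefact of real data.

All simulators are pure functions of (config, seed) and bit-reproducible.

## Numerical choices and degenerate inputs

* Trigamma inversion by Newton iteration with the standard asymptotic
  start (`0.5 + 1/y`), 50-iteration cap, relative tolerance 1e-10.
* Residual variances of exactly zero are excluded from moment matching
  but still moderated toward the prior.
* Correlation of constant columns is undefined: zero-variance genes are
  excluded from gene graphs with a warning; constant samples produce no
  edges in sample graphs.
* Problem sizes in the test and acceptance suites (2,000–12,000 genes,
  50 null replicates, 10–20 structural seeds) were chosen as the smallest
  sizes at which the statistical assertions are stable.

## Limitations

* FPKM uses the merged exonic length supplied in the annotation;
  transcript-assembly-derived effective lengths are not reproduced.
* The pipeline starts from count/FPKM matrices; read processing,
  alignment and quantification are out of scope.
* The expression filter defaults to raw library sizes (a flag applies TMM
  factors), since which variant the upstream convention used is ambiguous.
* Curated annotation content (GO term databases, brain reference atlases,
  immune marker compendia) is consumed as user-supplied files, never
  bundled.
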