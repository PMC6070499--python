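# Methods

This note documents the models and procedures implemented in `ctcdetect`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## The dual-pass design

The package treats one droplet scRNA-seq sample of CD45-depleted blood as
potentially containing 0–3 circulating tumor cells (CTCs) among ~10³–10⁴
blood cells. Because a single rare cell contributes almost nothing to any
population-level statistic, the analysis runs twice:

* the **outlier pass** maximizes sensitivity to single cells: every gene is
  kept regardless of how few cells express it, per-gene scaling is left
  uncapped, and variable-gene selection imposes no lower bound on mean
  expression;
* the **robust pass** is the conventional parameterization (genes in ≥ 5
  cells, scaled values capped at ±10) used to cluster the abundant blood
  populations, with the outlier pass's calls written back in as a
  supervised "CTC" label.

The two passes are independent: gene filtering for the robust pass never
changes what the outlier pass computes (this is a tested property).

## Preprocessing

**Log-normalization.** `y = ln(1 + s·x/N)` with scale factor `s = 10⁴`
(configurable). All-zero cells map to all-zero columns.

**Covariate regression.** Each gene's log expression is regressed by OLS on
an intercept, total UMIs and mitochondrial fraction, and the *pure
residuals* are used downstream (the intercept is not re-added — the next
step re-centers per gene anyway). The fit is a single vectorized
least-squares solve over all genes; zero-variance covariates are dropped
with a warning. Mitochondrial fraction is stored as a fraction in [0, 1],
never as a percent.

**Scaling.** Per-gene centering to mean 0 and division by the SD (ddof=1);
`cap=None` for the outlier pass, `cap=10` for the robust pass.
Zero-variance genes become all-zero rows. Uncapped scaling is the load-
bearing choice: a gene expressed by k of n cells reaches z ≈ √(n/k) in the
expressing cells (≈ 41 for 3 of 5,000), which is what makes a rare cell's
program dominate a principal component.

**HVG selection.** Dispersion = variance/mean of the de-logged expression
(`expm1` of the log-normalized values, unbiased variance). Genes with any
expression are split into 30 equal-frequency bins of mean log expression
(ties broken by gene order, so selection is deterministic), dispersion is
z-standardized within each bin (z = 0 for singleton or zero-spread bins),
and a gene is selected when z ≥ 1 (configurable) and, if a lower mean bound
is supplied, its mean passes it. The outlier pass uses no lower bound: the
entire program of a cell present at 2–3 copies per 5,000 has mean log
expression ≈ 10⁻³–10⁻², below any conventional bound. The benchmark makes
this concrete: at 2 rare cells in 5,000, selection without a bound captures
≥ 80% (typically 100%) of the rare program; a bound of 0.1 captures none.

## Outlier calling

PCA is computed by exact SVD with cells as observations on the scaled,
HVG-restricted matrix; the per-component sign is fixed by making each
loading column's largest-magnitude entry positive, so reports are
reproducible. For each of the first `n_pcs_test = 5` PCs, each cell gets a
robust z-score `|v − median| / (1.4826·MAD)`; a cell is flagged when its
maximum over tested PCs reaches `z_threshold = 10`. PCs with zero MAD are
skipped. The threshold is deliberately extreme: for Gaussian coordinates
the probability of any background cell reaching 10 robust SDs is
negligible, while a spiked rare cell sits at z ≈ 400–1,600 on the component
its program creates. On the default synthetic conditions the background
maximum observed across seeds is ≈ 6–8, so calls are not threshold-
sensitive in a wide band. Median/MAD assume the bulk of cells form a
unimodal mass per component; coordinate distributions that are a point mass
plus a sparse tail (see "What the generator does not model") break that
assumption, which is why the study conditions matter.

**Per-cell differential expression.** Single cells admit no within-group
variance estimate, so per-CTC DE is proxied by the difference of scaled
residual means (target cells minus all others). This ranking — the "scaled
fold-change" — is what preranked GSEA consumes.

## Grouped tests

**Hurdle (bimodal) LRT.** Expression of a gene is modelled as a Bernoulli
detection component times a Normal on the positive log values. The
alternative fits per-group detection rates and means with a pooled σ; the
null pools everything. The free-parameter difference is 2, so the deviance
is referred to χ²(2). Closed-form MLEs make the test vectorizable over all
genes; σ² is floored at 10⁻⁶ when a gene is detected once in a group. The
test is calibrated by construction on hurdle data: empirical type-I error
at α = 0.05 over 2,000 null genes (200 cells/group) lands in [0.03, 0.07],
and the null p-values pass a KS uniformity check.

**AUC markers.** One-vs-rest AUC per cluster and gene via midranks
(P(in > out) + ½P(tie)); exact — it equals brute-force pair counting
bitwise — and invariant under monotone transforms. Singleton clusters are
computed but flagged low-confidence.

**FDR.** Benjamini–Hochberg step-up (statsmodels backend), NaN-propagating
with a warning.

## Preranked GSEA

Genes are ranked by score (descending, ties by input order). The enrichment
score is the signed maximum deviation of a running sum that increments at
set members proportionally to |score|^w (w = 1 by default) and decrements
uniformly at non-members; the extremum is found in O(set size) per
evaluation. The null permutes *gene labels* — with a single cell as the
"phenotype" there is nothing else to permute — with `n_perm = 1000` under a
caller-supplied seed. NES divides ES by the mean same-sign permuted ES;
nominal p is the same-sign exceedance fraction; FDR is the standard pooled
same-sign NES-ratio estimator, clipped to [1/n_perm, 1]. Sets shrinking
below 5 genes after restriction to the ranking are skipped.

## Clustering and integration

The kNN graph (k = 30) connects each cell to its k nearest PC-space
neighbors, union-symmetrized, with Jaccard shared-neighbor edge weights;
neighbors tied at the k-th distance are all included, so exactly
equidistant geometries resolve symmetrically. Clustering is seeded Leiden
modularity optimization (RB-configuration, resolution 0.8). Greedy
modularity optimization is vertex-order sensitive, so when vertices carry
barcodes the graph is canonicalized by barcode before clustering — the
partition then depends only on the cells, not their order. tSNE (perplexity
30, seeded) is strictly a visualization; nothing downstream consumes it.

For two samples, the union of each sample's top-2,000 dispersion genes
(restricted to the shared namespace) defines the feature space. Both
matrices are gene-standardized with the robust capped scaling, and the
cells₁ × cells₂ cross-product is decomposed by SVD; the leading 20 left and
right singular vectors, scaled by √singular value, are the paired canonical
embeddings. The reported canonical correlation per component is the Pearson
correlation of the two components pulled back to gene space (so a dataset
integrated with itself reports exactly 1.0), and components are ordered by
it. Alignment maps each component of sample 2 onto sample 1's empirical
distribution by rank (a monotone quantile map): deterministic, closed-form,
order-preserving, and sufficient to shrink every shared population's
cross-sample centroid distance on the benchmark. Time-warping alignment was
deliberately not implemented; the quantile map is the simplest transform
with the needed guarantees.

## The synthetic data generator

The generator emulates one CD45-depleted blood sample: `n_cells = 5000`
background cells in six populations (T .35, B .12, NK .10, monocyte .30,
pDC .03, RBC .10), `n_rare = 3` spiked hepatocyte-like cells appended at
the end, `n_genes = 2000`, log-normal library sizes (meanlog 8.3, sdlog
0.45 → median ≈ 4,000 UMIs, range ≈ 700–30,000), gene-wise negative
binomial counts (inverse-dispersion θ = 10) around per-cell expected
proportions, and a 13-gene `MT-` block whose per-cell share is a
Beta(10, 90) draw (mean 10%, SD 3% — the spread of a cell-called, QC-passed
matrix; dying high-mito cells are assumed already removed). Dropout arises
from low means; there is no separate zero-inflation term.

Population identity multiplies a 35-gene program by 2^1.5 — deliberately
conservative relative to real blood lineages, which differ by hundreds of
genes. The rare cells express the 15-gene hepatocyte program at
2^`rare_log2fc` times a typical (median-weight) gene — at the default
`rare_log2fc = 6` the program takes a CTC-realistic double-digit share of
the cell's library — and mildly down-regulate five pan-leukocyte genes
(PTPRC and friends, ×0.25) to emulate CD45-negative selection. Blood
background for the hepatic genes is exactly zero: blood cells do not
express them, and ambient RNA is out of the generator's scope. The realized
within/without fold-change therefore far exceeds 2^(rare_log2fc−1), which
is the tested lower bound.

**What the generator does not model, and why it matters.** No ambient RNA,
no doublets, no cell calling from raw droplets, no read-level error — and,
because 2,000 genes stand in for the expressed transcriptome, baseline
expression weights are floored (minimum expected ≈ 0.06 counts/cell) so the
roster contains no ultra-sparse genes. These choices are not merely
simplifications: ambient hepatic counts or a tail of 2–10-cell genes create
PC coordinate distributions that are a point mass plus a sparse tail, whose
MAD collapses and whose tail cells alias as outliers. Real data contain
such genes, and a real analysis relying on median/MAD calling would either
inspect the PC plots (as a human analyst does), restrict testing to the
leading structured PCs, or pre-filter the pathological axes. Passing the
synthetic benchmark therefore demonstrates the pipeline's sensitivity and
specificity *under clean study conditions*, not robustness to every
artifact of raw droplet data.

## Benchmark problem sizes

The packaged checks use: 20 independent 5,003-cell simulations for
spiked-cell recovery; one 5,002-cell sample for the HVG ablation; 2,000
null genes × 400 cells for LRT calibration; a 20-gene × 200-cell fixture
for AUC exactness; 1,000 permutations × 27 sets for GSEA truth recovery;
and a 2,402 + 1,601-cell patient pair for integration. These sizes mirror
the study conditions at desk scale and complete in a few minutes on one
CPU.

## Known limitations

* The outlier caller's median/MAD statistic presumes the non-outlier bulk
  is unimodal per component; heavily multimodal or sparse-tailed
  coordinates need the mitigations above.
* The hurdle test's χ²(2) reference is asymptotic; for groups of < ~20
  detected cells the calibration degrades (the variance floor keeps it
  finite but conservative).
* The CCA alignment matches marginal component distributions only; it
  cannot repair differences in the *joint* geometry of the two samples.
* GSEA FDR uses the pooled-permutation ratio estimator, which is the field
  convention but is known to be conservative for small set collections.
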