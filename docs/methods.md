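# Methods

`mglkit` implements a two-arm analysis of bulk and single-cell RNA-seq from
cultured microglia-like cells: (1) how similar are different cell sources
(e.g. iPSC-derived microglia-like cells vs ex vivo microglia) at the whole-
transcriptome level, and is their separation in PC space statistically
meaningful; (2) how do the cells respond transcriptionally to a stimulus
(e.g. LXR pathway agonists), in bulk and per single-cell subpopulation, and
which subpopulations drive the bulk changes.

## Bulk preprocessing

Samples are removed when total reads < 10,000,000, alignment rate < 60%, or
— for paired-end libraries only — duplicate-read fraction > 50%. All
inequalities are literal and strict, so boundary values survive; a removal
log records which rule fired for each dropped sample. Because the duplicate
rule was designed for externally downloaded libraries, it can be disabled
per run (`apply_duplicate_rule=False`).

Genes whose symbols start with "RP" or "MT" (uppercase prefix match on
uppercased symbols, so `MTOR` and `RPA1` are also caught — the rule is
deliberately literal) are removed. For PCA-bound data, genes with median
TPM < 1 across samples are dropped, values are transformed to
log2(TPM + 0.01), and each gene is z-scored across samples using the n−1
standard deviation (matching the default of the statistical environments
this kind of analysis is usually run in). Raw TPM is retained on a parallel
branch for marker-panel median summaries. Zero-variance genes cannot be
scaled and are dropped with a warning.

Batch adjustment is a location-scale standardization: per gene, each
batch's values are centered and scaled by the within-batch mean and SD,
then rescaled to the gene's grand mean and classic pooled SD (weighted by
batch degrees of freedom). After adjustment every batch has identical
per-gene means and the gene's grand mean and pooled variance are preserved
to ~1e−9. This treats batch removal as preprocessing rather than
inference; an empirical-Bayes variant (ComBat-style shrinkage of the
per-batch moments) is a deliberate non-feature and a documented extension
point. Batches with a single sample are rejected with advice to merge or
exclude.

## PCA and meaningful components

PCA is computed as a centered SVD with samples as observations. Each
component's score vector is sign-flipped so its largest-magnitude entry is
positive, making outputs deterministic across BLAS backends.
Cross-source similarity (the PC1/PC2 distance summary) is the set of all
|A|·|B| Euclidean distances between sample scores of two sources on the
first two components.

"Meaningful" components are detected by permutation: 100 datasets are
formed by independently shuffling each gene's values across samples
(destroying gene–gene correlation while preserving every gene's marginal),
and the variance-explained fraction of the top PC is recorded for each.
The noise threshold is mean + 2 SD (n−1) of those 100 values; the
meaningful count is the leading contiguous run of observed PCs above the
threshold (components are variance-ordered, so the first sub-threshold PC
ends the signal block; counting any PC above threshold is available as
`mode="any"`). A single top-PC threshold is used for all ranks; per-rank
thresholds would be more stringent for later PCs but are not what the
single-threshold definition implies.

## Separability statistics

Both statistics are computed on the sample scores restricted to the
meaningful PCs of the pair being compared (each pair gets its own scaling,
PCA and threshold).

**Silhouette width.** s(i) = (b(i) − a(i)) / max(a(i), b(i)) with a(i) the
mean Euclidean distance to the sample's own source (excluding itself) and
b(i) the mean distance to the other source; the reported score is the mean
over samples. Higher = better separated. Groups of one are rejected (a(i)
undefined).

**SigClust score.** The 2-group cluster index CI = (within-group sum of
squares) / (total sum of squares about the grand mean). For the labeled
source comparison the partition is the given source labels; the reported
SigClust score is the fraction of Gaussian-null cluster indices that are
≤ the observed CI (lower = more separable). The null simulates datasets
from independent Gaussians whose diagonal covariance is the eigenvalue
spectrum of the sample covariance, hard-floored at a background noise
variance estimated as (1.4826 × MAD of the mean-centered entries)²; 1000
null datasets by default. Soft eigenvalue thresholding is not implemented;
the hard-floor variant is the package's choice.

For the *unsupervised* cluster index (no labels), the best 2-partition is
found exactly by enumeration for n ≤ 10 points. This is not an
optimization nicety: the globally optimal within-SS 2-partition is not
always a Voronoi partition of its own centroids (cluster-size factors
enter the optimal assignment condition), so Lloyd-type k-means cannot
reach it from any initialization. Above n = 10, 20 seeded Lloyd restarts
are used, vectorized across restarts.

Degenerate inputs: all-identical points give CI = 0 with a warning (the
0/0 ratio is defined away); two points always give CI = 0.

**Empirical p-values.** Source labels are shuffled jointly over the fixed
meaningful-PC score matrix (PCA is *not* recomputed per permutation) 100
times. For silhouette, p = (# permuted scores > observed)/n_perm; for
SigClust the permutation ranking uses the labeled cluster index directly
— the SigClust p is a monotone nondecreasing step function of the CI, so
this is the same test with the Gaussian-null discretization ties broken by
the underlying continuous statistic (without this, every label split of a
null cloud saturates the score at 1.0 and the strict inequality would
reject always). Comparisons are strict, so p = 0 is representable; a
(b+1)/(n+1) mode is available (`correction="add_one"`). The Gaussian null
CI distribution depends only on the point cloud, never on labels, so it is
simulated once per pair and reused across permutations.

When no PC clears the noise threshold the pair is flagged "no signal above
noise" and scores are omitted (default), or the first two PCs are used
instead (`on_no_signal="top2"`) — appropriate for calibration studies,
where the permutation machinery itself is under test and the top-2 PC
plane is the view such analyses always examine.

Known behavior: with estimated covariance spectra at moderate n and low
dimension, sample eigenvalues overdisperse and the unsupervised SigClust
p-value is conservative (few small p-values on a single Gaussian cloud).
This is a property of the estimator family, not of this implementation;
the permutation p-values, which are what the pipeline reports for source
pairs, are calibrated by construction.

## Single-cell processing and differential expression

Cells are kept when genes detected > 1500 AND total counts < 100,000 AND
mitochondrial fraction < 20% (strict, literal); genes are kept when
detected in ≥ 3 cells. QC metadata are recomputed from the matrix when
absent. Expression is normalized to 10,000 counts per cell and
transformed with the natural-log log1p — the ecosystem default parameters
for this normalization, which the underlying protocol does not specify.

Per-gene differential expression between two cell groups uses the
two-sided Wilcoxon rank-sum test: exact enumeration when both groups have
≤ 10 members, else the tie-corrected normal approximation with continuity
correction. The exact branch handles ties through midranks and computes
the full rank-sum distribution by a subset-sum dynamic program over
doubled midranks; the two-sided p is P(|S − μ| ≥ |S_obs − μ|) with
μ = n₁(n+1)/2. The two branches agree within ±0.02 around the crossover
sizes. Fold change is log2((mean(expm1 x₁) + 1)/(mean(expm1 x₂) + 1)),
the back-transformed-mean-with-pseudocount convention; detection
percentages are percent of cells with a nonzero value.

Multiple testing is adjusted per contrast × cluster with
Benjamini–Hochberg by default (the common default when "adjusted" is
otherwise unspecified); Bonferroni is a switch (`method="bonferroni"`).

Cluster markers: adjusted p < 0.01, detected percentage > 40%, log2FC >
0.6 (upregulated only). Cluster response DEGs: |log2FC| > 0.6, adjusted p
< 0.05, and detection percentage > 10% in at least one of the two groups
(max-over-groups semantics). Bulk DEGs: |log2FC| > 0.6, adjusted p <
0.05, max TPM across samples > 1. All threshold calls are pure set
filters: output ⊆ input and idempotent.

## Bulk counts: normalization and the test statistic

Bulk counts are normalized by median-of-ratios: the reference is the
per-gene geometric mean over samples, excluding genes with any zero count;
each sample's size factor is the median over reference genes of
count/reference. The bulk per-gene p-values come from the same two-sided
Wilcoxon machinery applied to normalized counts, with fold change
log2((mean₁+1)/(mean₂+1)) and no shrinkage. This is an intentionally
simple, transparent substitute for a negative-binomial GLM — the threshold
logic downstream is agnostic to how the statistics were produced and
accepts any table with gene/log2_fc/adj_p columns. Note the granularity
consequence: with n vs n replicates the smallest attainable rank-sum p is
2/C(2n, n), so designs need enough replicates for that minimum to clear
the multiple-testing threshold across the gene panel (n = 8 suffices for
~2000 genes at FDR 0.05; n = 6 does not).

## Deconvolution, overlaps, concordance

Each bulk DEG is assigned to the set of clusters where it is a
same-direction single-cell DEG for the matched contrast; bulk DEGs with no
same-direction hit are labeled bulk-only, and opposite-direction hits are
recorded separately as discordant, never merged. The three categories
partition the bulk DEG set. DEG-set overlaps are reported as
(a-only, shared, b-only) counts, per direction where relevant. Fold-change
concordance between conditions (or between the bulk and single-cell arms)
is the Pearson correlation over the shared genes with finite fold changes
(≥ 3 required).

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
any real dataset's gene-level values.

**Bulk.** log2-scale model: per-gene baseline ~ N(3, 2) (TPM spanning
~0.1–1000), plus a per-source shift of (k−1)·δ·sign(g) on a chosen gene
subset (signs alternate, so consecutive sources differ by exactly δ in
expectation — verified on ensemble means), plus per-(batch, gene) offsets
~ N(0, σ_batch), plus residual noise ~ N(0, σ_noise); TPM = 2^(sum). The
default residual SD of 1 log2 unit reflects the sample-to-sample spread
typical of heterogeneous public bulk compendia. Five percent of the gene
panel carries names with "MT-"/"RP" prefixes so the literal prefix filter
is exercised; shifted genes are drawn from well-expressed non-prefix genes
so planted truth survives the median filter. QC-failing samples (an exact
rounded count) receive read totals uniform in [1e6, 9.99e6], tripping the
10M threshold deterministically.

**Single cell.** Negative-binomial counts (variance μ + αμ²) with shared
dispersion α = 0.3, gene mean scales log-normal around 5. The gene panel
is deliberately small (2000) for speed, so per-gene means are set high
enough that healthy cells detect well over 1500 genes — keeping the
*absolute* QC thresholds meaningful at reduced dimension. What this does
not emulate: per-cell library-size variation beyond NB noise, ambient
RNA, doublets, or realistic mean–dispersion trends; conclusions from
passing tests are about the analysis machinery, not about robustness to
those artifacts. Each cluster gets 40 marker genes at 4× baseline.
Response genes (100) are multiplied by 2^treatment_lfc in treated cells of
the responsive clusters only, and carry a 4× elevated baseline in those
clusters in both conditions — mirroring the observed pattern that
stimulus-response programs concentrate in the responding subpopulation,
which is what keeps a cluster-confined response visible above the bulk
fold-change threshold after mixture dilution. Cells forced to fail QC (an
exact rounded count per condition) alternate between a collapsed library
(2% of normal means) and a 30× inflated mitochondrial load.

**Pseudobulk.** Bulk replicate counts whose per-gene means are the
equal-weight mixture of the single-cell cluster means (×30 depth, NB
dispersion 0.05, 8 replicates per condition — see the granularity note
above), sharing the single-cell config's planted truth so the
deconvolution arm can be validated end to end.

All generators are deterministic given config + seed; sub-streams are
derived from the top-level seed by fixed offsets so each module is
independently reproducible.

## Pipeline

Runs are YAML-configured (stages, seed, permutation counts, thresholds).
All protocol thresholds appear by name with their defaults pre-filled
(`min_median_tpm: 1`, `lfc_cutoff: 0.6`, ...); unknown names are rejected
and any override is echoed into the run manifest. The manifest records a
config hash, the seed, and SHA-256 checksums of every output, and
identical config + seed reproduces byte-identical outputs. The report
stage emits one TSV per summary plus a JSON index validated against a
shipped JSON-schema-style document.

## Problem sizes used in validation

Calibration and power studies run at 2 sources × 10 samples × 2000 genes
with 100 permutations (200 and 100 replicates respectively); the noise
floor study at 20 × 500; single-cell recovery at 4 clusters × 150 cells ×
2 conditions × 2000 genes. These sizes were chosen so ensemble statistics
are stable while whole-suite runs stay interactive.

## Known limitations

- The bulk test statistic is a rank test, not a count model; it is less
  powerful than an NB GLM at small n and its p-values are discrete.
- Batch adjustment assumes batch effects are location-scale per gene;
  interactions between batch and source are not modeled, and confounded
  designs (a source present in only one batch) will remove real signal.
- Cluster labels are inputs everywhere; no clustering is performed.
- SigClust's Gaussian null uses a diagonal (eigenvalue) spectrum; heavy
  tails or strongly non-Gaussian scores make the unsupervised p-value
  approximate. The permutation p-values do not share this assumption.
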