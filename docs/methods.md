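# Methods

This note documents the models, numerical conventions and design
choices behind `rbsubtyper`, and what the synthetic cohort generator
does and does not emulate.

## Synthetic cohort model

The generator produces a two-subtype cohort (default 30 + 30 samples)
emulating the structure of a retinoblastoma multi-omics series.

**Expression** (genes × samples, log2 array-intensity scale). Each gene
has a baseline mean drawn N(7, 1); per-sample residual noise is
N(0, 1). Marker blocks (40 genes each by default) are shifted by the
expression effect size (default 2.0 log2 units): late cone markers
(PDE6H, GNAT2, ARR3, GUCA1C, … plus synthetic fillers) up in subtype 1
only, neuronal/ganglion markers (EBF3, DCX, GAP43, …) up in subtype 2
only. The four early cone markers (OTX2, CRX, THRB, RXRG) are raised by
half the effect in *both* subtypes: both subtypes derive from committed
cones and differ in maturity, not lineage. The eight cone-panel genes
share a common baseline so that the relative early/late marker levels —
not random per-gene offsets — carry the differentiation signal; this is
what makes Pearson staging against the organoid reference meaningful at
this cohort size. Probe-level normalization (RMA) is not simulated;
inputs are taken to be post-normalization, as array pipelines deliver
them.

**Stromal contamination** mixes each stromal-block gene additively in
linear space: observed = (1 − w)·tumor + w·stroma, with per-sample
weight w uniform on a configurable interval (default [0, 0.3]) and the
pure-stroma level fixed at 16-fold (4 log2 units) above each gene's
tumor baseline. The fixed fold-change gives every stromal gene the same
response curve in w, which is what makes the contamination a single
recoverable independent component.

**Methylation** (CpGs × samples, beta values). Island CpGs start lowly
methylated (Beta(2, 10)), open-sea CpGs highly (Beta(10, 3)); 40% of
CpGs are islands. A planted 20% of CpGs are differential: island CpGs
gain the beta effect size (default 0.3) in subtype 2, open-sea CpGs
lose it — the island-hypermethylation / open-sea-hypomethylation
pattern of the aggressive subtype. Noise is Gaussian (SD 0.05) clipped
to [0, 1]; a logit-normal alternative (noise on the logit scale,
matched to the Gaussian SD at beta = 0.5) avoids boundary clumping and
is selectable by config.

**Copy number.** A simplified genome of 13 chromosome arms carries
per-sample arm events drawn with subtype-conditional probabilities:
1q gain (0.10 vs 0.70), 2p gain (0.15 vs 0.50), 16q loss (0.10 vs
0.60), 6p gain (0.50 both), and a focal 2p amplification only in
subtype 2 (probability 0.17, matching an ~1-in-6 amplification rate)
with copy number log-uniform on [14, 246]. Segment values get Gaussian
measurement noise (SD 0.05), as array- or sequencing-derived copy
numbers do; without it the region matrix would be exactly constant for
unaffected samples and sample–sample correlations degenerate. Ground
truth is emitted both as a SEG-like segment table and as a pre-averaged
arm × sample region matrix, so copy-number clustering can be tested
with or without the segment-processing stage.

**Clinical covariates** are drawn with subtype-conditional
probabilities calibrated to the published cohort: bilateral disease
0.32 vs 0.07, endophytic growth 0.22 vs 0.63, necrosis 0.53 vs 0.77,
sex near-balanced; age at diagnosis is log-normal with medians 11.0
and 23.9 months. **Organoid time-courses** follow rising sigmoids in
differentiation day (width 12 d) with marker-specific onsets (OTX2 d30
… GUCA1C d140, the last marker to switch on); late phototransduction
markers plateau higher (amplitude 8 vs 5 log2 units), as mature cone
genes do.

What the generator does *not* emulate: batch effects, probe-level
artifacts, IDAT/FASTQ-level processing, per-subtype heteroscedasticity
(no variance structure is published, so defaults are homoscedastic),
or intra-tumor heterogeneity. Passing tests therefore demonstrate that
the algorithms recover planted block-structured signal at realistic
effect sizes — not that they are robust to every artifact of real
arrays.

## Feature selection

rCV is MAD/max(|median|, 1e−8) (an IQR/|median| variant is provided);
robustness to outlying samples is the point of using
median-based dispersion. The variance test is realized as a one-sided
chi-squared test of H0: σ²_g = median variance, statistic
(n−1)s²_g/σ²_med on n−1 df — the natural parametric reading of testing
"whether the variance for a gene is higher than the median variance".
Subsets at decreasing rCV percentiles are nested by construction since
the variance filter is fixed.

The stromal filter fits a deflation-based FastICA (k = 3 components)
on the gene-centered matrix, z-scores gene loadings per component, and
tests both ±2.5 tails of every component for hypergeometric enrichment
of a stromal marker list (enrichment p < 1e−3); genes in any enriched
tail are dropped. Screening all components in both signs automates
what is otherwise a manual inspection step of single components.
Non-convergence is retried with incremented seeds (5 attempts), then
raised.

## Consensus clustering and stability

Samples are clustered on 1 − Pearson correlation distance computed over
the chosen feature subset; zero-variance samples make the correlation
undefined and are rejected by name rather than imputed. Ward linkage is
applied to the correlation dissimilarity as if squared-Euclidean — the
convention of the array-clustering tools this mirrors, stated here as a
dialect choice. Agglomeration and tree-cutting use
`scipy.cluster.hierarchy`; merge tie-breaks follow scipy's
deterministic input ordering.

The stability score perturbs each feature subset with i.i.d. Gaussian
noise and re-clusters. The perturbation scale is printed ambiguously in
the protocol this follows ("σ = 1.5× median variance"); since σ denotes
a standard deviation and must share units with the data, the default is
σ = 1.5·√(median feature variance), with the literal reading
(σ = 1.5 · median variance) available as `sigma_mode="literal"`.

The symmetric-difference score between partitions A and B is the
symmetrized pair-retention similarity: with S_X the set of sample pairs
co-clustered in X, score = (|S_A∩S_B|/|S_A| + |S_A∩S_B|/|S_B|)/2, a
directional ratio with empty denominator counting 0, and 1 when both
sets are empty (two all-singleton partitions agree perfectly). Though
sometimes called a distance, the quantity is oriented as a similarity:
identical partitions score exactly 1. A Jaccard variant on the same
pair sets is available.

## Integration and classification

The cross-omics co-classification entry for a sample pair is the
fraction of *shared* platforms in which the pair co-classifies;
samples present in fewer than `min_presence` (default 2) platforms are
excluded with a warning. Complete linkage on 1 − co-classification cut
at k_cc = 3 yields two core subtypes (the two largest clusters) plus
ambiguous samples. Subtype 1 is the core cluster with younger mean age
when clinical data is available, otherwise the cluster containing the
earliest-listed sample; size ties break toward the cluster with lower
mean dissimilarity. The module accepts any number of omics partitions
at any k each.

Centroid models rank features by a two-sided two-sample test within
each direction of change (Welch's t for expression, Wilcoxon rank-sum
for beta values — rankings that track moderated-t orderings closely at
these sample sizes), keep the top n per direction, and store per-class
feature-wise medians. Classification drops missing features pairwise
(≥ 50% of model features and ≥ 3 overlapping values required) and
rejects queries whose best Pearson correlation is below the model
threshold (0.1 expression, 0.3 CpG panel) or whose profile is constant.
Panel selection ties (equal p) break by larger |Δβ|, then feature
identifier, making the panel fully deterministic. The Tukey outlier
rule for contamination screening uses linear-interpolation quartiles
(stated because fence membership can depend on the quantile
convention).

## Copy number

Coordinates are 1-based inclusive (SEG convention); overlap arithmetic
converts to half-open internally. The zero level is the
length-weighted median of absolute copy numbers, or — for log ratios —
the midpoint of the tallest bin of a length-weighted histogram with
0.05 bin width (ties to the lower bin; width configurable). Calls use
strict inequalities: gain > zero + 0.5, loss < zero − 0.5 (±0.15 in
log-ratio mode); amplification ≥ 5 copies and homozygous deletion
≤ 0.5 in absolute mode, and mean ± 5 SD of the already-called-normal
segments in log-ratio mode. Features are weighted by marker count when
present, else segment length; per-chromosome aberrant proportions are
weighted, the cross-chromosome mean is not. Segmentation itself is out
of scope — inputs are pre-segmented tables.

## Scores and statistics

The stemness index mean-centers genes, Spearman-correlates each
sample's centered profile with a signature weight vector over shared
genes, and min–max scales across the cohort, so every cohort spans
exactly [0, 1] (single-sample input returns the raw correlation with a
warning). For synthetic runs the weight vector is +1 on the
neuronal/progenitor block and −1 on the late-cone block — stem-like
versus differentiated — standing in for an externally trained
stem-cell signature. The ssGSEA score ranks genes by expression per
sample and integrates the difference between the rank^α-weighted
in-set cumulative distribution and the uniform out-of-set one
(α = 0.25; α = 0 degenerates to the unweighted CDF difference);
cohort scores are range-normalized. Chi-squared tests use no
continuity correction (with Yates' correction the published laterality
p-value is not reproduced). The two-sided Fisher p sums hypergeometric
probabilities of tables at most (1 + 1e−7)× as probable as the
observed one — the dominant software convention. The differential
effect size Δ is the difference of class means (median by flag).

## Staging and phylogeny

Organoid centroids are per-day medians over replicates; group centroids
are correlated with each day's centroid over the 8-gene panel, and the
assigned stage is the argmax day (ties toward the latest; constant
profiles are an error since Pearson is undefined). Neighbor joining
comes from scikit-bio with negative branch lengths clamped to zero.
Balanced minimum evolution starts from the NJ topology and applies
nearest-neighbor interchanges while the Pauplin length
Σ_{i<j} D_ij·2^(1−p_ij) (p_ij = edges on the i–j path) decreases,
then fits ordinary-least-squares branch lengths clamped at zero. By
construction the search never returns a tree with larger balanced
length than its NJ start.

## Pipeline defaults and problem sizes

The full pipeline (simulate → stromal filter → feature ladder →
per-omics stability and consensus → cluster-of-clusters → centroid
classification of ambiguous samples → CpG panel → instability →
stemness → staging → association tests) runs at desk scale by default:
600 genes, 600 CpGs, 13 copy-number regions, 60 samples, stability over
k = 2..5 with 20 noise iterations, and 50 features per centroid
direction. These sizes keep a full run and the test suite fast while
preserving the study's effect sizes (2.0 log2 expression, 0.3 beta),
its 24-member ensembles and all thresholds; the study-scale parameters
(200 iterations, k = 2..8, 400 genes/5,000 CpGs per direction) remain
the documented defaults of the respective config objects and are
exercised on larger synthetic cohorts where the behavior depends on
them (e.g., the 800-feature model's noise rejection). Consensus
clustering selects the most stable k per omics; subsets smaller than 5
features (2 for copy number) are skipped since near-degenerate subsets
make sample correlations unstable.

## Known limitations

- The CNA consensus partition alone is a weak subtype signal (events
  are probabilistic and shared across subtypes), exactly why
  integration across platforms is needed; single-omics copy-number ARI
  against truth can be near zero at default event rates.
- The NNI search is greedy first-improvement and may stop in a local
  optimum of the balanced length; for the panel-sized trees used here
  this has not been observed to matter.
- Hypergeometric enrichment treats genes as exchangeable; no
  gene-length or expression-level bias correction is applied.
- The pipeline's stemness weight vector is synthetic; applying the
  stemness index to real cohorts requires an externally trained
  signature supplied by the user.
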