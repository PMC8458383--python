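# rbsubtyper

Multi-omics molecular subtyping of retinoblastoma, packaged as a
reusable Python library with a thin command-line pipeline.

Retinoblastoma, the most common pediatric intraocular cancer, splits
into two molecular subtypes: a clinically milder, cone-differentiated
subtype 1 and a more aggressive, less differentiated subtype 2 marked by
CpG-island hypermethylation, recurrent 1q/2p gains and 16q losses,
expression of neuronal/ganglion markers and higher stemness. This
package implements the analysis machinery needed to discover and apply
that subtyping on transcriptome, methylome and copy-number data — and a
synthetic multi-omics cohort generator so every stage can be exercised
and tested without access-controlled patient data.

## What it implements

- **Feature selection** — a robust-CV ladder (rCV = MAD/|median| at
  percentile thresholds 99.5th → 60th) intersected with a one-sided
  chi-squared variance test (p < 0.01 against the median feature
  variance), plus ICA-based removal of stromal-contamination genes
  (|loading z| > 2.5 tails tested for marker enrichment).
- **Consensus clustering** — per omics, an ensemble of hierarchical
  clusterings (8 feature subsets × {average, complete, Ward} linkage,
  distance 1 − Pearson), reduced to a co-classification matrix
  C(i,j) = #{partitions with i, j co-clustered}; the consensus
  k-partition is complete-linkage clustering of MAX_VALUE − C. Partition
  stability under Gaussian perturbation (σ = 1.5·√(median feature
  variance), 200 iterations at study scale) is scored by the symmetric
  pair-retention similarity, which is 1 for identical partitions.
- **Cluster-of-clusters integration** — per-omics consensus partitions
  are merged into a fractional co-classification matrix (0 = never
  co-classify, 1 = always, over shared platforms; samples need ≥ 2
  platforms) and cut at k = 3: two core subtypes plus an ambiguous
  group.
- **Centroid classifiers** — per-class median profiles over the 400 most
  differential genes per direction (800 total; 5,000 CpGs per direction
  for the methylome model); queries are assigned by best Pearson
  correlation with an unclassified rejection below r = 0.1, and a
  two-stage minimal CpG panel (top 50 hyper-/30 hypomethylated by
  p-value, re-ranked by |Δβ|, 7 + 7 kept) supports assay-based
  classification at threshold r = 0.3.
- **Copy number** — per-sample zero-level estimation (length-weighted
  median of absolute copy numbers, or histogram mode of log ratios),
  Gain/Normal/Loss calls (±0.5 absolute, ±0.15 log ratio; amplification
  ≥ 5 copies, homozygous deletion ≤ 0.5), and a genomic instability
  score: the mean over chromosomes of the aberrant feature fraction.
- **Signature scores** — Spearman-correlation stemness index min–max
  scaled to [0, 1], ssGSEA enrichment scores (rank^α weighting,
  α = 0.25), z-scored pathway meta-scores, and the
  immunohistochemistry quick score QS = I × P.
- **Differentiation staging** — Pearson correlation of subtype centroids
  with retinal-organoid centroids per differentiation day on an 8-gene
  cone panel (OTX2, CRX, THRB, RXRG, PDE6H, GNAT2, ARR3, GUCA1C), and
  minimal-evolution phylogenies (neighbor joining, or balanced minimum
  evolution with NNI search) on the panel's Euclidean distances.
- **Clinical statistics** — chi-squared (no continuity correction),
  two-sided Fisher exact, Kruskal–Wallis, BH correction, differential
  feature calling (Wilcoxon/Welch + BH + effect-size filter) and
  hypergeometric enrichment.

## Worked example

```python
import rbsubtyper as rb
from sklearn.metrics import adjusted_rand_score

expr, meth, segments, truth = rb.generate_cohort(rb.CohortConfig(seed=1))

partitions = {}
for omics, matrix in [("expression", expr), ("methylation", meth),
                      ("cna", truth.region_matrix)]:
    subsets = [s for s in rb.feature_subsets(matrix) if len(s) >= 2]
    ensemble = rb.build_partition_ensemble(matrix, subsets,
                                           rb.ConsensusConfig(), k=2)
    partitions[omics] = rb.consensus_partition(ensemble, k=2)

result = rb.cluster_of_clusters(
    rb.cross_omics_coclassification(partitions), k_cc=3)
core = result.core_labels
print(core.value_counts().to_dict(), len(result.ambiguous))
print(adjusted_rand_score(truth.subtype[core.index], core))
```

prints

```
{1: 30, 2: 30} 0
1.0
```

— all 60 samples land in two core clusters of 30 and the integrated
subtypes match the planted labels exactly (adjusted Rand index 1.0).
The scripts in `examples/` walk through each capability the same way:
simulation, consensus subtyping, classification, copy-number scoring,
organoid staging with tree building, and clinical association testing.
Running `examples/04_copy_number.py`, for instance, prints mean genomic
instability 0.052 for subtype 1 versus 0.123 for subtype 2 — the planted
arm-level events concentrate in subtype 2.

The same stages are available from the shell:

```bash
rbsubtyper simulate --seed 17 --outdir cohort/
rbsubtyper run-all --seed 17 --outdir run/
```

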