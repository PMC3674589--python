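# Methods

This note documents the models, conventions and numerical choices behind
`coexnet`, and what the synthetic study design does and does not establish
about real data.

## Synthetic study design

The generator emulates a two-species transcriptomic comparison: a human
cohort of 25 controls, 16 sicca patients and 24 patients with primary
Sjögren's-like disease (65 samples, disease coded ordinally 0/1/2), and a
mouse disease-model time course with 5 animals at each of weeks 4, 8, 12,
16 and 20 (25 samples, trait = standardized week).

Expression follows a latent-factor model. Each module *m* has a per-sample
eigengene *e<sub>m</sub>* = effect<sub>m</sub> · trait + ε, standardized to
mean 0 / sd 1; gene *i* of module *m* is

  *x<sub>i</sub>* = *w<sub>i</sub>* *e<sub>m</sub>* + √(1 − *w<sub>i</sub>*²) · σ · ε<sub>i</sub>,

with loading *w<sub>i</sub>* ~ Uniform(0.6, 0.95) and noise sd σ = 1, so
cor(*x<sub>i</sub>*, *e<sub>m</sub>*) = *w<sub>i</sub>* and the first
principal component of the module provably approximates *e<sub>m</sub>*.
Background genes are pure noise. The large-sample module–trait correlation
has the closed form effect · sd(trait) / √(effect² var(trait) + 1), which
the tests verify at n = 5000 within ±0.02.

Defaults (the study conditions for all tests): 6 modules of sizes
100/80/60/50/40/30 plus 640 background genes (~1,000 genes); trait effects
(+1.0, −0.8, 0, 0, 0, 0), giving population module–trait correlations of
about +0.65 and −0.57 at the human group sizes — the magnitude of the
strongest disease modules such studies report; exactly one module (the
positive one) preserved across species. Effect sizes are a design choice
for testability: field studies do not report them on this scale.

Cross-species structure: preserved modules reuse the same genes and
loadings in both species (the trait effect re-expressed on the week axis);
all other genes have their mouse labels scrambled, which destroys
within-module topology while preserving marginal distributions — a cleaner
null than deleting genes, because module size and expression scale stay
intact. Batch structure is two batches with per-gene additive shifts
(N(offset, offset/2), offsets 0 and 0.5); probe redundancy duplicates each
gene into 2 probes with probe-specific offsets (sd 0.5) and noise (sd 0.3).

What the generator does **not** emulate: probe-level array chemistry,
mean–variance relationships of real intensities, correlated background
(housekeeping) structure, realistic gene-set/GO topology, or sex effects on
expression. Passing tests therefore establish correctness of the
*computations* and their behaviour under a known truth — not performance
guarantees on real microarray data.

## Preprocessing

Fixed order: interarray-correlation outlier screen → quantile normalization
→ ComBat batch adjustment → probe collapse. The outlier screen standardizes
each sample's mean correlation with all other samples and flags z < −2.5 (a
conventional cut; on well-behaved data nothing is flagged — the threshold
is exposed because the literature names the method, not a cut). Quantile
normalization maps each column's ranks onto the row-means of the sorted
columns, averaging reference values over ties; it is idempotent to 1e-12.
Batch adjustment is the parametric empirical-Bayes ComBat model (via
scanpy); the nonparametric variant is out of scope. Note that EB shrinkage
leaves residual batch-mean differences of order noise/√n per gene — exact
equalization is not the model's goal. Probe collapse keeps, per gene, the
probe with the highest across-sample mean (first occurrence wins ties, a
deterministic rule required for reproducibility). Ortholog projection keeps
only pairs that are one-to-one in both directions and logs the drop count.

## Network construction and module detection

Signed adjacency ((1 + r)/2)<sup>β</sup> with β = 12 (the conventional
default; no scale-free-fit selection is performed). The signed TOM uses the
shared-neighbour formula with connectivity k from the signed adjacency; no
absolute values are reintroduced. Correlations use the fast complete-data
path, falling back to pairwise-complete with ≥ 3 shared samples when values
are missing.

Clustering is UPGMA (scipy). The branch cut is a static cut at
(0.99 − 0.01·deepSplit) × max merge height (deepSplit ∈ {0..4}, default 2 —
lower cuts split more finely), keeping branches with ≥ minModuleSize
(default 30) leaves, followed by a hybrid stage: each unassigned gene joins
its nearest module if its mean dissimilarity to that module is below the
module branch's own top internal merge height. This recovers borderline
members while leaving noise genes grey, because noise sits near the maximum
dissimilarity while module branches close well below it. On the default
design this recovers the planted partition with mean adjusted Rand index
≈ 0.96 over 10 seeds and leaves pure-noise data entirely grey.

Blockwise mode pre-partitions genes by k-means on their top-30
principal-component projections (blocks ≤ maxBlockSize, default 5,000,
oversized clusters split recursively), runs the full pipeline per block,
then merges modules whose eigengenes correlate above 1 − mergeCutHeight
(default 0.85) by average-linkage clustering of eigengene dissimilarity —
one merge pass, which suffices because merging is transitive within a flat
cluster. Modules are renamed by the conventional color sequence in
decreasing size order, ties broken by the lexicographically smallest member
gene; `grey` is reserved for unassigned genes.

## Module eigengenes and trait association

The eigengene is the leading right singular vector of the gene-standardized
module submatrix, scaled to unit variance. Sign is fixed so the eigengene
correlates non-negatively with the mean standardized module profile — a
mandatory convention, since reported module–trait correlations are signed.
The grey background is summarized and tested like any module (its eigengene
can track a trait even when its genes are not a cluster). Module–trait
association reports the Pearson correlation test and the Kruskal–Wallis
group test side by side, because both are in common use for this design
and they answer slightly different questions (linear trend vs any location
shift); Bonferroni adjustment is over the number of modules tested.

## Preservation

Statistic set (fixed by this package so results are well-defined): density
family meanSignedCor, meanAdj, propVarExplained (mean kME²), meanKME;
connectivity family cor_kIM, cor_kME, cor_cor. The null treats a uniformly
random gene set of the module's size as the module in the test data while
the reference-side vectors stay fixed — test-side label permutation.
Z = (obs − null mean)/null sd per statistic; family Zs are medians;
Zsummary is the mean of the two family medians. Default 200 permutations;
the empirical p uses the add-one estimator (1 + #{null ≥ obs})/(nPerm + 1)
so p is never 0, and a normal-tail p for Zsummary is reported alongside
(very small published preservation p-values imply an analytic tail).
Grey/background genes are excluded as modules but remain in the permutation
sampling pool. Preservation is evaluated against the pooled test dataset
(all weeks together). A zero null sd yields an infinite Z with a warning
rather than an error. medianRank ranks each observed statistic across
modules (average ranks on ties) and takes the median — insensitive to
module size, complementing Zsummary.

## Screening

The two-group screen uses the Welch t-test by default (`var_equal=True`
gives the pooled form; the choice is exposed because conventions differ),
point-biserial correlation with the first group coded 1, a signed ratio
fold change (mean1/mean2 or −mean2/mean1; NaN when a mean is non-positive —
flagged missing, never fabricated), the rank-form AUROC with half-credit
ties, and Benjamini–Hochberg q-values. q-values are BH rather than a
local-FDR estimator: deterministic, dependency-free, and conservative in
the same direction. The numeric-trait screen reports the Pearson
correlation, its Student t test, and a concordance-based AUROC analog
(C-index over pairs with unequal trait values). Statistics are computed on
present samples; `nPresentSamples` is reported per gene.

Concordant-gene selection requires correlation ≥ +0.5 (or ≤ −0.5) with
disease progression in both species. Comparisons are *inclusive*: published
selections print rounded correlations, and a strict rule would drop genes
printed exactly at the threshold.

## Enrichment

Hypergeometric upper tail with the ≥-tail convention (the observed
overlap's pmf term included — implementations differ by exactly this term,
so it is stated). The background is the set of genes surviving
preprocessing (configurable); chip-wide annotation backgrounds require
annotation databases that are out of scope. Sets with zero background hits
are skipped; Bonferroni and BH are applied over tested sets.

## Pipeline and determinism

Stage order is fixed; each stage's outputs are written before the next
starts, and a JSON manifest records config, seed, shapes, warnings and
timings. The global seed fans out to per-stage child seeds through
SeedSequence spawn keys, so stages can be re-run in isolation. All TSV
writers use a fixed float format (`%.10g`); reruns with the same config are
byte-identical (the manifest differs only in elapsed times). The default
end-to-end run (~1,000 genes, 65 + 25 samples, 200 permutations, 2 probes
per gene) takes well under a minute on one CPU; test and validation
problem sizes (10–50 simulation seeds, 500 trait replicates, 2,000 null
genes) were chosen to give stable rates while keeping a full validation run
in minutes.

## Known limitations

* The dynamic branch cut is a faithful-in-spirit reimplementation (static
  cut + hybrid assignment), not a port of the reference tree-cut algorithm;
  on deeply nested or strongly unbalanced dendrograms the two can split
  branches differently. The smallest planted module (30 genes, at the
  minModuleSize boundary) occasionally stays grey at noisier seeds.
* Preservation Z scales grow with module size and data quality; the >10/<2
  decision thresholds are interpretive conventions, not error rates.
* The ComBat step assumes no batch–group confounding; the generator assigns
  batches round-robin within groups, so this holds by construction.
* Missing-data support is limited to pairwise-complete correlations and
  per-gene present-sample counts; no imputation is provided.
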