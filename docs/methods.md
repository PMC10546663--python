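# Methods

This note documents the models, statistics and numerical choices behind
`crosstype`, and what the synthetic-data studies do and do not establish.

## Synthetic cohorts

The generator draws gene-by-sample counts from a negative binomial with
mean `m` and variance `m + φ·m²` (dispersion `φ = 0.15` by default, shared
across genes — a mid-range value for bulk RNA-seq).  Per-gene baselines are
log-normal: log2 mean ~ Normal(4, 1.5) on a TPM-like scale.  Biology enters
as log2-scale shifts:

- each subtype owns a block of panel genes plus `n_informative_per_subtype
  = 60` extra genes, up-shifted by `effect_size` (default 2, i.e. 4-fold)
  in that subtype;
- the homologous pair named by `shared_axis` shares one signature across
  species — this is the planted cross-species homology;
- species-private subtypes (subtypes of the shared-axis species other than
  the homologous one) get a 2× effect multiplier and a signed ±effect
  pattern across the remaining panel genes.  This encodes what
  "species-private" means operationally: the subtype diverges from every
  cross-species profile more than the other species' subtypes differ among
  themselves.  Without it, clean synthetic data lets the private subtype
  sit inside the big non-basal human cluster at the minimal dendrogram
  cut, which is not the biology the private subtype represents;
- batch/species effects are a location-scale distortion of the log2 means
  (per-gene shifts drawn around the configured location), applied after
  biology;
- the three receptor marker genes are pinned to per-subgroup FPKM targets
  chosen to straddle the ER/PR threshold of 1 and the HER2 threshold of 35
  with wide margins, so threshold calls have an unambiguous planted truth;
- library sizes are uniform on 2–4 million; gene lengths log-uniform on
  0.3–10 kb; counts convert to FPKM (`counts·1e9 / (length·total)`) and
  TPM (column-normalized FPKM × 1e6) exactly as the units are defined.

Two named configurations freeze the study conditions: a 143-sample
(69 + 74) single-species cohort for subtype recovery (800 genes — enough
for nested most-variable subsets of 800/400/200 while keeping 30-run NMF
consensus tractable on one CPU), and a two-species cohort (canine 69+74;
human Basal/LumA 80 each, LumB/Her2 70 each, Normal 27) for the homology
experiment.  The homology configuration generates both species on a common
scale — the pipeline's ComBat step is assumed to have removed species
location-scale effects already.  We correct batch effects with ComBat when
batches are not confounded with the biology of interest; across species the
private-subtype signature *is* confounded with species, and empirical-Bayes
correction would transfer an inverted copy of it onto the homologous canine
subtype, so the homology studies use the corrected condition directly.

What passing these studies does not show: real cohorts have correlated
genes, heteroskedastic dispersions, annotation noise, partially shared
panels and batch structure entangled with biology.  The synthetic studies
validate the machinery (statistics, algorithms, bookkeeping), not the
biological conclusion on any real cohort.

## Subtype discovery

NMF uses the classical multiplicative updates for the generalized
Kullback-Leibler objective, run on log2(TPM+1) values (the +1 pseudocount
keeps zeros finite; the factorization input must be nonnegative, which the
log transform preserves).  Each factorization runs from `n_runs = 30`
random starts; per-sample labels are the argmax of H; the consensus matrix
is the fraction of runs co-assigning each sample pair; the cophenetic
coefficient correlates average-linkage tree distances on (1 − consensus)
with the consensus dissimilarities.  Rank selection maximizes the
cophenetic coefficient, ties to the smaller rank.  Updates run in single
precision (the consensus depends on coarse structure only) with a relative
objective tolerance of 1e-4 checked every 10 iterations, max 300.

Consensus subtyping repeats the factorization per gene subset, aligns
binary labelings by identity-vs-swap (Hungarian matching for rank > 2),
and flags a sample consistent only when every subset run assigns it the
same aligned label — the strictest reading of "consistently divided".

Metagene extraction scores each gene's normalized basis row by
`1 + Σ p log2 p / log2(rank)` (1 = loads on one factor, 0 = flat) and keeps
genes above median + 3·MAD whose dominant loading exceeds that factor's
median loading.

Cross-method validation runs k-means (10 restarts), resampled consensus
clustering (default 1000 resamples of 80% of samples, average-linkage inner
clustering, consensus-matrix cut) and average-linkage hierarchical
clustering with gene-bootstrap co-clustering support (plain bootstrap
support; the multiscale-bootstrap approximately-unbiased variant is not
implemented).  Note that on pure noise the three methods still agree with
each other well above chance — they partition the same realized noise —
so the meaningful null check is agreement with an independent reference
labeling, which is what the tests assert.

## Panel classification

Centroids are trained from a labeled reference: per-gene standardization
(mean/sd over the reference; zero-variance genes dropped), per-subtype
median profiles.  Classification computes the Spearman correlation of each
sample to each centroid over the shared panel genes; the label is the
argmax with ties broken in the fixed order Basal, Her2, LumA, LumB,
Normal; the confidence is the winning correlation and the margin the gap
to the runner-up.  Rank correlation makes calls exactly invariant to any
monotone per-sample transform.  Because the classifier consumes the
sample's cross-gene ranks, inputs should be on a relative scale when the
signature is single-axis (e.g. a binary feature-set model): the
feature-selection evaluator standardizes test samples per gene with the
training parameters before classifying.  Training from a reference keeps
the artifact self-contained; published centroid files can be dropped in as
a TSV with the same layout.

## Cross-species homology

Each repeat samples 60 human tumors per listed intrinsic subtype without
replacement plus every member of the always-included (normal-like) group;
the RNG stream is derived from (seed, repeat index) so repeats are
independently reproducible.  Post-hoc coverage of the human pool is
reported, not enforced.  The merged canine+reference matrix on the shared
panel genes is row-scaled jointly (sample sd), clustered with average
linkage on Euclidean distances, and cut at the smallest k whose partition
maximally separates the two human anchor groups, where the separation
score S(k) is the fraction of anchor samples lying in clusters free of the
opposite anchor.  Cuts are replayed from the merge order (nested
partitions), which makes S(k) non-decreasing and the "minimum k attaining
the maximum" well-defined; for disjoint anchors the maximum is exactly 1.
Matching requires one cluster to contain a strict majority (> 50%) of all
samples of a canine subtype and of a human subtype simultaneously.

Per repeat, classical (Torgerson) MDS embeds the Euclidean distances in
2 dimensions (configurable; 2 matches the plotted embedding convention)
and the Mahalanobis distance between subtype centers uses the pooled
within-group covariance with a 1e-8 ridge.  Aggregates: per-pair match
tallies; a 2×2 Fisher exact test comparing the homologous pair's tally to
the species-private pair's; Wilcoxon rank-sum comparisons between distance
distributions.  The Fisher p-value sums hypergeometric probabilities not
exceeding the observed table's (1e-9 relative slack against float ties);
the rank-sum test enumerates exactly for n+m ≤ 12 without ties and
otherwise uses the normal approximation with tie and continuity
corrections.

## Feature selection

Candidate pools are pairwise DE gene sets (BH p ≤ 0.05, no fold cutoff at
this stage) between the target subtype and each other subtype.  Boruta
rounds append an independently permuted shadow copy of every feature, fit
a random forest (default 500 trees, sqrt(p) features per split, impurity
importance), and score a real feature a hit when it beats the best shadow.
Decisions are two-sided binomial tests against 1/2, Bonferroni-corrected
over the full feature family, taken from round 10 onward; undecided
features at exhaustion (max 100 rounds) stay tentative and are excluded.
Two details matter for calibration: the Bonferroni denominator stays fixed
at the initial family size, and every feature (decided or not) remains in
the forest with a full shadow set — shrinking either leaks false
confirmations by lowering the max-shadow bar over rounds.  Even so, the
per-seed zero-false-confirmation rate is bounded by the data, not the
algorithm: the most chance-correlated feature of a null dataset is
genuinely (if spuriously) informative in-sample, and an all-relevant
selector confirms it in a minority of seeds at any n.  The per-feature
false-confirmation rate sits near the configured alpha.

The outer loop splits samples 80/20 (stratified), repeats Boruta
`n_outer_repeats` times per pool with distinct derived sub-seeds, keeps
genes confirmed at least `freq_cutoff` times (default: every repeat — the
strictest reading), unions pools, and reports held-out nearest-centroid
accuracy on the selected genes.

## Expression statistics

Size factors are median-of-ratios over genes positive in all samples.
The DE test is a deliberately simple NB-Wald surrogate: per-gene
method-of-moments dispersions shrunk 50/50 toward an `a0 + a1/mean` trend,
Wald z on the log fold change with standard error from the NB GLM
information, a half-count prior per group against zeros, BH adjustment,
and the 2-fold + p ≤ 0.05 significance rule (alpha configurable; a
stricter 0.01 is used for large-cohort contrasts).  It is validated by
calibration (null type-I ≈ 5%, zero BH discoveries) and power (> 80% on
4-fold effects at n = 10/10), not by matching any published gene list —
those would require the external cohorts.  Genes with literally identical
counts in every sample are reported as non-differential by definition.

ssGSEA ranks a sample's genes descending (ties by gene id), weights set
members by |value|^alpha (default 0.75, the cited tool's documented
default; 0 gives a pure rank statistic) and sums the running difference
between the weighted in-set ECDF and the uniform out-of-set ECDF.  No
cross-sample normalization is applied by default.

The correlation screen keeps genes above FPKM 1 in ≥ 10% of the subtype's
samples, requires |R| > 0.3 with matching sign for Pearson AND Spearman,
and BH-adjusts each coefficient family separately (p < 0.05 in both); a
target failing its own expression filter is skipped with a warning.
Crosstabs report counts, integer-rounded column percentages and marginals.

ComBat (parametric empirical-Bayes location-scale, via scanpy) corrects
batch effects on log2(TPM+1).  EB shrinkage leaves per-gene noise-level
residual batch differences by design (≈ 0.11 mean absolute at n = 50 per
batch for a planted shift of 2 — matching the R reference implementation
to 2e-4) and is therefore only near-idempotent; a second pass moves values
by up to ~0.13 on such data.  Zero-variance genes pass through unchanged;
a single batch is a no-op; single-sample batches are an error.

## Known limitations

- The generator's shared dispersion and independent genes understate real
  biological correlation structure; recovery numbers on synthetic cohorts
  are upper bounds on real-data behavior.
- The homology statistic is sensitive to how "maximally separate" is
  operationalized; the S(k) purity score with nested cuts is one defensible
  choice among several.
- The DE surrogate does not implement full dispersion-shrinkage machinery
  and should not be used as a drop-in replacement for a production DE tool
  on real data.
- Cross-species ComBat under species-confounded biology distorts signatures;
  the pipeline assumes species correction happens where batch and biology
  are separable.
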