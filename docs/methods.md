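# Methods

`rankvec` re-implements, as a tested pipeline, the statistical workflow of a
2x2 factorial RNA-seq experiment: pre-natal and post-natal corticosterone (B)
exposure, crossed, in Japanese quail, with gene expression profiled in two
HPA-axis tissues (hippocampus, hypothalamus).  The four treatment groups are
named pre-natal letter first: CC, BC, CB, BB.  Each biological replicate is a
pool of four birds; there are three replicates per group per tissue.  All
analyses run per tissue, never pooled across tissues.

## Normalization and transformation

Raw counts are scaled per sample by the 75th percentile of the nonzero count
distribution (upper-quartile normalization), computed with linear
interpolation between order statistics.  `normalize` maps each sample onto a
fixed reference scale: value = count x 256 / Q75.  A fixed reference (rather
than a data-driven one such as the mean of sample quantiles) makes
normalization *exactly* invariant to multiplying any sample's counts by any
positive constant, which is the property the correction exists to provide;
no data-driven reference can satisfy it.  The reference 256 only sets the
common output scale and interacts with the additive offset below.
`upper_quartile_factors` separately reports dimensionless per-sample factors
centred to geometric mean 1, which is the conventional QC view of the same
quantities.

Normalized values are transformed as log2(value + 32).  The offset damps the
variance of low-count genes toward a constant and bounds the transformed
matrix below by log2(32) = 5.  A consequence worth knowing (it shapes the
category results): for a down-regulated gene whose normalized baseline is
below roughly 8x the offset — i.e. below the sample's upper quartile — the
*second* step of a cumulative (dose-dependent) response is strongly
compressed, so down-regulated cumulative genes are only recoverable when
highly expressed.  This is a property of the published transform, not of
this implementation.

PCA over samples (genes centred, not scaled) is provided for QC only and
feeds no downstream decision.

## Rank product differential expression

For a contrast with n1 and n2 samples, all K = n1 x n2 single-origin
pairwise differences (class1 sample minus class2 sample, log2 scale) form
the comparison columns.  Genes are ranked within each column — rank 1 the
largest difference for the "up" analysis, the smallest for "down", ties
broken deterministically to the lower gene index — and the rank product is
the geometric mean of a gene's K ranks.  Six contrasts run per tissue in a
fixed order: BC_vs_CC, CB_vs_CC, BB_vs_CC, CB_vs_BC, BB_vs_BC, BB_vs_CB.

Significance uses e-values: the expected number of null genes with a rank
product at or below the observed one, estimated from B = 1000 permutations
(configurable).  pfp (percentage of false positives, an FDR estimate) is
e-value / rank position, made non-decreasing along the ranking by a running
maximum so that a pfp threshold yields a coherent call set.  Genes are
called at pfp <= 0.10; a gene significant in both directions (pathological)
is assigned to the direction with the smaller pfp, ties to "up".

Two permutation nulls are implemented (`RunConfig.rp_null`):

* `"expression"` (default): gene labels are permuted independently within
  every sample column and the full statistic is recomputed.  This preserves
  the dependence between comparison columns that share a sample — with
  n1 = n2 = 3, the 9 columns contain only 6 independent samples — and is
  calibrated: on all-null simulations of 15 000 genes it yields ~0-1 calls
  per contrast, and the realised false-discovery proportion of its calls on
  planted data is well below the nominal 0.10.
* `"ranks"`: every column receives an independent uniform permutation of the
  ranks 1..G (the classical textbook null).  Because it ignores the shared-
  sample dependence it is roughly an order of magnitude anti-conservative
  for all-pairs comparison matrices (measured: ~5% of null genes called per
  direction at pfp <= 0.10).  It is retained because it is the null against
  which the statistic's small-sample behaviour can be checked exactly by
  enumeration, and for comparison with analyses that used it.

The expression-permutation null is computed by a compiled (numba) kernel.
For speed the *null* ranking uses a counting sort on expression values
quantized to 2^11 levels with mid-ranks on within-bin ties; observed
statistics are always ranked exactly.  Quantization perturbs null ranks by
at most a few units out of G, far below the Monte-Carlo noise of the
e-values (verified against a literal numpy implementation of the same
null).  The kernel draws its permutations from a dedicated xorshift64*
stream seeded from the caller's generator, so results are reproducible from
the master seed.  The two classes are processed in a canonical order,
making the up/down outputs of a contrast and its swap exact mirror images.

Mean log2 fold change is reported as the mean of the K pairwise differences
(on the offset-transformed scale).  `linear_fold_changes` additionally
reports the signed linear ratio of normalized class means (0.5 -> -2),
clearly labelled; no claim is made that either matches any particular
external convention, since fold changes can be computed before or after the
offset.

## Vector analysis

Each universe gene (union of genes significant in at least one of the six
contrasts) is represented in two Cartesian analyses:

* postnatal_response — response to post-natal B given the pre-natal
  environment: axis 0 = CB_vs_CC (carrier pre-natal background),
  axis 1 = BB_vs_BC (B pre-natal background);
* prenatal_response — axis 0 = BC_vs_CC, axis 1 = BB_vs_CB.

With n replicates per group each axis contributes n^2 between-replicate
log2 differences, and the gene's vectors are the full cross product of axis
pairs: (n^2)^2 = 81 vectors at n = 3.  Vsum is their componentwise sum;
|Vsum| (Euclidean norm) mixes effect size with replicate consistency, and
at n = 3 equals 81x the mean per-axis fold change for a perfectly
consistent gene.  The default |Vsum| threshold 40 therefore corresponds to
a mean consistent fold change of ~0.49 log2 units; the vector count is
recorded in the output so the threshold can be rescaled for other n.  An
optional mode sums unit-normalized vectors instead (pure consistency,
|Vsum| <= 81); it is off by default because vector length is meant to carry
magnitude information.

Significance is a permutation test on |Vsum|, B = 1000 label permutations
shared across genes within a round, p = (1 + #{permuted >= observed}) /
(B + 1).  Three schemes are available (`RunConfig.vector_null`):

* `whole_design`: the 4n involved samples are reassigned to the four group
  slots.  Fine-grained (12!/(3!)^4 = 369 600 arrangements at n = 3), but a
  purely additive gene (group values 0, s, s, 2s) is *structurally* unable
  to reach p <= 0.05 — permutations that concentrate its extreme values
  produce larger |Vsum| than the true arrangement in ~8.5% of cases even
  without noise — so cumulative responses would never pass the filter.
* `per_axis`: each axis's 2n samples are shuffled among themselves,
  independently.  This certifies additive genes (structural p ~ 0.004) but
  with only C(6,3) = 20 splits per axis its p floor at n = 3 sits at ~0.05,
  truncating genes whose response lives on a single axis.
* `combined` (default): Bonferroni combination p = min(1, 2 min(p_whole,
  p_axis)).  Both components are valid tests of the same null (gene values
  exchangeable across the involved samples), so the combination is valid
  (super-uniform under the null, checked by nested simulation), and
  together they have power for every response geometry the sector classes
  describe.

Filtered genes (|Vsum| >= 40 and p <= 0.05) are classified by the angle of
Vsum into eight 45-degree sectors centred on the four semi-axes and four
diagonals (both_up, only0_up, only1_up, opposite_0down_1up, ...); sector
boundaries lie at odd multiples of 22.5 degrees and are half-open
counterclockwise.  Genes failing either filter are "unchanged".

## Behavioural categories

The two class labels per gene combine into the factorial categories through
a data-driven rule table (editable TSV; defaults in
`rankvec.categories.DEFAULT_CATEGORY_RULES`):

| postnatal class | prenatal class | category | reading |
|---|---|---|---|
| only0_s | only0_s | I (s) | one exposure suffices; no further shift in already-exposed birds (common, non-additive) |
| both_s | both_s | II (s) | all four single-exposure fold changes share one sign (cumulative) |
| unchanged | both_s | III (s) | pre-natal-specific |
| both_s | unchanged | IV (s) | post-natal-specific |
| anything else | | none | mixed signs, opposite_*, only1_*, double unchanged |

The I-row follows from the category's definition: a gene equally shifted in
BC, CB and BB responds to each exposure only in the carrier-only other-stage
environment.  only1_* labels (response only in the already-B-exposed
environment) map to no category; they are logged as warnings for
inspection rather than silently merged.  Categories are mutually exclusive
and exhaustive over the universe, and I/II are disjoint by construction
(only0 vs both labels).

For synthetic runs, `truth_confusion` tabulates planted versus assigned
categories with a dedicated not-in-universe column.

## Synthetic data generator

Counts for gene g in sample j of group G(j) are negative binomial with mean
s_j * 2^(m_g + t_g + offset(g, G(j))) and size (dispersion) r:

* m_g ~ Normal(mu = 7, sd = 2) on the log2 scale — the typical gene near
  128 counts, i.e. a few million gene-assigned reads per library over
  15 000 genes, matching an early single-end sequencing depth;
* s_j ~ logNormal(0, 0.25): ~ +/-30% library-size spread, enough to
  exercise the upper-quartile normalizer;
* r = 25 by default: each emulated replicate is a pool of four birds, so an
  individual-level biological CV of ~0.4 (size ~6) drops to ~0.2 — pools
  are not simulated bird-by-bird because pooling only affects variance,
  which the dispersion absorbs;
* t_g ~ Normal(0, 2) is a per-gene between-tissue baseline shift (second
  tissue only), giving the strong tissue separation on PC1 that real brain
  regions show;
* offsets encode planted categories in (CC, BC, CB, BB) order:
  I (0, s, s, s), II (0, s, s, 2s), III (0, s, 0, s), IV (0, 0, s, s) with
  s = +/-delta, delta = 1.5 log2 units by default, 50 genes per category
  per sign (100 per category at the default 50/50 sign split).

Everything is drawn from one seeded generator; identical parameters and
seed give bit-identical output, and both tissues share the planted truth
but are sampled independently.

What the generator does not emulate: per-bird variation within pools, sex
or maternal-identity structure (the study pooled two males and two females
per replicate and avoided shared mothers), gene length or GC effects,
correlated gene modules, and count-level technical artefacts.  Passing
tests therefore demonstrate the statistical machinery under a clean
overdispersed count model, not robustness to every artefact of real
libraries.

## Pipeline, seeds, reproducibility

Each stage is file-based inside a run directory (counts.tsv, samples.tsv,
truth.tsv; per tissue: expr, pca, six rankprod tables, a Table-1-shaped
summary, two vector tables, assignments, a Table-2-shaped summary,
confusion).  `run-all` chains the same stage functions, so chained
subcommands and `run-all` are byte-identical.  One master seed derives a
substream per stage/tissue/analysis via SeedSequence over CRC32 tokens
(all derived seeds < 2^31), letting any single stage be re-run
reproducibly.  A manifest records the config snapshot, derived seeds,
SHA-256 checksums of all outputs, stage timings and the package version.

## Problem sizes used in validation

The statistical acceptance tests run the pipeline at the emulated study's
scale — 15 000 genes, four groups of three replicates, 1000 permutations —
with 20 seeded replicates each for the null-calibration,
category-recovery and absent-category specificity studies, and 100
planted instances for the power study; `scripts/acceptance.py` recomputes
the same quantities at the same per-run scale with fewer replicate seeds
(5-10) so a complete rerun stays desk-sized.  Exhaustive enumeration
oracles for the rank product run at up to 4 genes x 3 columns, where the
full null (all per-column rank permutations) is tractable.

## Known limitations

* Down-regulated cumulative (category II) genes below the upper quartile of
  expression are intrinsically hard to classify under the log2(x + 32)
  transform (see above); the recovery studies quantify this.
* Category I recovery at delta = 1.5 and n = 3 is materially lower than
  III/IV: a category-I gene carries signal on only one axis of each
  analysis, so its |Vsum| is ~sqrt(2) smaller than a II gene's and its
  combined permutation p sits closer to the threshold.
* The expression-permutation null assumes genes are exchangeable within a
  sample under the null; strong mean-variance structure is handled by the
  rank step, but gene sets with pervasive co-regulation still violate
  exchangeability in ways no within-sample permutation can capture.
* Absent categories are suppressed but not exactly zero: planting only
  categories I-III still yields a median of ~3 category-IV calls per
  15 000 genes across seeds, from sector-boundary noise on planted genes
  plus FDR-level false universe genes (the specificity study quantifies
  this).
* With n = 1 replicate per group the vector permutation test is vacuous
  (p = 1); the design validator flags groups with fewer than 2 replicates.
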