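# Methods

This note documents the models, defaults and numerical choices behind
`endotype`, and what the synthetic validation does and does not show.

## Responder definition and matching

Anti-proliferative response is the proportional Ki67 change
`pc = 100·(Ki67_2wk − Ki67_baseline)/Ki67_baseline` (percent; negative =
suppression). Eligibility requires ER+, HER2−, both paired Ki67 values,
and baseline Ki67 strictly above 10% — the strict inequality minimises
the imprecision of proportional falls from small baselines. Poor
responders are all eligible patients at or above the `1 − 0.15` sample
quantile of `pc` (linear-interpolation quantile; ties at the threshold
are all included and the realized fraction may exceed 15% slightly).
The good-responder pool is the eligible patients at or below the median
`pc`; GRs are drawn uniformly at random (seeded, `match_seed`) within
each baseline-Ki67 category — `[10,20)`, `[20,30)`, `[30,100]`,
half-open boundaries to avoid double counting — to match the per-category
PR counts 1:1. When a category pool is too small the whole pool is taken
and a warning issued. Random-within-category matching emulates categorical
matching without reimplementing any proprietary matching routine; the
1:1 ratio is exposed in `AnalysisConfig.match_ratio`.

ESR1 strata split at log2-normalized counts of 12; the boundary value is
assigned HIGH (a documented decision — the threshold itself is stated
only as "above and below"). Stromal TILs categories: low < 11%,
intermediate 11–59%, high ≥ 60% (boundary 60 assigned high). Plasma
estradiol above 130 pmol/L is excluded from correlation analyses as not
plausibly postmenopausal; the exclusion is strict (`> 130`).

## Calibrated intrinsic subtyping

Samples are called LumA / LumB / HER2e / Basal by correlating their
centered PAM-gene profile with per-subtype centroids. Classification uses
Spearman rank correlation by default (standard for PAM50-style calls and
invariant to any strictly monotone per-sample transform); Pearson is a
config switch. The call is the argmax correlation, ties resolve to the
fixed subtype order with a flag, `confidence` is the maximum correlation,
and constant profiles are flagged unclassifiable. Only the four subtypes
above are called; no Normal-like centroid is used.

Two centering strategies are implemented:

* **Naive baseline** (`naive_median_centering_calls`): per-gene
  whole-cohort median centering against row-median-centered centroids.
  With a composition-skewed cohort the cohort median is pulled towards
  the prevalent subtypes, which biases the calls — measurably so for the
  LumA/LumB axis.
* **Random-subset calibration** (`calibration_search`): each iteration
  draws k uniform in [5, 15], k reference-called study samples, a
  training subset exactly matched to the composition of those reference
  calls, and proposes `centering = mean(study subset) − mean(training
  subset)` per gene. Because the biological content of the two subsets
  matches in expectation, the difference estimates the per-gene platform
  offset. All reference samples are re-called after centering and the
  vector with maximal concordance to the reference calls wins (ties:
  higher mean assigned-centroid correlation, then earliest iteration).
  Inside the search the subsets are compared by their means, while the
  naive baseline uses medians — both as documented above. The random
  stream is consumed strictly per iteration, so runs are reproducible and
  the best concordance is non-decreasing in `n_iter` for a fixed seed.
  The study-side k-subset is drawn from the reference-called samples
  (the only samples whose reference subtype is known, hence the only
  self-consistent choice). A per-gene offset added to the study matrix is
  absorbed exactly by the centering vector, leaving calls invariant.

Default `n_iter` is 50,000 — on synthetic cohorts the concordance argmax
is stable far below the millions of iterations the procedure supports,
and a run takes seconds; larger values are a config away. In the fast
path the per-iteration Spearman uses ordinal ranks (double argsort,
stable, ties broken by gene order); expression values are continuous so
this coincides with average-rank handling except on measure-zero ties,
and the public `centroid_correlate` uses exact average ranks.

Centroids are supplied as a genes-by-subtypes table; the package bundles
no published centroid values. The synthetic generator's truth centroids
serve for testing, and any user-supplied PAM50-style TSV loads the same
way. The `confidence` value is a correlation, and the conventional 0.95
"high confidence" threshold is exposed without asserting equivalence to
any assay-specific probability.

## Signature scoring

ssGSEA: genes are ordered by descending expression (ties broken
deterministically by gene identifier); walking that order, the score
accumulates the difference between the weighted in-set ECDF — weights
`rank^alpha` with ascending average ranks, `alpha = 0.25` — and the
uniform out-of-set ECDF. The exponent and rank normalization follow the
method's reference implementation; both are configurable. Optional
cohort normalization divides by the overall score range.
`score_matrix` drops sets whose overlap with the expressed genes falls
outside `[min_size, max_size] = [5, 2000]`.

Preranked GSEA uses the weighted Kolmogorov–Smirnov statistic (weight
`|stat|`), a gene-permutation null drawing random sets of the same size,
`NES = ES / mean(|null ES| of the same sign)`, and a same-sign one-sided
permutation p floored at `1/(n_perm+1)`, BH-adjusted across sets.
Immune/TME collections are consumed as ordinary GMT gene sets scored by
ssGSEA; no curation is reimplemented.

H/I is the difference of log2-normalized *HOXB13* and *IL17BR* values —
a log-ratio. Published means for this score on other platforms use an
unspecified normalization, so only the direction (higher in poor
responders) is comparable, and the generator encodes exactly that.

## Differential expression

A deliberately simplified NB workflow, not a clone of any package:
median-of-ratios size factors (reference = geometric mean over genes
positive in all samples) rescaled to geometric mean 1; log2 values are
`log2(count/factor + 1)`. The expressed-gene filter keeps genes with CPM
above `min_count / median library size × 1e6` in at least the smallest
group size of samples and total count ≥ 15.

The test fits per-gene NB GLMs (log link, size-factor offsets, one mean
per group, Newton iterations vectorized across genes). Gene-wise
dispersion is profile maximum likelihood over a 40-point log-spaced grid
(1e−4 to 10) with a Cox–Reid adjustment (−½ log of the per-group expected
information), shrunk on the log scale half-way toward a trend
`a0 + a1/mean` fitted by Huber robust regression. The Wald statistic is
the group log-mean difference over its expected-information standard
error. Genes with an all-zero group receive a 0.5-count continuity
offset (spread over the group's samples) so both the reported LFC and
the test are finite; without it the Wald information degenerates. There
is no outlier handling, independent filtering or LFC shrinkage — the
design is validated by simulation calibration: at 20 vs 20 samples with
10,000 null NB genes the p < 0.05 rate is within 0.05 ± 0.01, and genes
spiked at log2FC = 2 (dispersion 0.05) are detected at FDR < 0.05 with
power above 0.9. BH adjustment is the standard step-up with enforced
monotonicity.

## Genomic alterations

Somatic filters are conjunctive: VAF ≥ 0.05, alternate reads ≥ 5,
high/moderate consequence, population allele frequency < 1e−5 (null AF
passes — absent from population databases). A per-rule removal log is
returned. Per-gene group comparison is a mutated-vs-wild-type Fisher
test per gene (min 3 mutated samples overall to avoid degenerate
tables), BH across tested genes. TMB is retained mutations per tumour
compared by Mann–Whitney.

Copy-number segments (0-based half-open internally; SEG files are
1-based inclusive) are thresholded at log2 ratio ±0.2 (inclusive) —
common single-copy-sensitivity defaults, configurable, standing in for
unpublished HMM state criteria and flagged as an approximation. Calls
are projected onto 3-Mbp bins tiling hg38 autosomes by majority overlap
(ties → neutral; uncovered bins flagged and excluded from tests); each
bin × direction is a Fisher test, BH across all of them. Chromosomal
instability is the length fraction of a sample's covered genome with a
non-neutral call, invariant under segment splitting. Compound TP53
status requires ≥ 1 retained TP53 mutation and ≥ 1 loss-called segment
overlapping the TP53 locus (default chr17:7,668,421–7,687,490, hg38 gene
body, configurable). No purity/ploidy correction is applied.

## Statistical primitives

Two-sided Fisher exact sums hypergeometric point probabilities ≤ the
observed one (with 1e−7 relative slack) — the R-style convention, which
reproduces the printed clinical-table p-values; it is tested against
exact-rational enumeration for every table with margins ≤ 12.
Mann–Whitney uses exact enumeration for ≤ 8 per group without ties,
otherwise the tie-corrected normal approximation. Spearman is Pearson on
average ranks with the t-approximation. The hypergeometric overlap test
is upper-tail `P(X ≥ overlap)`. The group summary table tests each
categorical level as level-vs-rest 2×2 with unknowns excluded (this
construction reproduces the published grade-G2 p-value of 0.002) and
continuous covariates by Mann–Whitney.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Per sample: intrinsic subtype from a configurable composition
(default 45/40/8/7% LumA/LumB/HER2e/Basal — a luminal-skewed ER+HER2−
population); a latent immune score N(0,1); TP53 mutation (24%);
ESR1-low membership at a population rate of 5% distributed across
subtypes with non-luminal weighting (after responder selection about a
third of PRs and almost no GRs are low, matching the published
post-selection composition). Resistance is Bernoulli with logit =
intercept + 3.0·ESR1low + 1.0·HER2e + 1.5·Basal + 1.0·TP53mut +
0.8·immune; the intercept is solved numerically (Brent) on the realized
cohort so the marginal resistant fraction hits its 0.15 target —
mirroring the poor-responder selection fraction. Proportional Ki67
change is uniform(−100, −80) for sensitive and uniform(−48, +184) for
resistant tumours, spanning the published response ranges;
`Ki67_2wk = baseline·(1+pc/100)` clipped to [0, 100], with baselines
from per-subtype clipped lognormals.

Expression: 50 PAM genes take centroid values built from shared latent
axes (ER, proliferation, HER2, basal programs, scale
`centroid_separation = 1.0` log2 units) so that subtype centroids are
realistically correlated — LumA and LumB differ mainly on the
proliferation axis; independent per-subtype draws would make subtypes
implausibly separable and hide the composition bias the calibration
corrects. ESR1 is a two-component mixture (modes 13.5 / 9.5, clearly
across the threshold-12 analogue); an immune program (40 genes) scales
with the immune score; an oestrogen-response program (30 genes) scales
with log plasma estradiol; *HOXB13* is shifted +0.5 in resistant
tumours. Sample noise is N(0, 0.6); study counts are NB with dispersion
0.05 around `library × 2^log2-expression`, matching the mean–variance
assumptions of the DE stage. The balanced training set is noise-only
(microarray-like) on the centroid platform; the study matrix adds a
per-gene N(0, 0.8) platform offset to the PAM genes, recorded in truth.
Reference calls emulate an orthogonal assay: true subtype with a
configurable per-sample error rate.

Estradiol is lognormal (median ≈ 15 pmol/L) with a −0.4 log shift in
resistant non-ESR1-low tumours and a 1% implausibly-high outlier rate to
exercise the exclusion rule. TILs are zero-inflated Beta on [0, 60)
pushed up by the immune score; the upper category never occurs, as in
the study data, and the distributional form is a modelling choice — the
source only fixes category boundaries. Mutations: configured per-gene
driver prevalences (PIK3CA 35%, TP53 24%, CDH1/KMT2C/GATA3 10%, …)
whose rows pass the somatic filters by construction, plus
Poisson-distributed artifact rows each assigned a failure mode
(sub-threshold VAF, < 5 alt reads, low consequence, common population
AF) so the filters are exercised without disturbing the configured
marginals; non-TP53 drivers carry a marginal-preserving 1.5× rate ratio
in resistant tumours, reproducing the higher burden of poor responders.
Copy number: per-chromosome random segmentation with 10%/10% gain/loss
states (1.5× in TP53-mutant tumours), a dedicated TP53 segment losing a
copy with probability 0.35 (0.75 if resistant) and a dedicated chr6q
segment (covering the *ESR1* region) gained with probability 0.10 (0.35
if resistant).

All draws flow from `SimConfig.seed` through named child streams, so a
config reproduces its cohort bit-for-bit.

### What passing tests show — and what they do not

The synthetic validation demonstrates internal correctness and parameter
recovery: selection, matching and stratification implement their
definitions; the calibration search recovers cross-platform centering
that beats naive median centering under composition skew; the DE test is
calibrated; enrichment structure configured into the generator (resistant
fraction, TP53 compound rates, mutation burden) is recovered by the
analysis. It does not show that real FFPE RNA-seq noise, batch structure
beyond a single per-gene platform shift, isoform effects, subclonality or
purity variation are handled — none of those are simulated — and
published effect magnitudes that depend on unavailable patient data
(e.g. exact DE gene counts, H/I score means on other platforms) are not
reproduced, only their directions.

## Validation problem sizes

The shipped benchmarks use desk-scale sizes chosen to make the studies
routine to re-run: 20 cohorts of n = 300 (59 reference calls, 3% label
error, 50,000 calibration iterations) for the calibrated-vs-naive
comparison, 10,000 null and 500 spiked genes at 20 vs 20 samples for DE
calibration, and one n = 400 cohort for the end-to-end run; the
reproduction script uses 8 cohorts for the calibration study.
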