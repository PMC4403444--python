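# Methods

This note documents the models behind corego, the defaults that matter, the
design choices made where the procedure was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Count model and normalization

Counts are modelled as negative binomial with the edgeR-style
parameterization var = mu + phi * mu^2; phi = 0 degenerates to Poisson. This
convention is used everywhere: the generator, the dispersion estimator and
the exact test.

TMM scaling factors follow the published algorithm. The reference sample is
the one whose 75th-percentile library-scaled count is closest to the mean
75th percentile. Per sample-vs-reference pair, genes with zero counts in
either member are excluded; M values are trimmed 30% from each tail and A
values 5% from each tail (rank-based, ties averaged); the factor is the
inverse-variance-weighted mean of the surviving M values with weights
1/[(N_k - y_k)/(N_k y_k) + (N_r - y_r)/(N_r y_r)]; factors are rescaled to
geometric mean 1. The implementation reproduces edgeR's `calcNormFactors`
to 1e-6 on a fixture (cross-checked through Rscript in the test suite).
Note that exact invariance to rescaling a single sample's counts holds for
M, A and the trimming but not for the precision weights, which retain a
mild depth dependence — factors move by a few percent under a 7x depth
change.

CPM uses TMM-effective library sizes (raw library x factor) everywhere,
including the expressed-gene filter; the alternative (raw libraries for the
filter) is not offered, to keep a single convention. Percentiles and
quantiles throughout the package use linear interpolation between order
statistics (numpy default, R type 7).

Quantile normalization maps each column's sorted values onto the
across-column mean of sorted values; tied input values receive the mean of
the reference values their positions span, which makes the transform
idempotent.

## Differential expression

**Expressed filter.** A gene is expressed when its mean CPM exceeds 1 in at
least one condition; the comparison is strict, so CPM exactly 1 everywhere
is not expressed.

**Single-replicate caller.** log2FC = log2(CPM+1)_trt - log2(CPM+1)_ref on
condition means; DEG iff |log2FC| > 0.58 (= log2 1.5, rounded to two
decimals, the package default). The lincRNA caller is the same rule
restricted to genes annotated lincRNA.

**Exact test.** After scaling counts to the geometric mean of the effective
library sizes (rounded to integers — the conditional argument requires
exchangeable libraries), the conditional law of the group-A total given the
pooled total is negative hypergeometric with shapes n_a/phi and n_b/phi,
independent of the mean; for phi = 0 it is Binomial(total, n_a/(n_a+n_b)).
The two-sided p sums the conditional probabilities of all outcomes at most
as probable as the observed one (minimum-likelihood rule), with a 1+1e-12
relative gate absorbing float round-off of exact ties. The log-pmf is
evaluated in a symmetric grouping so equal group sizes give bitwise
symmetric p-values under group swap.

**Common dispersion.** A single phi maximizes the conditional
log-likelihood of each gene's replicate vector given its condition total,
summed over genes and replicated conditions, on equalized libraries —
conditional maximum likelihood without edgeR's quantile adjustment. A
bounded 1-D search over [1e-6, 4] is used; estimates at the lower boundary
report 0. On simulated data the estimator recovers phi = 0 to < 0.02 and
phi = 0.2 within [0.1, 0.3] at 2000 genes, 2 vs 2.

**Median-ratio test.** lmr = log2((median CPM_trt + c)/(median CPM_ref + c))
with pseudocount c = 1 on the CPM scale, mirroring the log2(x+1) transform
used for fold-changes. Its null pools, across all genes, the lmr values of
every informative relabeling of the samples into groups of the original
sizes — for 2 vs 2, the 2 informative partitions of the 3 distinct ones
(identity and mirror excluded). Gene-wise nulls from 2 partitions would be
useless alone; only pooling yields the resolution a global effect cutoff
needs. The per-gene p is the two-sided add-one empirical p, never 0, and
its floor is 1/(pool size + 1).

**Combination.** Both p-values are converted to one-sided in the direction
of the observed lmr sign (the exact test's half-p flipped when its effect
sign disagrees), mapped to normal scores and combined as
Z = (z_exact + z_lmr)/sqrt(2 + 2*rho), with rho the correlation of the
signed scores estimated across genes; the combined p is reported two-sided.
The denominator is the one deliberate departure from a textbook
equal-weight Stouffer: the exact test and the median-ratio test score the
same group difference on the same counts, and their signed scores correlate
at ~0.995 on null simulations. With the independent-test denominator
sqrt(2), the combined test's null rejection rate at alpha = 0.05 is ~0.17;
with the dependence-adjusted denominator it is ~0.05 (Hartung-style
combination of dependent tests). Under planted effects rho absorbs some
signal correlation, making the adjustment mildly conservative; measured
recovery (below) is unaffected in practice.

**Calling.** DEG iff combined p < 0.05 and |lmr| >= cutoff, direction =
sign(lmr). The default cutoff is the mean of the magnitudes of the pooled
null's 2.5th and 97.5th percentiles. The literal arithmetic mean of those
two percentiles is ~0 for any symmetric null, so the magnitude reading is
the only one that yields a usable positive effect bound; the cutoff is also
user-overridable. On the default synthetic conditions this cutoff lands
near 0.95 — the pooled null mixes low-expression genes with large median-
ratio noise, so it sits well above the planted effect floor only for weakly
expressed genes.

## Concordance statistics

Fisher's exact test is two-sided by the minimum-likelihood rule and
evaluated in exact rational arithmetic (integer binomial coefficients), so
tie comparisons cannot be flipped by float rounding; it matches independent
enumeration to 1e-12 on an exhaustive scan of all 2x2 tables with N <= 40.
Quadrant classification requires |log2FC| > 0.58 in BOTH comparisons; the
2x2 of response signs is what the test sees. Set-overlap fractions are
reported as integer percentages rounded half away from zero (16/54 ->
30%), with an upper-tail hypergeometric p. The over-representation scan is
a plain hypergeometric test with the p < 0.1, count >= 3 retention rule —
deliberately not DAVID's jackknifed EASE variant.

Average-linkage clustering runs on distance 1 - r via scipy; ties break
deterministically by label order.

## Promoter ChIP enrichment

Reads with MAPQ > 5 (strict) that are uniquely aligned are retained;
uniqueness in BED input is proxied by the MAPQ filter because public BED
exports carry no explicit flag (multi-mappers receive MAPQ <= 1 under
common aligner conventions). The normalization library size is the
post-filter retained count — the library actually counted. Promoter
windows are [tss-2500, tss+500) on +, mirrored on -, clipped at 0; a read
counts for every window it overlaps by >= 1 bp, strand-agnostically, and a
read spanning two promoters counts in both. Enrichment is
(RPM_IP + 1)/(RPM_ctrl + 1); the 1-RPM pseudocount keeps zero-control
promoters finite and is exposed as a flag. Binned profiles sort genes by
anchor log2 enrichment descending (ties by gene id), cut consecutive
500-gene bins (last bin may be short) and average log2 enrichment per bin;
the anchor's bin means are non-increasing by construction and asserted on
every run.

## Synthetic data: what it emulates and what it does not

The expression generator plants DEGs with known log2 effects (default
magnitude 1.5, up/down with equal probability) into NB counts with
log-normal baseline means (meanlog = ln 200, sdlog = 1 — a realistic
abundance profile for genes that survive a CPM > 1 filter) and dispersion
0.1; the paper-scale default DEG fraction is 0.25 per perturbed condition.
Two depletion conditions share sign-concordant DEGs under `shared_fraction`:
each first-condition DEG is forced into the second condition with that
probability, and the second condition's exact quota is filled uniformly at
random — 0 gives independent DEG sets, 1 a superset. lincRNA genes receive
the same abundance model as coding genes and differ only by biotype flag.

The ChIP generator plants bound promoters (Bernoulli, default 20%) with a
fixed IP rate multiplier (default 8) over a Poisson background (default 20
reads/promoter) and places reads uniformly in the window. Each factor gets
its own control sample: factors measured in different experiments do not
share control noise, and a shared control demonstrably leaks correlation
into the binned co-binding profile. A co-factor copies the anchor's bound
status with probability rho and draws independently otherwise.

Not emulated: batch effects, gene-length bias, fragment-size structure,
read sequences, peak shape, graded (non-binary) binding affinity. Two
consequences matter for interpreting the benchmarks:

* With a single shared WT reference and one replicate per condition, the
  estimated log2FCs of two comparisons are positively correlated even
  without any shared regulation — the WT sample's noise enters both with
  the same sign. Quadrant-concordance null calibration therefore holds at
  the level of planted true effects, not of single-replicate estimates;
  quadrant p-values computed from single-replicate designs overstate
  concordance generally.
* Because binding is binary, genes sorted by anchor enrichment form a
  step-shaped profile (bound block, then a flat tail whose order is pure
  noise). The bin-index Spearman correlation of a perfectly co-bound
  factor is therefore bounded near -0.7 regardless of noise level; values
  like -0.95 arise only from graded co-varying affinity (as in real data)
  or from shared-control leakage.

## Problem sizes and numerical choices

Benchmarks run at 2000 genes (expression; 2 vs 2 or three single-replicate
conditions) and 20000 promoters (ChIP), sizes at which every statistic is
stable yet the full suite runs in well under a minute per check. The
exact-test oracle scans are exhaustive (pooled sums <= 60; all 2x2 tables
with N <= 40). Dispersion search tolerance is 1e-6; Stouffer inputs are
clamped to the open unit interval with a warning; empirical p-values use
the add-one convention; all quantiles are linearly interpolated.

## Known limitations

Common dispersion only (no tagwise/trended); no covariate designs; no
multiple-testing correction beyond the combined-p + effect-cutoff rule the
procedure itself defines; BAM/FASTQ input, peak calling and fragment
modelling are out of scope. The permutation-derived effect cutoff depends
strongly on the expression mix in the pooled null and should be inspected
(it is reported with every run) before being relied on.
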