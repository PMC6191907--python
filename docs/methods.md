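# Methods

## Decay model and fitting

After transcription initiation is blocked with rifampicin, transcript
abundance is modeled as first-order decay, N(t) = N(0)·2^(−t/t½). The
observable is the averaged log₂ ratio y_t of the t-minute sample to the
pre-rifampicin reference, so under the model y_t = −t/t½. We fit y_t
against t by ordinary least squares **with a free intercept** and do not
add a synthetic (0, 0) anchor: the fit uses only measured ratio points,
and an intercept absorbs residual array-level offsets. The coefficient
of determination is R² = 1 − SSres/SStot; when SStot = 0 (a flat
profile) R² is undefined and the gene is censored as non-decaying.

Gating: a fit is accepted if R² > 0.7 (strict inequality) and the slope
is negative. Genes failing on all four time points (2, 5, 10, 15 min)
are refitted on {2, 5, 10}: a short-lived transcript reaches the
array's detection floor before 15 min, which flattens the last point and
destroys an otherwise clean line. Genes missing any of the three early
time points are unresolved. Nonnegative slopes are censored, not
reported as infinite half-lives, and censored/unresolved genes are
excluded from all summaries. The decay math is in log base 2
throughout; t½ = −1/slope is base-consistent with the normalization.

Reported half-lives are rounded to 0.1 min in output tables; all
internal arithmetic (operon means, summaries, correlations) uses the
unrounded values. Published operon tables in this field show the same
convention: operon means computed from unrounded member values can
differ in the last digit from the mean of the printed (rounded) member
values, which is why the operon output carries both the rounded and
unrounded mean.

## Array normalization

Spot quality: Flags ≥ 0 AND (F635/B635 ≥ 3 OR F532/B532 ≥ 3). The OR is
deliberate — the reference channel carries the undecayed t0 sample, so a
gene decayed below noise in the test channel still yields a usable,
strongly negative ratio. A zero background with positive foreground
counts as passing that channel. The filter is monotone in the
foreground intensities.

Normalization: the 1:1 spike-in controls are exogenous RNAs added in
known equal amounts to both samples, so their true ratio is 1 and their
measured mean log₂ ratio estimates the array's dye/scale bias. The
factor f = 2^(−mean log₂ r) over passing control spots multiplies every
ratio on the array; afterwards the controls' mean log₂ ratio is 0 by
construction (asserted to 1e−9). Arrays with no passing control spot
are rejected with a diagnostic rather than silently passed through.

Replicates are averaged on the log₂ scale (a geometric mean of ratios):
this makes the average invariant under dye swap of any replicate, which
an arithmetic mean of linear ratios is not. A (gene, timepoint) needs
only one passing replicate to enter the profile; the replicate count is
recorded so stricter reanalyses can refilter. Ratios that are zero or
negative after background subtraction are dropped per spot, and the
count of dropped spots is reported per array.

## Group statistics

The one-way ANOVA is computed from the sum-of-squares decomposition
(F = (SSB/dfB)/(SSW/dfW), p from the F distribution) rather than
delegated, so its definition is explicit and testable against an
independent implementation. The post-hoc test is a one-sample two-sided
t-test of each category against the global mean treated as a fixed
constant — the comparison asked is "does this category differ from the
overall average", not "do two samples differ"; a two-sample variant is
out of scope. The Bonferroni multiplier m is the number of categories
actually tested (n ≥ 2 members with accepted estimates), and adjusted
p-values are capped at 1. Zero-variance groups are flagged degenerate
with p ∈ {0, 1} instead of raising.

Abundance correlations use log₁₀(FPKM) over genes with FPKM > 0 by
default, since transcript abundance spans orders of magnitude and is
conventionally plotted on a log axis; raw-scale correlation is available
via a flag. FPKM itself is count · 10⁹/(length · library size) with the
library size taken as the sum of gene-assigned fragments (not raw
reads); the uniquely-mapped/≤1%-mismatch filters are properties of the
upstream count generation recorded as provenance.

## rRNA fragmentation calling

The mapper is intentionally naive: a full-length, ≥ 99%-identity
placement rule realized as a brute-force scan of every offset on both
strands, accepting ≤ floor(0.01 · read length) mismatches, keeping
minimum-mismatch placements and breaking ties uniformly at random with
a seeded generator. Bacterial rRNA gene copies are near-identical, so
multi-mapping is the norm rather than the exception; random single
placement keeps per-copy coverage comparable while remaining
reproducible. Indels, base qualities and partial alignments are out of
scope.

Region calling: the locus mean coverage C̄ includes the low-coverage
positions themselves (a literal reading of "average gene coverage");
called regions are maximal runs of positions with depth strictly below
0.05·C̄, in 1-based inclusive coordinates (1140–1159 spans 20 nt), with
no merging across interruptions. A position at exactly the threshold is
never called. An all-zero track is degenerate (no meaningful mean) and
returned as a single flagged whole-locus region. Cross-copy comparison
groups regions whose start and end each differ by ≤ 2 nt, labelling
groups shared (in every copy) or unique.

## Synthetic data

The generators define the study conditions: 4 time points {2, 5, 10,
15} min, 3 replicates with dye swap on the even replicate, 32 spots per
1:1 spike-in control, half-lives log-normal with median 5.7 min and
log-sd 0.4 (matching the global scale such experiments report),
baseline abundances log-normal (median 2000 intensity units, log-sd 1)
over a background of mean 50 so the S/N ≥ 3 filter actually removes
weak spots. Channel model: foreground = level + background, with the
array's scale factor (log-normal, log₂-sd 0.25) applied to the Cy5
channel and independent multiplicative noise (default log₂-sd 0.15, an
engineering choice — the original arrays' noise magnitude is not
published) applied to the test-sample level. The quoted ratio of
medians is therefore exact in the noiseless limit, which gives the
end-to-end identity used in testing: with zero noise and no bad spots,
estimated half-lives equal truth to floating point.

rRNA reads are sampled uniformly among start positions whose full span
avoids every planted gap, so gaps are exactly the zero-coverage runs of
the truth track; substitution errors are opt-in (default 0) to keep
mapper checks exact. Consequences for interpretation: coverage ramps
toward gap edges and locus ends mean read-derived calls recover planted
gaps only to within read_length − 1 at the boundaries, while directly
constructed tracks are recovered exactly. The generators do not emulate
scanner saturation, spatial artifacts, print-tip effects, quality-score
variation or fragment-length distributions, so passing recovery tests
demonstrates correctness of the estimators under the stated noise
model, not robustness to every real-array pathology.

## Problem sizes

Default test and demonstration sizes — 300-gene simulations for noisy
recovery (median relative error < 5% at log₂ noise 0.1), 2000-simulation
null calibration of the ANOVA (type-I error 5% ± 1%), reference loci of
0.5–2.7 kb with a few thousand reads — are chosen so the full suite
runs in well under a minute while leaving the Monte-Carlo checks
statistically meaningful.

## Known limitations

- The half-life model assumes a single exponential phase; delayed-onset
  decay, biphasic decay and transcripts with residual synthesis are not
  modeled.
- The Excel-era provenance of the original analysis leaves two details
  undecidable from the text (whether an implicit t0 point entered the
  fit, and whether replicate averaging was on the linear or log scale);
  this implementation uses no t0 anchor and log-scale averaging, with
  the averaging scale configurable.
- One published region length ("1717–1770, 55 nt") is internally
  inconsistent with inclusive arithmetic (54 nt); the caller reports the
  inclusive length and leaves the discrepancy documented rather than
  special-cased.
- The naive mapper is quadratic and meant for rRNA-scale references
  (kilobases), not genomes.
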