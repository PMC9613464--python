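# Methods

This note documents the models behind each stage, the tunable parameters
and their defaults, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Single-hit limiting-dilution estimation

Model. Each animal injected with dose *d* engrafts independently with
probability *p(d) = 1 − e^(−f d)*: engraftment requires at least one
active (stem) cell, active cells are Poisson-distributed across the
graded doses, and activity is a cell-autonomous property. The
log-likelihood over assay rows (dose *dᵢ*, tested *nᵢ*, responders *rᵢ*)
is ℓ(f) = Σ rᵢ log(1 − e^(−f dᵢ)) − (nᵢ − rᵢ) f dᵢ.

Estimation. The score in θ = log f is strictly decreasing on the
interior, so the MLE is a bracketed Brent root of the score equation
(xtol 1e−14); the starting bracket comes from the pooled closed form
−ln(1 − r/n)/d over rows with 0 < r < n, else from the overall negative
fraction. With a single informative dose the fit reduces to the closed
form exactly (tested to 1e−10 relative). Assays in which no animal or
every animal responded have no interior maximum and are returned with
`boundary_flag` "zero" / "infinite" and no interval rather than a forced
number.

Confidence bounds. The default 95% interval is Wald on log f using the
*expected* Fisher information, I(θ) = Σ nᵢ (f dᵢ)² e^(−f dᵢ)/(1 − e^(−f dᵢ)),
which is the information a complementary log-log GLM fit by Fisher
scoring reports; a profile likelihood-ratio interval is available via
`ci="lrt"`. Denominators are rendered to one decimal ("1/286.4").
Intervals are reported as (lower-frequency denominator, upper-frequency
denominator), the lower frequency being the larger denominator.

Calibration caveat. At small, near-saturated designs the outcome space is
tiny and discrete: the handful of finite-MLE outcomes that carry almost
all probability mass produce intervals that cover the truth, so the
finite-MLE-conditional coverage of any ~95% interval sits above nominal
(≈ 0.98–0.99 at an 18-animal four-dose design). `lda_coverage_sim`
reports this coverage together with the boundary-replicate count and the
median denominator so the behavior is visible rather than hidden.

## Subclonal copy-number detection

The procedure assumes a *reference* sample in which the clone of interest
is dominant, and a *query* in which it may be present at fraction φ, so
each amplified segment's bulk signal is attenuated to
(1 − φ)·CN_base + φ·CN_sub. Reference segments are projected onto the
query's binned track by bin-midpoint containment (0-based half-open
coordinates; bins outside all segments are counted and excluded, and bin
totals are conserved). Adjacent segments are compared by two-sample
Wilcoxon rank-sum: exact null distribution when both sides have ≤ 25 bins
and no ties, otherwise the normal approximation with tie and continuity
correction; two constant identical samples return p = 1 by convention.
Tests are two-sided with raw per-pair p-values and stars (p < 0.05 *,
< 0.01 **, < 0.001 ***); no multiple-testing correction is applied by
default because per-pair stars are the reported quantity, and a
Bonferroni pass can be layered on by the caller.

Region verdict. The reference's own segment means define an expected
up/down/flat direction per adjacent pair (flat when the means differ by
≤ 0.25 copies). A pair is concordant if its query test is significant at
α = 0.05 *and* steps in the expected direction; the region is "detected"
when the concordant fraction among non-flat pairs reaches 0.75. The 0.75
threshold and the direction-matching rule are this package's
formalization of an otherwise qualitative judgment; both are parameters.

Segmentation stand-in. When no external segmentation (e.g. an HMM-based
caller) is supplied, a deterministic binary segmentation with Gaussian
cost is used: a split is accepted while the reduction in within-segment
sum of squares exceeds a penalty, default 2σ̂² log n with σ̂ estimated
robustly from the median absolute successive bin difference. This is a
stand-in for read-depth-aware segmentation, adequate because the
downstream rank tests only need boundary positions, not segment means.

Gain/loss thresholds: segment mean < 1.5 → loss, > 2.5 → gain, boundary
values neutral.

## CORE discovery and group discrimination

Null model and threshold. For a sample with *P* peaks spanning extent *G*
on a chromosome, uniform placement makes the start-to-start span of *k*
consecutive peaks distributed as G·Beta(k−1, P−k+2) (a difference of
uniform order statistics). Every run of *k* consecutive peaks
(2 ≤ k ≤ 20 by default) receives this left-tail p-value, and runs with
p ≤ α/m (α = 0.05, Bonferroni over the m = P−k+1 runs of that order)
qualify. Qualifying runs are accepted greedily in ascending p-value —
ties broken by larger order, then smaller span, then coordinate — with
runs overlapping an accepted CORE skipped. Ordering by evidence rather
than by order matters: a high-order window that merely *contains* a tight
cluster plus stragglers is less improbable than the cluster itself and
must not swallow it, and a window containing two distinct clusters must
lose to both. An elbow-style alternative (`threshold="knee"`: the point
of maximum distance below the chord of the ascending sorted span curve)
is provided for comparison; on an exchangeable background the sorted span
curve is convex, which makes the elbow permissive, so it is not the
default.

Catalog and detection. Per-sample COREs are union-merged across samples
by single linkage on ≥ 1 bp overlap; a sample detects a catalog CORE iff
one of its own called COREs overlaps it by ≥ 1 bp (a reciprocal-overlap
fraction is configurable). The predictability coefficient of a catalog
CORE is the balanced accuracy of "detected ⇒ positive group",
PC = (freq₊ + (1 − freq₋))/2, so PC = 0.5 whenever the two group
frequencies are equal and 1 at perfect separation; ranking breaks PC ties
by descending |freq₊ − freq₋| then coordinate. Member-CRE accessibility
uses consensus members (union-merged member intervals of contributing
samples) and any-overlap against each sample's peaks. CORE names render
1-based inclusive ("CORE-chr9-2014811-2032652" style) while all
computation stays 0-based half-open.

## Stemness scores

All three scores take a log-scale expression column; no normalization is
performed here, so input should already be library-size- and
log-normalized.

* Correlation score: Spearman ρ (average-rank ties) between the sample
  and a reference profile over their shared signature genes; ≥ 3 shared
  genes required, missing genes are reported by name. Invariant under any
  strictly increasing transform of the sample.
* Weighted score: Σ wᵢxᵢ over signature genes; unweighted signatures use
  unit weights; missing genes either fail (default) or drop with the
  score over the present genes.
* Enrichment score: genes ranked by descending expression (stable order
  on ties); the running sum steps up at signature genes by
  (N − i + 1)^τ-weighted increments normalized to total 1, and down by
  1/(N − n) elsewhere; the score is the sum of the N running-sum values.
  τ defaults to 0.25; τ = 0 gives the unweighted walk, under which the
  complement of a half-size signature scores exactly the negative. This
  is a running-sum single-sample statistic in the ssGSEA family, not a
  Kolmogorov-Smirnov-style variance-adjusted score: absolute values
  differ from GSVA's, while the group contrasts the scores exist to
  measure are preserved.

`score_hierarchy` evaluates all three per sample and reports, per score,
whether group medians strictly decrease along the declared
stem-to-mature tier order (None when fewer than two tiers are present).

## Synthetic data: what it emulates, and what it does not

Defaults mirror the study conditions the pipeline was designed around:
41 LSC+ and 52 LSC− samples; an active-cell frequency of 1/286.4 with
the 30,000/7,500/1,875/469-cell, 3/4/6/5-animal dilution design; one
discriminative planted CRE cluster (7 CREs of 300 bp, 2 kb gaps) carried
by 75% of LSC+ vs 20% of LSC− samples among five group-balanced decoy
clusters on a 10-Mb synthetic chromosome with 5 background peaks/Mb; a
φ = 0.3 amplification ladder (+3 copies, Gaussian bin noise SD 0.3,
500-kb segments at 1-kb bins); and a four-tier expression hierarchy
(1,000 genes, 20 signature genes, effect size 1.0, noise SD 0.5, five
samples per tier) mirroring a CD34/CD38-style sort. Values not fixed by
the study (background peak rate, peak width, genome length, decoy count,
samples per tier) were chosen once as realistic desk-scale magnitudes
and are exposed as parameters.

Generator structure. Dilution assays draw per-dose binomials at the
single-hit probability. Copy-number bins are Gaussian around the clone
mixture mean — no GC waves, mappability structure or long-range
autocorrelation, which the rank-based tests are robust to but which real
read-depth data contain. Peak atlases use uniform-start fixed-width
Poisson background — the simplest exchangeable null for cluster calling —
with no chromatin-domain clumping, peak-width variation or signal
strengths. Expression tiers add per-signature-gene effects whose
magnitudes span 0.5–1.5× the effect size (mean exactly 1×), scaled by a
tier multiplier decreasing linearly 1 → 0 from stem to mature; the
heterogeneous magnitudes give the stem-like profile a *shape* that
resembles the reference, so rank-correlation scoring has signal, not just
the mean-shift that the weighted score reads. Passing tests therefore
demonstrate correctness of the procedures under their stated assumptions,
not robustness to the artifacts of real ATAC/WGS/RNA-seq data.

Reproducibility. All randomness flows from one root seed through
SeedSequence spawning with a fixed child index per stage (dilution 0,
copy-number 1, peaks 2, expression 3), so stages are independently
reproducible and identical (seed, config) pairs give byte-identical
files; the pipeline manifest hashes every output to make this checkable.

## Problem sizes

The shipped validation runs use desk-scale sizes chosen to estimate each
quantity to useful precision: 1,000 simulated assays for estimator
calibration, 500 random instances (n, m ≤ 8) for the exact rank-sum
cross-check, 50 atlases of 93 samples for planted-CORE recovery, 2,000
adjacent pairs for null calibration and 100 ladders for detection power,
and 5 expression hierarchies for the tier contrasts.

## Known limitations

* The limiting-dilution model is single-hit with per-animal Bernoulli
  responses: no multi-hit kinetics, heterogeneity in f across animals, or
  overdispersion.
* The predictability coefficient is one defensible formalization
  (balanced accuracy of presence ⇒ group); alternative discrimination
  scores (odds ratios, Fisher p-values) would rank differently near ties.
* The CORE null assumes exchangeable peak placement within a chromosome's
  observed extent; strong large-scale accessibility gradients would
  inflate calls, and the span test ignores peak widths (start-to-start
  spans).
* Wilcoxon adjacent-pair tests treat bins as independent; autocorrelated
  read-depth noise would make the effective sample size smaller than the
  bin count.
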