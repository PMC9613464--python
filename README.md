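# lsckit

Quantitative procedures for characterizing a leukemia-stem-cell (LSC)
driven AML hierarchy: limiting-dilution stem-cell frequency estimation,
subclonal copy-number detection, discovery of clusters of cis-regulatory
elements (COREs) that discriminate LSC+ from LSC− fractions, and
single-sample stemness signature scoring. It is written for researchers
who work with functionally sorted AML fractions (xenograft-validated
LSC+/LSC− populations) and want the downstream statistics of that kind of
study as reusable, tested code.

Because the primary datasets for such studies are access-restricted, the
package includes a first-class synthetic-data generator that reproduces
the statistical structure each stage assumes, so every procedure can be
exercised, calibrated and power-tested end to end without any downloads.

## The statistics

**Limiting-dilution analysis** (`lsckit.lda`). Graded cell doses *d* are
transplanted into cohorts of mice; under the single-hit Poisson model the
engraftment probability is *P(d) = 1 − exp(−f·d)* with *f* the per-cell
LSC frequency. The MLE of *f* (equivalently a binomial GLM with
complementary log-log link and log-dose offset) is found by a bracketed
1-D score solve; Wald confidence bounds on log *f* use the expected Fisher
information *I(log f) = Σ nᵢ(f dᵢ)² e^(−f dᵢ)/(1 − e^(−f dᵢ))*, with a
profile-likelihood interval as an option. Frequencies are reported as
denominators ("1 in N cells"). Degenerate assays (no responders anywhere /
every animal responded) are flagged instead of fitted.

**Subclonal copy-number detection** (`lsckit.cnv`). A minor clone at
fraction φ shifts a bulk copy-number segment by only φ·ΔCN. Segment
boundaries from a reference sample in which the clone is dominant (e.g. a
cultured derivative) are projected onto the query's 1-kb binned track by
bin-midpoint containment, and each pair of adjacent segments is compared
with a two-sample Wilcoxon rank-sum test (exact null when both sides have
≤ 25 bins and no ties, normal approximation with tie correction
otherwise; stars at p < 0.05 / 0.01 / 0.001). A region is called
subclonally detected when ≥ 75% of the non-flat adjacent pairs are
significant in the reference's up/down direction. A Gaussian-cost binary
changepoint segmenter (BIC-style penalty) stands in when no external
segmentation is supplied, and segment means are thresholded into
loss (< 1.5) / neutral / gain (> 2.5) calls.

**CORE discovery and discrimination** (`lsckit.cores`). COREs — dense
clusters of accessible-chromatin peaks, analogous in spirit to
super-enhancer stitching — are called per sample: under a uniform
placement null, the span of *k* consecutive peaks out of *P* scales as
Beta(k−1, P−k+2), and runs whose span p-value clears a
Bonferroni-corrected α = 0.05 are accepted greedily, most improbably
tight first. Per-sample COREs are union-merged into a catalog; each
catalog CORE gets a presence/absence profile across samples and a
**predictability coefficient** — the balanced accuracy of the rule
"detected ⇒ LSC+": PC = (freq₊ + (1 − freq₋))/2 — which ranks COREs by
how well they separate the two groups. Member-CRE accessibility
frequencies per group are reported for any CORE of interest.

**Stemness scoring** (`lsckit.stemness`). Three per-sample scores from a
log-scale genes × samples matrix: Spearman correlation to a reference
profile over signature genes (the LSC104 procedure), a fixed weighted sum
Σ wᵢxᵢ (the LSC17 procedure; weights supplied externally as GMT/TSV),
and a rank-based single-sample running-sum enrichment score (ssGSEA-style,
τ = 0.25 default). `score_hierarchy` scores a whole sorted-fraction
hierarchy and checks that group medians decrease from stem-like to mature
tiers.

## Worked example

Fit the single-hit model to the bundled 12-week dilution series
(30,000 cells: 3/3 engrafted; 7,500: 4/4; 1,875: 6/6; 469: 4/5):

```bash
$ lsckit lda --assay tests/data/table2_assay.csv
{"f_hat": 0.0034916651518691316, "denom_hat": 286.39630563219606, "ci_denom": [803.9183955097269, 102.02881827049549], "se_log_f": 0.5266021408415279, "boundary_flag": "none"}
lower_frequency	estimated_frequency	upper_frequency
1/803.9	1/286.4	1/102.0
```

The estimated LSC frequency is 1 in 286.4 cells, with a 95% interval from
1 in 803.9 (lower frequency) to 1 in 102.0 (upper frequency): roughly one
cell in every three hundred of this fraction can initiate a graft.

The full synthetic pipeline — dilution assay, copy-number ladder, 93-sample
peak atlas, four-tier expression hierarchy — runs with:

```bash
lsckit run --outdir out/ --seed 1
```

and prints a manifest hash that is identical across reruns with the same
seed and configuration.

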