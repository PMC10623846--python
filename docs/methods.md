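# Methods

## Model

The package treats a bulk methylation measurement as a purity-weighted
mixture. With tumor-cell fraction *f* and per-CpG signals *s*ₜ (tumor) and
*s*_b (non-neoplastic background), the expected observed signal is

    E[observed] = f·sₜ + (1 − f)·s_b.

For a heterozygous, copy-number-neutral driver mutation, *f* = min(2·VAF, 1),
so driver VAF measured by NGS is an objective proxy for specimen purity, and
tumor cellularity is reported as min(2·VAF·100%, 100%). A truly methylated
tumor (*s*ₜ well above the assay cutoff, *s*_b well below) crosses the
positivity threshold only when *f* exceeds
(cutoff − *s*_b)/(*s*ₜ − *s*_b); below that purity the assay returns a
false negative. All cohort-level analyses quantify where that transition
sits on the VAF axis.

## Assay call rules

- **Pyrosequencing**: score = arithmetic mean of the per-CpG methylation
  percentages (the 4-CpG clinical assay); POSITIVE iff score ≥ cutoff.
  Default cutoff 10.0% (clinical convention); 7.28% is available because the
  original array-model validation used it. All comparisons are inclusive.
- **Methylation array**: the MGMT-STP27 logistic model,
  logit(p) = β₀ + β₁·M(cg12434587) + β₂·M(cg12981137), with the published
  coefficients (4.3215, 0.5271, 0.9265) and probability cutoff 0.358 shipped
  in `src/vafqc/data/mgmt_stp27.json`; any coefficient set can be supplied
  via JSON/YAML. The *MGMT* score is the logit of the predicted
  probability; it is computed as the linear predictor itself, which is
  algebraically identical and finite even where the probability saturates in
  floating point. An optional symmetric equivocal band around the
  probability cutoff yields EQUIVOCAL calls; its default halfwidth is 0
  (binary calls) because no published equivocal criterion exists.
  M = log₂(β/(1−β)) converts beta values; a log₂((meth+α)/(unmeth+α))
  helper (α = 1) covers raw intensities.
- **ddPCR**: POSITIVE iff percent methylated template ≥ 4.0%.

## Cumulative curves and cutoff detection

Samples are ranked by increasing VAF (stable sort, ties broken by sample
id) and the running mean positivity — or running mean/median score — is
computed over every prefix. Only the value at the final index of a block of
tied VAFs is invariant to within-tie ordering; this caveat is documented on
the curve type. EQUIVOCAL and QNS samples are excluded (with a warning),
never folded into NEGATIVE.

**Fisher-exact cutpoint scan.** Candidate cutpoints are midpoints between
consecutive distinct VAFs, so ≥/< assignment is unambiguous; each candidate
must leave at least `min_per_side` (default 5) samples on each side. For
each candidate a 2×2 table (at/above vs below × positive vs negative) is
tested with the two-sided Fisher exact test (probability-mass-summation
convention, via scipy); the optimal cutpoint minimizes p, ties toward the
smallest cutoff. The minimal p is an optimized statistic; no
multiple-testing correction is applied, and every output labels it as raw.

**Two-part regression changepoint.** Every distinct curve VAF with at least
`min_seg` points on each side is tried as a split; OLS lines are fitted to
the low and high segments and the split maximizing the signed slope
difference (low − high) wins, ties toward the smallest split. Two
conventions matter and are deliberate:

- *The split point lies on both segments* (low: VAF ≤ split; high:
  VAF ≥ split). The knee of a hinge is the last point of the rising limb
  and the first point of the plateau; excluding it from the high segment
  makes the candidate one grid step below the knee tie with the knee and
  the tie-break would then report a systematically early split. With the
  shared-point convention a noiseless hinge is recovered exactly.
- *Adaptive segment floor*: `min_seg` defaults to max(3, 15% of the curve).
  The slope of a k-point segment spanning Δx of the VAF axis has standard
  error ∝ σ/(Δx·√k); with only 3 points at fine grid spacing that error
  dwarfs the true slope contrast and the exhaustive argmax latches onto
  noise at the curve ends. At 15% per segment, knee recovery on the noisy
  hinge benchmark (knee 0.20, 200 points, noise sd 0.02) is 88–95% within
  ±0.05 across seeds; at 3 it is 0%. `min_seg` remains a parameter.

Degenerate segments (all-identical x) are skipped as candidates. A constant
segment (zero y-variance) gets slope 0, R² 0, p 1 — the no-variance-explained
convention; R² is not defined as 1 there even though the fit is perfect.

## Purity discrepancy

For samples with a microscopic cellularity estimate, the difference
(microscopy − VAF-based, percentage points) is regressed on VAF. Under the
generator's bias model (below), microscopy overestimates at low purity and
the difference-vs-VAF slope is negative.

## Risk flagging and rate arithmetic

A sample is flagged iff its call is NEGATIVE and its driver VAF is below the
subtype-specific cutoff. Two default sets ship: regression-derived
(GBM 0.18, astrocytoma 0.325, oligodendroglioma 0.30) and scan-derived
(0.115 / 0.325 / 0.405); every report names the set used. Flagged samples
carry a recommendation for orthogonal re-testing (array and/or ddPCR). The
cohort-level false-negative-rate estimate is the product
(fraction of samples below the cutoff) × (methylation prevalence), shown to
one decimal as a percent.

## Synthetic cohort generator

`simulate_cohort` draws, per sample: subtype (mix 0.68/0.21/0.11), true
methylation ~ Bernoulli(prevalence 0.35/0.70/0.96 by subtype), VAF ~
0.5·Beta(α, β) with subtype means 0.34/0.38/0.39, f = min(2·VAF, 1). Four
per-CpG tumor signals are Normal(μ_meth = 30 or μ_unmeth = 3, σ_signal = 8);
one shared background draw Normal(μ_bg = 2, σ_signal) per sample makes sites
correlate through purity. Observed sites are the mixture plus
Normal(0, σ_noise = 2) measurement noise, clamped to [0, 100] (clamping, not
resampling — it slightly biases means near the bounds). The pyrosequencing
score is the site mean, called at 10%. Microscopic cellularity is
100·f + 30·(1 − f) + Normal(0, 8), clamped — the +30·(1−f) term encodes
microscopy's overestimation at low purity; the noise sd of 8 percentage
points reflects the subjectivity of visual estimates. With these constants
a truly methylated sample crosses the 10% cutoff near f ≈ 0.29 (VAF ≈ 0.14)
in the noise-free limit, placing the positivity knee in the VAF 0.15–0.20
range.

The generator emulates: the subtype mix, subtype-specific methylation
prevalence and VAF scale of a realistic glioma cohort, and the dilution
mechanism. It does **not** emulate: intratumoral methylation heterogeneity,
copy-number alterations at driver loci, array/ddPCR measurement physics
(only the pyrosequencing arm is simulated at signal level), assay batch
effects, or any real cohort's signal parameters — all constants are design
choices, so passing tests demonstrate correctness of the pipeline's
behavior under the dilution model, not estimates of clinical performance.

Helpers: `make_hinge_curve` (piecewise-linear curve with optional Gaussian
noise, clipped to [0, 1]; the changepoint benchmark) and `make_step_cohort`
(uniform VAFs with positivity 0.10 below / 0.60 above a step at VAF 0.20 by
default; the cutpoint-scan benchmark — a pronounced step, since the scan's
localization accuracy is what is being exercised).

## Numerical choices

- Fisher odds ratio is the conditional sample ratio a·d/(b·c), ∞ when
  b·c = 0 and a·d > 0, NaN when both vanish.
- Mann-Whitney uses the exact null for small untied samples and the
  tie-corrected normal approximation otherwise; t-tests are unpaired,
  equal-variance; all p-values two-sided.
- Changepoint ties are detected with a 1e-9 (scaled) tolerance on the slope
  difference before the smallest-split tie-break, so exact ties are not
  resolved by float jitter.
- Cohort files: UTF-8, tab- or comma-delimited auto-detected from the
  header; enum tokens case-insensitive on read, uppercase on write; missing
  optionals are empty strings, never zeros; floats written with `repr` so
  read∘write is the identity. QNS samples are retained in tables but
  excluded from every downstream statistic.
- Problem sizes used by the test suite and acceptance script — 20 seeds at
  n = 2000 for the dilution gradient, 20 seeds at n = 500 for scan
  recovery, 200-point curves for changepoint recovery — are chosen so each
  check is decisive at desk scale (Monte-Carlo error well under the margins
  asserted) while the whole suite runs in well under a minute.

## Known limitations

- Subtype cutoffs ship as fixed constants; they are cohort-derived values,
  not universal biology, and should be re-derived (scan + changepoint) on
  local data before clinical interpretation.
- The scan's minimal p is not a calibrated significance level.
- VAF-based purity assumes heterozygosity and copy-number neutrality of the
  driver; gliomas violating that (e.g. *TERT*-locus gains) will mislead both
  the purity estimate and the flag rule.
- The STP27 confidence interval is not computed, only the point probability
  and its logit.
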