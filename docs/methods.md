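# Methods

## The analysis pipeline

One row per infant carries six clinical covariates — age at blood collection
(AaBC, integer hours), gestational age (GA, weeks), birth weight (BW, g),
sex, reported race/ethnicity set, TPN status — and 41 MS/MS analyte
concentrations. The pipeline:

1. **Exclusions.** Records with unknown AaBC or collection outside 12–168 h,
   BW outside 1,000–5,000 g, or GA outside 28–42 weeks are removed; when TPN
   filtering is enabled, TPN-positive and TPN-unknown records go too. Each
   dropped record is attributed to the *first* rule it violates, in the
   fixed order aabc → bw → ga → tpn, so exclusion tallies are reproducible
   (published analyses report only the final cohort size). All interval
   endpoints are inclusive on integer units; fractional collection ages are
   floored on ingest (whether registry timestamps are floored or rounded at
   window boundaries is unknowable from published window labels; flooring is
   a fixed convention here).
2. **Reference restriction.** AaBC comparisons use term infants
   (GA 37–41 wk) with BW 2,500–4,000 g (bounds inclusive) and TPN "no",
   removing the strongest known confounders of analyte levels.
3. **Binning.** Two systems: ten fine windows 12–17, 18–23, …, 60–65,
   66–72 h (reference 12–17 h) for trajectory profiling, and three coarse
   categories early 12–23 h / standard 24–48 h / late 49–168 h (reference
   standard) for screening-performance analysis. The early category is
   exactly the union of the first two fine windows.
4. **Effect sizes.** Cohen's *d* (pooled-SD form, no small-sample
   correction — the plain statistic is the field's convention for these
   group sizes) of every analyte in every non-reference bin. |d| > 0.2
   (strict) flags an AaBC-related difference; 0.5 marks a strong one.
5. **Clustering.** Rows of the fine-bin d-matrix are grouped by complete-
   linkage agglomerative clustering on Euclidean distance, cut at two
   clusters; the cluster with the lower mean terminal-bin d is labelled
   "decreasing". Linkage and metric are a fixed, recorded choice (published
   heatmaps rarely name theirs); single-linkage chains poorly separated
   profiles, so complete linkage is the default. Missing cells are imputed
   by within-row linear interpolation for clustering only, never for
   reported d values.
6. **Trajectory smoothing.** E[level | AaBC] per covariate stratum by a
   Gaussian GAM: cubic B-spline basis (15 functions spanning 12–168 h,
   boundary knots pinned to the window) fitted by penalized IRLS
   (statsmodels `GLMGam`), with the penalty weight chosen by minimising GCV
   over a 13-point log-spaced grid from 1e-4 to 1e8. Pointwise 95% bands
   use the normal approximation to the estimated mean. Fits are refused
   below 200 records (sparse late-collection strata produce unstable
   smooths). Stratum contrasts average the fitted-mean difference over an
   hour window; the p-value comes from a Welch t-test on the *raw* records
   inside the window, not on the smoothed curves, whose neighbouring points
   are strongly dependent.
7. **False-positive performance.** Per disease, FP counts per category are
   compared to E_i = N·π_i with π_i the screen-negative window shares
   (90,060 / 305,674 / 19,135 for the packaged published table). Overall
   Pearson chi-squared (df 2, warning when any E < 5) plus a per-window
   two-cell proportion test (df 1, no continuity correction) against the
   fixed share π_i — the negative cohort is ~3 orders of magnitude larger
   than any FP series, so treating π as fixed is numerically
   indistinguishable from the 2×2 test. Significance tiers 0.05/0.01/0.001;
   no multiple-testing correction by default, matching screening-table
   convention.

## Expected-count rounding

`expected_counts` computes exact, total-conserving expectations by default;
these feed every test statistic. Published screening tables derive their
expected cells from window shares *as reported at one decimal percent*
(21.7/73.7/4.6%), which changes one borderline cell (a 7.518 under exact
shares becomes 7.498 ≈ 7 under reported shares); `share_decimals=3`
reproduces that reporting convention, and the table report uses it. Display
integers round half away from zero.

## Consistency calls

A marker running high among screen-negatives in a window should inflate
false positives there when the disease is flagged by an *elevated* marker
and deflate them when flagged by a *decreased* marker, so the predicted
sign of O − E is `sign(d) × (+1 elevated / −1 decreased)`. The call is
**consistent** when the observed deviation has the predicted sign and the
window test rejects at 0.05; **inconsistent** whenever the deviation runs
against the prediction — significance is recorded but not required, because
a deficit where physiology predicts an excess contradicts the hypothesis
regardless of whether a tiny FP series can reach significance;
**indeterminate** when |d| ≤ 0.2, the deviation is zero, or the predicted
direction holds without significance (typically a small FP series). This
rule reproduces every qualitative mark in the packaged published table,
including the small-sample indeterminates.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular registry's marginals.

- **Trajectories.** Three parametric templates on 12–168 h: exponential
  decay to a plateau, saturating rise, and a quadratic dip with recovery.
  Amplitudes are parameterised in units of the analyte's own SD
  (`amp_sd × base × cv`) so effect sizes between windows are directly
  interpretable. The default 41-analyte panel assigns decreasing shapes to
  most amino acids and hydroxylated/dicarboxylic acylcarnitines, increasing
  shapes to short/medium straight-chain acylcarnitines, and dips to free
  carnitine, leucine-isoleucine and C5 — the qualitative cluster structure
  of real panels. Bases are plausible µmol/L-scale values; units are
  abstract (published tables give none).
- **Covariates.** GA is categorical over 28–42 wk (~5% preterm), BW normal
  around a GA-dependent mean, ~51% male, race/ethnicity category weights
  roughly matching a large US program (Hispanic 50%, White 26%, Asian 15%,
  Black 7%, other 2%) with 30% multi-category reports, and TPN rates of
  12.1% (preterm) vs 0.45% (term). Covariates act multiplicatively on the
  mean as additive offsets on the log scale in log-SD units — the simplest
  mechanism producing parallel stratified separations. Covariate effects
  are constant over AaBC; crossing trajectories seen for some real analytes
  are not emulated.
- **Noise.** Multiplicative lognormal with mean one (ε ~ N(−σ²/2, σ²),
  σ² = log(1+cv²)), default cv 0.25 — keeps concentrations positive and
  right-skewed. With cv c the value SD equals mean × c exactly.
- **Planted effects.** `plant_effect` adds `delta_sd × mean × cv` to values
  whose AaBC falls in the chosen category, *after* the noise draw, so the
  planted group keeps the reference SD and downstream Cohen's d recovers
  `delta_sd` exactly in expectation for a flat-trajectory analyte
  (multiplicative planting would bias d by ~delta²·cv). Stacked plants add.
  Values are floored at 1e-9 to preserve strict positivity under large
  negative plants (floor probability ~3e-5 at delta = −1, cv = 0.25).
- **Collection times.** Hour-level categorical weights: linear ramp through
  the early window, broad peak near 30–36 h, geometric tail through the late
  window, with category masses 21.7/73.7/4.6% matching a large program's
  reported shares.
- **False positives.** Per disease a multinomial over the three windows
  (default totals and shares from the packaged published table), hours
  uniform within window, covariates drawn inside the reference ranges.
- **Seeding.** One global seed expands into independent sub-streams
  (covariates, metabolite noise, FP table) via `SeedSequence.spawn`;
  identical config + seed is bit-identical.

What passing tests on these cohorts do **not** show: recovery of any real
registry's effect sizes or FP rates (those are data-dependent), robustness
to AaBC-correlated covariates (the generator draws them independently), or
behaviour under assay drift, batch effects and truncated/censored
measurement — none of which are simulated.

## Calibration and problem sizes

- Planted-effect recovery and null calibration use flat-trajectory analytes
  at 100,000 records split evenly between the early and standard windows
  (the default panel's AaBC-dependent trajectories make d(early, standard)
  nonzero by design, so the null condition is the constant shape). Sampling
  error of d at 50,000 per group is ~0.006 SD.
- Chi-squared type-I error is estimated over 2,000 null multinomial tables
  of 200 cases each.
- Band coverage is measured pointwise on the integer grid 12–168 h over 200
  cohorts of 5,000 records drawn with the default collection-time weights
  and a covariate-free decaying analyte; mean coverage of the nominal 95%
  band runs ~95% (GCV's mild undersmoothing offsets smoothing bias; single
  sharp-curvature cohorts can dip to ~75%).
- Cluster recovery uses 20 decaying and 21 rising templates with staggered
  amplitudes and time constants at 30,000 records.

## Known limitations

- The per-window proportion test treats the screen-negative shares as
  fixed; for FP series within two orders of magnitude of the negative
  cohort the 2×2 test should be preferred.
- The GAM bands are pointwise, not simultaneous; they understate
  curve-wise error.
- The consistency rule reconstructs a published qualitative convention;
  alternative reconstructions (e.g. requiring significance for
  inconsistency) change calls only for non-significant mismatches.
- No handling of multiple births, transfusions, or repeat specimens.
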