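# Methods

This note documents the models, conventions and numerical choices behind
`mirpanel`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

The generator (`mirpanel.cohort`) draws a longitudinal serum-marker
cohort with the structure the analysis assumes.

**Design.** 91 CRC patients: 71 with chronological perioperative sampling
(preop, then scheduled visits at 1, 3, 6, 12 and 24 months) and 20
sampled only preop + 1 month ("paired" arm); 71 healthy controls sampled
once; 13 recurrence cases among the chronological arm. Scheduled
postoperative visits are attended with probability 0.71 (preop and the
recurrence-detection visit are always attended). This missed-visit rate
is the value at which the *expected* totals match the design this
package targets — about 323 chronological samples from 71 patients
(71 × 6 = 426 scheduled draws, so some visits were necessarily missed)
and about 434 samples overall. Realized totals fluctuate by seed and are
reported in the truth record rather than forced.

**Tumor burden.** Burden is normalized to 1 preoperatively and drops to a
residual (default 0) after resection. Recurrence times are
Normal(15.6, 7.4) months truncated at ≥ 4 months. For recurrence cases
the burden regrows exponentially from 5% of detection level starting 9
months (configurable lead) before clinical recurrence, reaching
detection level (1.0) at the recurrence time. Recurrence subjects keep
scheduled visits up to the recurrence time and get one unscheduled blood
draw *at* recurrence detection — clinically, the recurrence work-up
includes a blood draw, and without it the sparse visit grid (not marker
behavior) would dominate whether re-elevation is observable.

**Signals.** Each regular probe has a log2 baseline ~ Normal(7, 1.5).
Twelve planted markers add `effect_size × burden` (default 2.5 log2 units
per unit burden — a deliberately strong, clearly-detectable effect;
real serum effect sizes are smaller) plus residual noise (SD 0.5 log2).
Batches (4, assigned by chunking samples in accrual order) apply an
additive location shift (SD 0.3) and a multiplicative scale (SD 0.05) on
the log2 scale — exactly the location/scale family the ComBat model
removes. Raw linear signals are `2^x` plus an additive optical background
(log2 ~ Normal(4, 0.4)); negative-control probes are pure background
draws, independent of group. A hemolysis confounder (5% of samples, +2
log2 on one planted marker) models hemolysis-susceptible miRNAs.

**Reference markers.** CEA-like and CA19-9-like columns are log-normal
with a weak burden coupling, calibrated so the fixed clinical cut-offs
(5.0 ng/mL, 37.0 U/mL) land near the operating points conventionally
reported for these markers (CEA ≈ 38%/95%, CA19-9 ≈ 15%/90%
sensitivity/specificity): `ln CEA = ln 2 + 0.75·burden + N(0, 0.55)`,
`ln CA19-9 = ln 10 + 0.27·burden + N(0, 1.02)`.

**What the generator does not emulate:** adjuvant-therapy effects, stage
or tumor-location substructure, age/sex covariates, probe cross-
hybridization, and realistic (weaker, heterogeneous) marker effect
sizes. Passing tests therefore demonstrate that the pipeline's selection
logic and statistics behave correctly under its assumed model, not that
any particular marker set would validate clinically.

## Preprocessing conventions

* Detection threshold: per sample, mean + 2·SD (sample SD, ddof = 1) of
  negative controls after removing `floor(n·0.05)` values at each rank
  extreme; probes must *strictly* exceed the threshold.
* Background subtraction happens on the linear scale, with log2 applied
  afterwards, because the floor rule is defined on the log2 scale.
  "Lowest signal on the array" is read as the per-sample minimum of
  successfully subtracted log2 values (the rule replaces per-array
  missing values); undetected and non-positive probes are floored at
  that minimum − 0.1 so the matrix stays rectangular.
* Quantile normalization maps each sample onto the cross-sample mean of
  sorted values; ties receive the mean of the reference quantiles they
  span. With ties present, the "all sorted columns identical" property
  holds only approximately (tied blocks are averaged), and exact
  idempotence holds only for tie-free columns.
* Batch adjustment is the parametric empirical-Bayes location/scale
  model: per-probe standardization against the batch-size-weighted grand
  mean and pooled variance, per-batch location/scale estimates shrunk
  toward cross-probe priors by the standard iterative posterior solution
  (convergence 1e-4, capped at 500 iterations), then adjust and restore.
  A single batch is returned unchanged (there is nothing to remove, and
  the shrinkage machinery would only inject estimation noise). On
  noise-free constructed inputs the cross-probe spread of the estimates
  is floating-point jitter, so degeneracy is detected *relative* to the
  estimate magnitudes and shrinkage is skipped. Note the EB shrinkage
  moves batch locations slightly, so per-probe grand means are preserved
  exactly only when shrinkage targets equal the estimates (e.g. uniform
  batch offsets). The implementation agrees with `sva::ComBat` to
  ~1e-15 on noisy two-batch data.

## Cascade conventions

* All phase tests are one-sided ("greater") rank-sum tests by default:
  upregulation is a directional claim, and a one-sided α = 0.05 test
  gives the expected α pass rate for null probes (a two-sided test plus
  direction filter would give α/2). A median-direction filter is kept as
  a guard; Benjamini–Hochberg correction is available behind a flag but
  off by default (raw p < 0.05 is the selection rule).
* The discovery phase defaults to the unpaired test with a paired
  signed-rank option, since the preop/1-month samples are in fact
  paired.
* "Higher than at any postoperative point" is operationalized as one
  pooled test per timepoint (all must pass), not per-patient
  monotonicity.
* Re-elevation is formalized as a cut-off-crossing rule: per marker, the
  cut-off is the minimum corner-distance point of the ROC on
  tumor-bearing vs tumor-free samples; a recurrence subject is flagged
  when some postoperative sample at or before the recurrence time is
  above the cut-off after an earlier postoperative sample was below it;
  the marker survives at a flagged fraction ≥ 0.5 (configurable). Both
  parameters are logged in the phase result.
* Phases only test survivors of the previous phase, so survivor sets are
  nested by construction; an empty set short-circuits the remaining
  phases with warnings instead of raising.

## Statistical primitives

* Rank-sum: exact null distribution when both n ≤ 8 and the pooled data
  are tie-free; otherwise the tie-corrected normal approximation with
  continuity correction. One-sided exact/asymptotic agreement at n = 8
  is ≲ 0.0055 in p; two-sided doubling makes it ≲ 0.011.
* Signed-rank: exact sign-pattern enumeration up to 10 nonzero pairs
  (average ranks for tied |differences| are enumerated exactly); normal
  approximation beyond.
* McNemar: exact two-sided binomial for ≤ 25 discordant pairs,
  chi-square with continuity correction beyond; p capped at 1.
* ROC: thresholds at midpoints between adjacent distinct pooled scores
  (± infinity endpoints); AUC is the pairwise-comparison estimate with
  ties counted ½. Cut-off selection minimizes the distance to the
  (0, 1) corner, with ties broken toward higher specificity, then higher
  threshold — favoring the confirmatory-test use of these markers.
* Paired AUC comparison: DeLong placement-value covariance estimate and
  a two-sided z-test; identical score vectors (zero variance of the
  difference) return p = 1 with a degenerate flag.

## Panels and evaluation

* Fisher weights `w = S⁻¹(μ₊ − μ₋)` with equal-prior midpoint centering
  define the 0 threshold of the diagnostic index; an index of **not less
  than 0** is tumor-bearing (boundary inclusive). Pooled covariances with
  condition number > 1e12 raise a fit error naming the collinear
  members; such panels are skipped (and logged) in the exhaustive
  search.
* Best panels are chosen by training AUC, per exact size, ties broken
  lexicographically; the leaderboard also reports the running best over
  sizes ≤ k, which is nondecreasing by construction. No cross-validation
  is applied by default, so leaderboard AUCs are apparent (optimistic)
  AUCs — on label-permuted data the best-panel AUC centers above 0.5 by
  exactly this selection optimism.
* Raw markers classify positive at value **>** cut-off (clinical
  exceedance rules); panels classify at index **≥** cut-off (the index
  rule is inclusive at 0). Reference markers always use their fixed
  clinical cut-offs and are never auto-optimized.
* Timelines report each chronological subject's ordered values against a
  cut-off; a recurrence lead time is the recurrence time minus the
  earliest postoperative time above the cut-off (single crossing by
  default; a sustained-window length is configurable). A lead of 0
  means the first crossing was at the recurrence-detection draw.

## Problem sizes and determinism

Unit and property tests run on a scaled-down cohort (30 CRC / 24
controls / 6 recurrences, 160 probes) that keeps the full design shape;
the acceptance-grade checks use the full default design (91/71/13, 2555
probes) over 20-seed ensembles and n = 2000/class for the Gaussian
discriminant check. All randomness flows from a single seed through
named sub-streams (`numpy` `SeedSequence.spawn`), and pipeline artifacts
are content-hashed in the run manifest; reruns with the same
configuration are byte-identical.

## Known limitations

* Selection-phase p-values are uncorrected by design; the cascade's
  false-discovery control comes from requiring consistency across
  phases, not from multiplicity adjustment.
* Training AUCs are optimistic; the optional subject-level evaluation
  splits are not enabled by default to mirror the analysis this package
  reproduces.
* The re-elevation criterion depends on the visit grid: with sparse
  scheduled visits and no recurrence-detection draw, a truly re-elevating
  marker can be missed for purely observational reasons.
* The exact-test size thresholds (n ≤ 8 rank-sum, n ≤ 10 signed-rank,
  ≤ 25 discordant McNemar) are implementation policy, documented as
  module constants.
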