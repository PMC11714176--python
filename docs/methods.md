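# Methods

This note documents the statistical procedures implemented in `tmescore`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Spatial statistics on TMA cores

A core is modelled as a disc (default radius 500 μm — a 1-mm-diameter
punch) containing cells with continuous planar coordinates in μm and one
exclusive phenotype among {tumor, T_CD3, T_CD8, macrophage, other}.  PD-1
flags are only meaningful on T cells and PD-L1 flags on macrophages and
tumor cells; the containers enforce this.

**G-cross estimator.**  `gcross_at_radius` estimates
G<sub>A:B</sub>(r) = P(a type-A cell has a type-B cell within r) as the
fraction of *eligible* reference cells whose nearest-neighbour distance to
the target type is ≤ r.  Nearest neighbours come from a k-d tree; an
all-pairs brute-force oracle is used in the tests for exact agreement.

*Edge correction.*  Minus-sampling (border method): with correction on,
only reference cells at least r from the disc boundary are eligible.  For
those cells the full disc of radius r lies inside the observation window,
so when the target process is homogeneous Poisson with intensity λ the
estimator is unbiased for 1 − e^(−λπr²).  This is why minus-sampling was
chosen as the default over Kaplan–Meier-style or Hanisch corrections: it
makes the closed-form calibration test exact in expectation.  An
uncorrected mode exists for sensitivity checks.

*Degenerate inputs.*  No eligible reference cells → the value is missing
(never 0) and propagates as a missing score component.  Reference cells
present but no target cells → the value is 0: a tumor without T cells is a
minimal-co-localization tumor, not an unmeasured one, mirroring how an
empty density is 0 rather than missing.

*Multi-core pooling.*  Distances are never computed across cores.  Per
(marker, region) the per-core values are combined by a reference-cell-count
weighted mean, so cores with more tumor cells contribute proportionally;
missing cores carry zero weight.  CD3 and CD8 are stained on separate
sections, so their patterns are never merged within one geometry.

**Densities** are counts per mm² of summed disc area over a region's cores
of the relevant panel.  Marker-flag filters (PD-1+, PD-L1+) restrict the
numerator only.

## Percentile scores

All categorical scores are rank-based, hence invariant under strictly
monotone transforms of the raw values.

Percentiles use the mid-rank convention,
pct(v) = 100·(#{x < v} + ½·#{x = v})/n, so ties are symmetric and the mean
percentile of any cohort is 50.  The density score averages the four
component percentiles (CD3/CD8 × CT/IM) that are available for a tumor —
partial cores keep the tumor in the cohort; only a tumor missing all four
components gets a missing score.  The bracket boundaries are closed below:
a mean percentile of exactly 25 is "low" and exactly 70 is "intermediate".
The proximity score runs the identical code path on the four G-cross
values; the combination rule (mean of four percentiles) is an assumption,
chosen to mirror the density score since the two are described as
analogous.

Tertile classes cut the mid-rank percentile at 100/3 and 200/3 with
boundaries falling to the lower group; heavy ties therefore share one group
and group sizes may be unequal, which is the intended semantics for
discrete densities.

**CLR density** is aggregates per mm of invasive margin.  The default
cutoff 0.42/mm classifies density ≥ cutoff as "high" (ROC thresholds
conventionally classify at-or-above as positive).  `roc_optimal_cutoff`
recomputes a cutoff by scanning the midpoints between consecutive sorted
unique values plus ±∞ and maximising Youden's J = sensitivity +
specificity − 1 against an event flag (disease-specific death ever observed;
censoring is ignored in this scan — a time-horizon ROC is out of scope).
Ties in J break toward the smallest threshold.

**PD-L1 tumor-cell brackets** follow the printed histoscore cuts: <1
negative, 1–<5, ≥5.

## Survival analysis

Times are years from surgery (inputs in days should be divided by 365.25).
Deaths within 30 days of surgery are post-operative and excluded before any
survival model; the exclusion count is reported.  Disease-specific survival
censors non-cancer deaths at the death time (cause-specific convention);
overall survival counts any death.

Kaplan–Meier estimation, the k-sample log-rank test and Cox
proportional-hazards fits stand on `lifelines`.  Cox models use Efron tie
handling (less biased than Breslow under the heavy ties produced by coarse
time units) and Wald confidence intervals.  Categorical covariates are
dummy-coded against an explicit reference level.  A non-reference level
with zero events would drive its coefficient to −∞; such levels are
reported as "No event" with their subject counts and removed from the
partial likelihood instead.  Non-convergence raises an explicit error —
never silent coefficients.

Median follow-up uses the reverse Kaplan–Meier technique: event and
censoring indicators are swapped, and the median of the resulting curve is
reported with a log-log (exponential Greenwood) 95% CI.  A cohort in which
everyone died carries no follow-up information and the estimate is flagged
undefined.

The model battery mirrors the study design: a univariable screen over the
clinicopathological and immune variables, plus four multivariable models —
one immune factor (CLR category, proximity score, PD-L1+ macrophage
tertile at CT, at IM) adjusted for comorbidity group, TNM stage (I–II
reference), tumor necrosis and intratumoral stroma — each fitted for DSS
and OS.

## Association tables

Cross-tabulations use Pearson's chi-square without continuity correction
and without a Fisher fallback; expected counts below 5 raise a warning but
never switch the method, since the analyses being reproduced report Pearson
statistics throughout.  Missing values are excluded pairwise and counted.
Column percentages round half away from zero to integers, matching the
printed style.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

**Core patterns.**  Tumor cells follow a Thomas cluster process: Poisson
parents (default 50/mm², simulated on a window extended by 3σ so boundary
clusters contribute), Poisson(16) offspring per parent with Gaussian spread
σ = 25 μm, thinned to the disc — about 800 tumor cells per default core,
in the range seen in carcinoma TMA cores.  Each immune phenotype draws a
Poisson count at its intensity (default 300 CD3+ T cells/mm²; "other"
cells 400/mm²); a fraction ρ of the immune cells is placed as Gaussian
offspring (τ = 15 μm) of randomly chosen tumor cells, the rest uniformly
in the disc.  ρ is the ground-truth attraction dial: ρ = 0 is complete
spatial randomness and increasing ρ must increase G-cross at 20 μm, which
the tests verify monotonically.  Marker positivity is Bernoulli (PD-1 on T
cells 0.3, PD-L1 on macrophages 0.4, on tumor cells 0.1).  Points whose
Gaussian offset lands outside the disc are resampled, so realized counts
are Poisson at the nominal intensity.

What this does *not* emulate: segmentation and phenotyping errors, nuclear
morphology, tissue-region boundaries inside a core, and spatial
inhomogeneity of the background intensity.  Tests passing on these
patterns validate the estimators' mathematics, not robustness to upstream
image-analysis noise.

**Cohorts.**  Categorical covariates are drawn independently to target
marginal proportions (defaults follow the published cohort's marginals).
Survival comes from two latent cause-specific Weibull
proportional-hazards times — cancer, driven by the DSS log-hazard effects,
and other causes, driven by the OS/other effects (comorbidity burden by
default) — with overall survival their minimum and the DSS event firing
when the cancer cause wins.  This design was chosen over thinning OS
events by a constant cause-of-death probability because constant thinning
forces DSS and OS hazard ratios to coincide; with latent competing times,
cause-specific Cox regression recovers the DSS effects exactly, which the
recovery and coverage tests exploit.  Administrative censoring is uniform
over 5–16 years, emulating staggered accrual with a fixed follow-up end.
Baseline shapes/scales (Weibull shape 1.1; cancer scale 220 y, other-cause
scale 32 y under the default effect sets) were calibrated once so the
default cohort yields roughly 20% disease-specific and 65% overall death
fractions, matching the scale of the motivating cohort.  Because the
covariates are independent, the joint distribution is not that of any real
cohort; parameter-recovery tests, not effect-size reproduction, are the
goal.

`emulate_reference_cohort` is the exception: a fixed-seed 171-patient cohort
whose categorical *marginals* are exact fixed multisets (including the
published missingness counts), with the CLR × metastasis cross-tab and the
postoperative-death split pinned.  It exists for pipeline smoke tests and
report-shape checks; its survival times carry only moderate stage and
comorbidity effects and its hazard ratios are not meaningful estimates of
anything.

**Linked studies.**  `simulate_study` ties the two levels together: each
tumor draws a latent immune quality q ~ U(0,1) that raises T-cell intensity
and attraction ρ, raises CLR density, lowers the cancer-specific hazard
(log-HR −1.5·q) and lowers the metastasis probability — so scoring a
simulated study end-to-end produces the expected direction of association
at every stage.

**Seeding.**  One global seed drives a named `SeedSequence` stream per
sub-generator (CRC-32 of the stream name as the child key), so draws are
platform-stable and adding a variable never perturbs earlier ones.

## Numerical choices and problem sizes

- Disc-containment tolerance for input validation: 1e-6 μm.
- ROC tie-break: smallest threshold within 1e-12 of the maximal J.
- The acceptance script uses 50 brute-force patterns, 200 CSR cores, 100
  pattern replicates per attraction level, 3 cohorts of n = 2000 for the
  hazard-ratio point recovery (their mean damps sampling noise) and 500
  cohorts of n = 300 for CI coverage — sizes at which the Monte-Carlo
  error is comfortably inside each check's tolerance.

## Known limitations

- The G-cross implementation evaluates single radii; full curves with
  simulation envelopes are out of scope.
- The proximity-score component set (whether and how IM cores contribute)
  follows the density-score analogy; source descriptions of this
  combination are incomplete, so it is an explicit assumption.
- DSS uses cause-specific censoring, not a competing-risks (Fine–Gray)
  formulation.
- Proportional-hazards diagnostics, time-dependent covariates and
  multiple-testing adjustment are deliberately absent.
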