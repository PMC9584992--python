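# Methods

`gfragree` quantifies how well creatinine- and/or cystatin-C-based GFR
equations reproduce a gold-standard measured GFR (iohexol plasma clearance) in
adults with autosomal dominant polycystic kidney disease (ADPKD), and what the
residual error does to treatment-threshold decisions. This note records the
models, conventions and numerical choices behind each stage, and what the
synthetic cohort does and does not emulate.

## Estimating equations and units

Twelve equations are registered: aMDRD, CKD-EPI-cr, CKD-EPI-cy,
CKD-EPI-cr-cy, Cockcroft-Gault, FAS-cr, FAS-cy, FAS-cr-cy, Lund-Malmö (Rv),
Grubb-2014 (CAPA), Hoek and Larsson, each transcribed from its primary
publication with no harmonisation of sex or age terms. Units are fixed:
creatinine in mg/dL (IDMS-traceable; multiplied by 88.4 where an equation
wants µmol/L), cystatin C in mg/L. There is no unit auto-detection.

All pipeline comparisons are in **absolute ml/min**. Equations that publish a
BSA-indexed value (ml/min/1.73 m²) are un-adjusted with the patient's Du Bois
BSA, `GFR = GFR_indexed · BSA/1.73`, because indexing to body surface area
distorts comparisons against an absolute tracer clearance. Cockcroft-Gault
and Larsson natively return absolute values and are left untouched.

Race coefficients (aMDRD, CKD-EPI 2009/2012) are applied only when a record's
`black` flag is explicitly true; the default cohort is European and the flag
defaults to false. The 2021 race-free CKD-EPI refits and pediatric equations
are out of scope. The registry is a plug-in table: `register_formula`
accepts any vectorised kernel, so the long tail of historical equations can
be added without touching the pipeline.

## Measured GFR: iohexol plasma clearance

The terminal elimination phase after a single iohexol injection is fitted by
ordinary least squares on ln C vs t (≥ 2 distinct late-phase times), giving
C(t) = c0·e^(−kt). The slope-intercept clearance CL1 = dose·k/c0 ignores the
fast distribution phase, so it is corrected with the Bröchner-Mortensen
one-pool quadratic

    CL = 0.990778·CL1 − 0.001218·CL1²,

whose increasing branch is valid to CL1 ≈ 400 ml/min (values outside [0, 400]
raise a warning). The coefficients are a stated convention — the standard
slope-intercept workflow for single-sample-free protocols — and are swappable
per call. Fits with log-space R² < 0.97 are flagged (`qc_pass=False`) as
poor decay curves; the threshold is a quality gate, not a published constant.
Full two-compartment fitting and assay-level corrections (dried-blood-spot
hematocrit) are out of scope.

The default synthetic sampling schedule is 120/150/180/240 min, a common
dried-blood-spot late-phase design. For subjects with severely reduced GFR
the elimination half-life reaches many hours and a 2–4 h window barely
constrains the slope; analyses that include predialysis GFR under
concentration noise should extend sampling (the test suite uses points to
600 min for that case), exactly as late-sampling protocols for advanced CKD
do.

## Agreement statistics

* **CCC** (concordance correlation coefficient):
  `2·s_xy / (s_x² + s_y² + (x̄−ȳ)²)` with divisor-n moment estimators.
  The estimator's mathematical range is [−1, 1]; descriptions of it as a
  0-to-1 index refer to the usual positive-association case.
* **TDI(p)**: the boundary capturing a proportion p = 0.90 of absolute
  differences. The empirical estimator is the ⌈p·n⌉-th smallest |d| — the
  smallest qualifying order statistic, no interpolation, ties resolved by
  that same rule. The parametric estimator is `sd·sqrt(q)` with q the
  p-quantile of the noncentral χ²(1, (mean/sd)²); at zero mean it reduces to
  `sd·z_(1+p)/2` and as sd → 0 to |mean|.
* **cp(κ0)**: the fraction of differences within ±κ0, κ0 = 10% by default
  (the a-priori acceptable bias); reported 0–100 in tables.

**Difference scale.** GFR estimation error is proportional, so the pipeline
computes TDI and cp on log differences ln(eGFR/mGFR) and back-transforms the
TDI boundary to the percent scale, `TDI% = 100·(e^κ − 1)`, which is read
directly as "% of mGFR". This is the standard treatment of proportional
error in the TDI literature and makes the boundary exact under lognormal
error: if ln(eGFR/mGFR) ~ N(0, σ), TDI%(0.90) = 100·(e^(1.645σ) − 1). A
plain percent-of-mGFR scale (d = 100·(e−m)/m) is available via
`tdi_scale="percent"`; note the order statistic of |d| on that scale does
*not* follow the lognormal closed form, because a symmetric log error is
asymmetric in percent space. cp on the log scale tests |ln(e/m)| ≤
ln(1 + κ0/100), which matches the percent-scale reading of "within +10%".

**Duality.** By construction, coverage evaluated at the empirical TDI(p)
is ≥ p, with equality exactly when p·n is an integer and the data are
continuous (no ties) — asserted in the tests.

**Bounds.** Table parentheticals are conservative one-sided 95% bounds from a
pair-resampling percentile bootstrap (B = 2000 default, explicit seed
mandatory): lower bound for CCC and cp, upper for TDI. Resampling is of
pairs, not residuals; the display convention rounds CCC to 2 decimals, TDI
and cp to integers. With fewer than 5 pairs the bootstrap refuses.

## Threshold misclassification and staging

Cohort strata use >90 / [60, 90] / [30, 60) / <30 ml/min; the closed upper
boundary of [60, 90] makes the four strata a clean partition with ">90" and
"<30". KDIGO categories use the conventional bands (G1 ≥90 … G5 <15).
Misclassification at the tolvaptan cut-off counts, among subjects with mGFR
below 30 ml/min, those a formula estimates at ≥ 30 (overcalls), and among
subjects with mGFR in the closed band [30, 40], those estimated below 30
(undercalls). Error magnitudes are partitioned into left-closed bands
|d| < 10, 10–20, 20–30, > 30 % of mGFR. Eligibility flags (below 30,
reimbursable above 45, not recommended at age 55–60 with GFR > 60) are
informational outputs with configurable thresholds, not clinical advice.

A bundled 14-patient reference table (`gfragree/data/example_pairs.csv`),
grouped in pairs of similar mGFR from 16 to 95 ml/min with four eGFR columns,
is the worked fixture for the counting rules.

## Synthetic cohort

The generator produces cohorts with the statistical structure the analysis
assumes, not a biophysical model of ADPKD:

* **mGFR**: stratum membership drawn with probabilities 0.32/0.30/0.24/0.14,
  uniform within (90, 125) / (60, 90) / (30, 60) / (8, 30) ml/min. The
  stratum ranges were set once so the pooled distribution has median ≈ 71 and
  IQR ≈ 44–97 ml/min.
* **Demographics**: age N(45, 14) truncated at 18; 50% male; sex-specific
  height and weight (clipped to plausible ranges); lognormal TKV with median
  1008 ml and log-SD 0.83 (matching an IQR spread of roughly 635–1941 ml).
* **Markers, generated backwards**: correlated error terms
  (ε_cr, ε_cys) ~ N(0, Σ) with σ_cr = 0.20, σ_cys = 0.22, ρ = 0.3 define
  target estimates mGFR·e^ε for a creatinine anchor (aMDRD) and a cystatin
  anchor (CKD-EPI-cy); the marker value is then obtained by bisecting the
  anchor equation (64 iterations, tolerance 1e-8) on creatinine ∈
  [0.1, 25] mg/dL (resp. cystatin mg/L). Inverting an anchor is the modelling
  choice standing in for unobservable marker biology: it guarantees the
  anchors recover mGFR up to the injected noise — a known truth for
  parameter-recovery tests — while all other formulas inherit larger,
  formula-dependent deviations. The bounds are wide enough that a target
  falls outside the anchor's attainable range only ~1 in 5000 draws at
  σ = 0.3 (such subjects are resampled); narrower bounds visibly truncate
  the error tail and bias the anchor TDI low. The default σ values were
  chosen so the full 12-formula table lands in the 35–60% TDI range typical
  of eGFR-vs-tracer comparisons in this population; they are a calibration,
  not an estimate from data.
* **Iohexol curves**: per subject, the slope-intercept clearance is set to
  the one-pool *inverse* of mGFR, with c0 = dose/V and k = CL1/V (dose
  3235 mg ≈ 5 ml of 647 mg/ml iohexol; V = 15 L, an extracellular-volume
  scale). Noise-free tables therefore round-trip through the measurement
  pipeline to machine precision; multiplicative noise is mean-one lognormal
  with the requested CV.

What the generator does **not** emulate: within-subject marker variability
over time, comorbidity effects (inflammation, thyroid disease, extremes of
muscle mass) beyond the noise term, assay bias between laboratories,
longitudinal GFR decline, and any genetic structure. Passing
parameter-recovery tests shows the statistics and plumbing are correct under
the stated error model; it does not validate any equation's real-world
accuracy.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit integer seed; a `RunConfig` fully
determines all artifacts, and a rerun with the same config is byte-identical
(the manifest records seed, a semantic config hash and package versions, and
deliberately no timestamp). Floats in CSV artifacts are serialised to 6
significant digits.

Default analysis sizes — cohort n = 1000, bootstrap B = 2000, and n = 5000
per σ for the recovery grid — keep a full run in the seconds-to-a-minute
range on one CPU while holding the Monte-Carlo error of a 0.90-quantile at
n = 5000 to about one percentage point of TDI. A ±2-point check against the
lognormal closed form at σ = 0.3 is therefore comfortably met by typical
seeds but is a ~2σ event for unlucky ones; averaging over seeds or raising n
tightens it at proportional cost.

## Known limitations

* The empirical TDI convention (order statistic, no interpolation) differs
  from interpolating quantile estimators by O(1/n); at n below ~50 the
  difference can reach a percentage point.
* The bootstrap bound is the plain percentile method; it has no second-order
  accuracy guarantees and is labelled "conservative" by direction, not by a
  coverage theorem.
* The one-pool quadratic is an empirical correction; outside roughly
  20–200 ml/min of true clearance its agreement with full two-compartment
  kinetics degrades, and the package warns rather than refuses.
* CCC is scale-invariant under a common positive rescaling of both series
  but not under shifting one series — it is an agreement index, not a
  correlation; both properties are asserted in the tests.
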