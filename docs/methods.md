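# Methods

## The estimand and the procedure

The package addresses a population-inference problem: a cross-sectional
cohort of children aged 3–18 measures continuous brain-structure outcomes
(cortical surface area, subcortical volume, ...), but its demographic
composition differs from the national population of children. The estimand
is the population-level age trajectory of each outcome — and summary
quantities of it, chiefly the age at which the trajectory peaks. The
procedure has three stages, run identically with and without weights so that
differences between the two arms are attributable to weighting alone.

### Calibration weighting

Weights are calibrated so that the weighted sample reproduces target
category proportions of four variables: sex, race/ethnicity, parental
education and family income. Two solvers are provided.

*Iterative proportional fitting (`ipf_rake`)* cycles over the variables in
the order they appear in the margin specification, multiplying each
category's weights by (target share)/(current weighted share). A cycle
count is an "iteration"; convergence is a maximum absolute margin error
below `tolerance` (default 1e-8, proportion units). The converged solution
is order-invariant (checked by test); the default iteration cap is 1000
because IPF converges only linearly when the sample's variables are
associated.

*Bounded-logit calibration (`calibrate_logit`)* solves the moment equations
Σ_k θ_k x_k = T for β, where x_k contains an intercept (total constraint)
plus one indicator per non-reference category of each variable — one
category per variable is dropped because the full indicator set is
collinear. Each weight is θ_k = init_k · α(A·x′_kβ) with the bounded-logit
link

    α(η) = l + (u − l) · logistic(η + log((c − l)/(u − c))),

an algebraic rewriting of the ratio form l(u−c)+u(c−l)e^η over
(u−c)+(c−l)e^η that is numerically stable for large |η|. α is strictly
increasing with α(0) = c and range (l, u). Defaults l = 0, u = 100, c = 1,
A = 1: with these wide bounds the link is an (approximately) exponential
distance, and as u → ∞ the solution coincides with classic raking — the test
suite verifies agreement to 1e-4 relative at u = 1e6 on random instances.
At u = 100 the two solutions differ by roughly α/u relatively, which is the
price of bounding the adjustments. The solver is damped Newton with
step-halving on the moment-equation norm; a singular Jacobian on the first
step signals collinear indicators (an input error), while singularity later
means the bounds have pinned all adjustments and the run ends with
`converged = False` and per-category residuals.

Weights are normalized to sum to the sample size n (a population total is a
config option); every downstream regression is invariant to this scale.

*Trimming (`trim_and_rerake`)* computes quartile fences
[Q1 − 3·IQR, Q3 + 3·IQR] from the initial-pass weights, clips, and
re-calibrates using the clipped weights as initial weights with per-unit
bounds l_k = fence_lo/clipped_k, u_k = fence_hi/clipped_k, so that the
re-calibrated weights both restore the margins (when feasible) and respect
the fence. Fences are stored in the returned `WeightSet`; a second
application reuses them and is a no-op, making trimming idempotent. A zero
IQR (constant weights) disables trimming.

### Weighted polynomial age models

For each outcome and each order p ∈ {1, 2, 3} the design is: intercept,
centered age powers (age − MeanAge)^1..p, dummy-coded covariates (sex,
race/ethnicity, parental education, income, scanner site) against fixed
reference levels, and mean-centered intracranial volume for head-size
dependent outcomes. MeanAge is the weighted mean age of the analysis arm.
Reference levels default to the first category of each variable's
vocabulary; AIC, predictions and peaks are invariant to this choice.

Fitting is weighted least squares (statsmodels WLS) with weights normalized
to sum to n. The information criterion is the Gaussian pseudo-likelihood

    AIC = n · ln(RSS_w / n) + 2 · (p + 1),

where RSS_w is the weighted residual sum of squares and p counts mean-model
parameters (+1 for the error variance). Because survey-weighted likelihoods
are not true likelihoods, this AIC is a pseudo-criterion defined identically
in both arms; only comparisons between orders within an arm are meaningful,
not absolute values. Standard errors are model-based by default with an
HC1 sandwich option.

Order selection: the selected order is the highest one whose AIC is at
least 2.5 points below the best AIC among all strictly simpler models,
falling back to linear. The 2.5-point threshold is the conventional bar for
preferring added polynomial complexity; it is configurable.

### Peak-age inference

Predicted trajectories use marginal standardization: at each grid age
(default 3 to 18, step 0.05) every participant's age is set to the grid
value, predictions are made with their observed covariates, and averaged
with the analysis weights. This is invariant to reference-level choices and
describes the weighted covariate mix rather than one demographic cell.
Grid ages outside the observed age support are flagged as extrapolation.

Peaks: quadratic fits use the vertex formula MeanAge − a1β/(2·a2β),
requiring a2β < 0. Cubic fits solve the derivative's two roots with the
numerically stable quadratic-root form (avoiding cancellation when a3β ≈ 0)
and keep the root where the second derivative is negative; a root outside
the age range triggers a fallback to the in-range argmax with
`interior=False`, and a negative discriminant raises a monotone-trajectory
error. ICV-adjusted outcomes use 2-year bins of the predicted curve —
consecutive [start, start+2) intervals from the range minimum — returning
the midpoint of the bin with the highest mean, ties broken toward the
younger bin (bin representative age is not standardized anywhere; the
midpoint is this package's choice). Peak differences are reported on
one-decimal-rounded peaks, matching conventional reporting precision.

## The synthetic cohort generator

The generator emulates the study conditions end to end: n = 1162
participants by default, ages uniform on [3, 18], ten scanner sites,
lognormal ICV (median 1.45e6 mm³, log-sd 0.08 — a typical child ICV scale),
and categorical demographics drawn from the packaged sample margins (the
multi-site child cohort column) with the ACS census margins as the raking
target. Variables are independent by default because the weighting consumes
only margins and independence keeps expected weights analytic; a pairwise
log-odds association knob (exponential tilt re-fit to the margins by IPF)
is available for sensitivity work on disjoint variable pairs.

Outcomes follow group-modified polynomials: group g's curve is
amplitude_g · P(age − center − shift_g) plus additive covariate effects, an
optional centered-ICV slope, and Gaussian noise. Parameterizing groups by a
peak *shift* (rather than raw coefficient deltas) makes each group's true
peak, and any margin-weighted mixture peak (`true_population_peak`, dense
grid with 0.001-year steps), known by construction. The default spec has
two outcomes:

* `total_surface_area` (mm²): concave quadratic with curvature
  −242.64 mm²/yr² (the scale of published total-surface-area fits), base
  peak near age 12.1, noise SD 4000 mm² — about 3.4 noise-SDs of curvature
  across the age range, enough for reliable order-2 selection at n = 1162.
* `subcortical_volume` (mm³): concave quadratic peaking near 11.75 with an
  ICV slope of 0.02 and noise SD 1500 mm³; exercises the binned peak path.

Both carry income-keyed peak shifts of −3.0 (<40k), −1.5 (40–100k) and 0
(≥100k) years, encoding earlier maturation in lower-SES groups. Because the
sample margins under-represent the <40k group relative to the census target
(24.8% vs 33.5%), the unweighted analysis over-states the population peak
age and weighting pulls it earlier — the qualitative behavior the pipeline
is designed to expose. With these defaults the true population peak is
10.80 years under the sample margins and 10.49 under the census margins.

What the generator does *not* emulate: measurement pipelines (no image or
surface simulation), longitudinal within-person structure, realistic joint
demographic dependence (unless the association knob is set), site effects on
outcomes, and non-Gaussian measurement error. Passing tests therefore
demonstrate correctness of the weighting and inference machinery under the
stated generative assumptions, not robustness to real-data pathologies.

## Numerical and design choices

* Calibration convergence: max absolute margin error < 1e-8 (proportions);
  Newton with up to 40 step-halvings per iteration.
* Infeasible targets (a positive-target category with no sample members)
  raise before any computation; targets unreachable under the bounds return
  `converged=False` with per-category residuals rather than raising, since
  partial calibration is still informative.
* Margin reports round percentages to one decimal and difference columns
  are computed from the rounded values, mirroring how such tables are read.
* The test-suite oracle for cubic peaks is the dense-grid *interior local
  maximum*: a cubic's local maximum need not be its global in-range argmax,
  and the derivative-root method intentionally targets the former.
* Problem sizes in the test suite (n = 800–5000 cohorts, 25–50 replicate
  seeds, 1e-4 peak grids) were chosen to keep the full suite around ten
  seconds while leaving each statistical check several standard errors of
  headroom.

## Known limitations

* No variance estimation for weighted quantities (no replicate weights,
  jackknife or BRR) and no confidence intervals on peak ages; the package
  deliberately reports point comparisons only.
* The pseudo-AIC is not a survey-corrected criterion (no design-effect
  adjustment); its absolute values are not comparable across weighting
  arms, only across orders within an arm.
* Calibration covers categorical margins only (no numeric GREG totals).
* Peak inference assumes a single interior maximum; plateau-shaped or
  multi-modal trajectories are outside the model family.
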