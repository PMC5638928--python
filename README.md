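# trajweight

Post-stratification sample weighting for developmental trajectory analyses.

Convenience cohorts in developmental neuroscience rarely look like the
population they are meant to describe: multi-site child neuroimaging samples
tend to over-represent high-SES, highly educated families and
under-represent the demographic groups that census data say make up much of
the population. When the *shape* of an age trajectory differs across those
groups — for instance, if brain-structure metrics peak earlier in
lower-income children — an unweighted analysis estimates the trajectory of
the recruited sample, not of the population, and quantities read off the
fitted curve (such as the age at peak) are biased accordingly.

`trajweight` implements the standard survey-statistics remedy and the
downstream trajectory analysis in one tested pipeline:

1. **Calibration weighting (generalized raking).** Per-participant weights
   θ_k are constructed so the weighted sample reproduces target population
   margins (sex, race/ethnicity, parental education, family income). Two
   algorithms are provided: classic iterative proportional fitting, and the
   bounded-logit calibration used by survey packages,

   θ_k = γ_k · α_k,  α_k = [l(u−c) + u(c−l)·exp(A·x′_kβ)] / [(u−c) + (c−l)·exp(A·x′_kβ)],

   where x_k stacks the category indicators, β solves the calibration
   moment equations Σ_k θ_k x_k = population totals (damped Newton), l < c < u
   bound each adjustment factor, and γ_k is a 3-IQR trimming factor with
   re-calibration.
2. **Weighted polynomial age models.** Each outcome is regressed on centered
   age powers (age − MeanAge)^p, p = 1..3, plus dummy-coded demographic and
   scanner covariates (and centered intracranial volume for subcortical
   measures), by weighted least squares. Orders are compared with a
   Gaussian pseudo-likelihood AIC = n·ln(RSS_w/n) + 2(p+1); a more complex
   polynomial is kept only when it lowers AIC by ≥ 2.5 points.
3. **Peak-age inference.** Age at peak from the first derivative of the
   selected fit — MeanAge − a1β/(2·a2β) for quadratics, the quadratic-formula
   roots of a1β + 2·a2β·x + 3·a3β·x² for cubics — or, for ICV-adjusted
   models, by averaging marginally standardized predictions within 2-year
   age bins. The unweighted and weighted analyses use the identical
   procedure, so any difference in peaks is attributable to the weighting.

A synthetic-cohort generator with known ground truth (demographic margins,
SES-modulated polynomial trajectories, analytic population peak ages) makes
the whole pipeline testable without access-controlled data.

## Worked example

```python
import trajweight as tw

report = tw.run_full_analysis(tw.RunConfig(seed=0))   # synthetic n = 1162
print(report.margin_table.head(5))
print(report.peak_table)
```

The margin table shows the raking at work — the synthetic cohort
under-represents White children (40.3% vs the 69.9% census target) and
over-represents Hispanic children (24.7% vs 7.5%), and after weighting every
difference is 0.0:

```
variable category  target_pct  unweighted_pct  weighted_pct  unweighted_minus_target  weighted_minus_target
    race    White        69.9            40.3          69.9                    -29.6                    0.0
    race    Black        13.6            10.2          13.6                     -3.4                    0.0
    race Hispanic         7.5            24.7           7.5                     17.2                    0.0
    race    Other         5.5            10.5           5.5                      5.0                    0.0
    race 2+ Races         3.5            14.3           3.5                     10.8                    0.0
```

The peak table compares the two analysis arms. Because the generator makes
lower-income groups peak earlier and the census margins up-weight them, the
weighted peak comes earlier:

```
           outcome  peak_unweighted  peak_weighted  difference     method
total_surface_area             10.8           10.6         0.2   analytic
subcortical_volume             10.0           10.0         0.0 binned-2yr
```

(The subcortical outcome is ICV-adjusted, so its peak is read from 2-year
bins, which are too coarse to resolve a sub-year shift.) The same analysis
is available from the shell:

```bash
trajweight simulate --out fixture/ --n 1162 --seed 0
trajweight rake --cohort fixture/cohort.csv --margins fixture/target_margins.csv --out weights.csv
trajweight run --out results/
```

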