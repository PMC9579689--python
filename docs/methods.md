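# Methods

## Anthropometric conversions

Heights convert to height standard deviation scores (HSDS) by the LMS
method: a reference distribution at each age and sex is summarised by the
Box-Cox power L, median M (cm) and coefficient of variation S, and
`z = ((x/M)^L − 1)/(L·S)` (the log form when L = 0).  L, M and S are
interpolated linearly in age between table rows; ages outside the table
raise an error rather than extrapolate.  The age used for a measurement
during treatment is `age_at_start + months_on_treatment / 12`.

The bundled table (`data/lms_height_synthetic_who_style.csv`) is a
*synthetic* WHO-style height-for-age reference: L = 1 throughout, yearly
anchor medians and SDs for ages 2–19 matching standard growth charts, and a
flat extension to age 21 so children starting treatment as late as 16 years
remain in range through 54 months.  It is built from anchor values, not
copied from any published table; analyses that need a specific national or
WHO edition should load it with `load_reference_csv`.  A second, tiny
constant-parameter table (`synthetic_reference()`) exists purely to make
unit-test arithmetic transparent (1 SDS = M·S cm exactly).

The scale "cm per SDS" is the derivative of the SDS→height transform at the
median, which equals M·S for every L.  Because the source of the published
cm equivalents does not state a sex convention, `cm_per_sds` exposes
`male`, `female` and `averaged` modes.

## Cleaning rules

Order is fixed: treatment window → HSDS range → height decrease →
broken-stick residual outliers.  All thresholds are configuration, with
defaults implementing the published protocol:

- window 0–54 months; subjects need ≥ 2 surviving measurements (they are
  also required by the mixed model, and dropping sparse subjects would bias
  the population estimates);
- HSDS strictly inside (−7, 2);
- a height ≥ 2 cm below the *running maximum* of earlier retained heights
  is removed (children on r-hGH do not shrink; with ~0.3 cm measurement
  error a 2 cm decrease is ~3 SD on either side).  The running-maximum
  form — rather than consecutive-pair comparison — never removes the first
  record, is idempotent, and does not depend on which of two inconsistent
  points is "wrong";
- broken-stick residuals (observed − subject fitted value) with
  |r| ≥ 0.5 SDS are removed, bounds inclusive, followed by exactly one
  refit (iterating to convergence is not part of the protocol).

### Detection limits of the residual rule

The residual uses the subject's BLUP curve computed *from all of the
subject's observations, including the one being screened*.  An isolated
error of size δ therefore shows up in the residual as δ·(1 − h), where h is
the observation's leverage.  On realistic irregular schedules the leverage
is substantial — median ≈ 0.3 on the default synthetic cohort, ≈ 0.7 for
the baseline visit (only that visit informs the month-0 knot) and ≈ 0.5–0.7
for temporally isolated visits — so a ±0.6 SDS spike typically retains only
≈ 0.4 SDS of residual and escapes the 0.5 bound, and a negative spike close
after a previous visit is often intercepted by the ≥ 2 cm decrease rule
first.  The rule is a gross-error screen (it removes clear recording
mistakes of roughly ≥ 1 SDS, depending on leverage), not a sensitive spike
detector; the cleaning-recall test documents this by measuring recall on
labelled ±0.6 SDS injections.

## Broken-stick model

A linear mixed model on a first-degree (tent) B-spline basis with knots at
0, 3, …, 48 months and a boundary knot at 54 so that observations in months
48–54 inform the fit; estimates are reported at 0–48.  Random effects have
an unstructured covariance Ω (one coordinate per knot); the residual
variance σ² is homoscedastic.  Assumptions: subjects exchangeable,
trajectories linear between knots, Gaussian random effects, data missing at
random.

Estimation is deterministic maximum likelihood via expectation–conditional
maximisation rather than Gibbs sampling: the estimand (BLUP knot values)
is the same up to Monte-Carlo error, and a deterministic fit makes builds
reproducible.  Per iteration: (1) a joint EM update of (Ω, σ²) from the
E-step at the current parameters; (2) every 10th iteration, a bounded 1-D
profile maximisation of σ² on the log scale (plain EM stalls near the
σ² → 0 boundary on noise-free data); (3) a GLS update of β.  Each step is
monotone in the marginal log-likelihood.  Because EM creeps on flat
directions of the 171-parameter Ω, an over-relaxation step extrapolates
along the last parameter change and is kept only when the log-likelihood
improves, preserving monotonicity (verified by a property test).
Convergence: relative log-likelihood change < 1e−6, at most 500 iterations
(non-convergence returns `converged=False` with a warning).  Ω is
initialised to identity × the empirical HSDS variance, σ² to a quarter of
it; diagonals get a 1e−8 ridge before inversion, and σ² is floored at
1e−10.  Subjects are bucketed by observation count so the E-step runs as
batched array operations.

Cross-checks: a small-instance comparison against an independent
mixed-model implementation (statsmodels `MixedLM`, ML) agrees on β to
< 1e−4 and on σ² to < 1%; a one-observation BLUP matches the closed-form
2×2 algebra; fixed effects on 500 simulated subjects are recovered within
3 model-based standard errors and σ² within 20%.

## Monthly curves and visit vectors

Knot estimates are interpolated linearly to integer months 0–48.  A new
patient's visits are aligned to the monthly grid by rounding the *treatment
time* to the nearest month (half away from zero) and averaging collisions.
Rounding time rather than the HSDS value is the reading adopted for the
"(rounded) monthly HSDS" input: matching requires alignment to the
database's monthly grid, while rounding HSDS values would discard precision
for no benefit.

## Matching Database and weighing scores

Selection: baseline HSDS in [−4, −1) (lower bound inclusive, upper
exclusive), positive HSDS gain in each of the four treatment years, age at
start in [3, 16).  GHD and SGA are pooled by default (their trajectories
are comparable); an indication filter supports subgroup databases.

The weighing score of a curve is `(good matches + 1)/N` with a good match
defined as residual SD < 0.03 (strict) between the *complete 0–48-month*
curves — 49 shared points, divisor 48.  Full-curve similarity is used
because the score expresses how common a whole trajectory is in the
database.  The divisor convention for the residual standard error is n − 1
for n ≥ 3 shared months and n below that, which keeps a single shared month
well defined.

## Matching and prediction

Distances between the visit vector and every database curve restricted to
the same months use the same residual-standard-error formula.  The k = 25
closest curves are kept (fewer would destabilise the weighted mean; more
would dilute match quality and clutter the chart); ties break on ascending
subject id so builds are deterministic; the patient's own curve is excluded
first when present.  If fewer than k candidates exist, all are returned
with a warning.  The prediction after the last matched visit month is the
weighing-score-weighted mean of the matched curves; distance does not enter
the weights.  Spread is reported two ways, since the display convention is
a free choice: the weighted SD per month and weighted quantiles
(10/25/50/75/90%).

## Validation design

Groups: (1) baseline HSDS only; (2) baseline + ≥1 visit in months 1–3,
history fed to month 3; (3) months 4–6, history to 6; (4) months 9–12,
history to 12; (5) months 7–12 *and* 13–24, history to 24.  A subject can
belong to several groups.  Errors (observed − predicted HSDS, observed
values, not model-smoothed ones) are scored at every rounded month after
the group's cutoff and summarised in bins 4–9, 10–14, 15–20, 21–27, 28–32,
33–39, 40–48; months 1–3 fall in no bin and are excluded from summaries.
Bin statistics: n, mean, sample SD, median, quartiles by linear
interpolation between order statistics (no convention was prescribed), min
and max; boxplots draw whiskers to min/max with a zero reference line.
Optional stratifiers (indication, age bands) refine the grouping.

## Synthetic cohorts

Each child follows `h(t) = h_inf − (h_inf − h0)·e^(−t/τ)`: decelerating
catch-up matching the shape of published treated-growth trajectories.
Defaults reproduce the reported cohort moments: `h0 ~ N(−2.4, 0.7)`,
`h_inf ~ N(−1.0, 0.8)` truncated above `h0`, τ lognormal with median 18
months (log-SD 0.35, so most catch-up completes within 3–4 years), 64%
boys, 23% SGA, age at start uniform on [3, 16), a baseline visit plus 1–4
visits per year at uniformly jittered times through month 54, and
N(0, 0.05) SDS measurement noise (~0.3 cm).  A 5% non-responder minority
declines slowly, exercising the yearly-increase selection rule.  Heights
are derived from the HSDS through the bundled reference, so HSDS and cm
stay mutually consistent.

What the generator does *not* emulate: puberty timing and its interaction
with age at start, dose and adherence effects, country-specific references,
seasonal growth, informative visit schedules, or drop-out.  Passing tests
therefore demonstrate the machinery's correctness and the qualitative
information-orderings of the design, not clinical accuracy on real
registries; in particular the per-bin error SDs on synthetic cohorts
(≈ 0.17–0.48 SDS depending on history) are not comparable to values
estimated on registry data.

`inject_artifacts` plants at most one labelled error per subject
(probabilities 3% out-of-range HSDS, 3% height drop ≥ 2 cm below the
running maximum, 10% ±0.6 SDS spike) to measure cleaning recall; one
artifact per subject keeps per-rule attribution clean.

## Numerical and interface choices

- Weighing scores use the Gram-matrix identity, so the N×N distance matrix
  is formed without an N×N×49 intermediate; squared distances are clipped
  at zero before the square root.
- `after_month ≥ 48` yields an empty prediction, not an error; an empty
  visit vector is rejected.
- The boundary knot is configuration (`KnotGrid(boundary=None)` restricts
  the basis to 0–48); whether the original analysis used one is unknown.
- Databases persist as a directory of CSVs plus a JSON manifest recording
  the selection criteria and the good-match threshold.

## Known limitations

- Matching uses HSDS only; covariates known to matter (age at start, target
  height, puberty status, dose) are not matched on.
- The residual outlier rule's sensitivity is leverage-limited (see above).
- Missing-covariate imputation is out of scope; records must carry sex,
  indication and age at start explicitly.
- The synthetic generator's exponential family makes between-subject
  covariance effectively low-rank; real registry curves are noisier, which
  would loosen the broken-stick shrinkage somewhat.
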