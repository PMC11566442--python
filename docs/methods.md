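# Methods

## Estimand and fusion model

The quantity of interest is the annual probability of premature (35–74 y)
cardiovascular death conditional on obesity status O ∈ {0, 1} and education
E ∈ {low, middle, high}, per 5-year age group, sex and calendar year. No
single source observes all three variables on the same person, so the
probability is assembled by Bayes' theorem from four aggregate components:

* **Pr(O, E | CVD)** — from the multiple-cause death file. Obesity at death
  is latent; the proxy is *obesity-related CVD mortality*: an any-mention
  CVD death (ICD-10 I00–I45 or I47–I99 anywhere in part 1 or part 2;
  cardiac arrest I46 excluded, implemented literally as the two ranges
  rather than a subtraction) that also mentions at least one marker code —
  diabetes E10–E14, chronic kidney disease N18, obesity E65–E66, lipidemias
  E78, hypertension I10–I15. Membership is decided on the 3-character
  category; later characters never disqualify (E11.9 counts as E11). Note
  hypertension is itself cardiovascular, so an I10-only certificate is both
  a CVD death and obesity-related.
* **Pr(CVD)** — CVD deaths over census person-years.
* **Pr(O | E)** — weighted obesity prevalence (BMI ≥ 30 kg/m², the cutoff
  value inclusive) given education from the examination survey.
* **Pr(E)** — weighted education shares from the household survey.

For O = 0 the denominator uses (1 − Pr(O=1|E))·Pr(E), as the probability
model forces. The formula conserves total probability by construction —
Σ_{O,E} Pr(CVD|O,E)·Pr(O|E)·Pr(E) = Pr(CVD) to floating-point precision —
and on a fully enumerated micro population whose four components are
computed from the same counts it reduces algebraically to direct stratified
counting. Both identities are enforced in the test suite; they are the
correctness anchors of the fusion code.

Assumptions worth stating: the fusion is an ecological calculation (the
components are combined at the (age, sex, year) level, not the individual
level); the marker proxy is treated as given (sensitivity/false-positive
dials in the generator quantify, but the pipeline does not correct,
misclassification); and no uncertainty is propagated from the component
estimates into the surface — intervals come only from the projection stage.

## Education harmonization

Four coding schemes are mapped onto {low, middle, high}: the 1989-revision
years-of-schooling and 2003-revision attainment codes found on death
certificates, and household-/examination-survey attainment codes. The
shipped lookup tables (`src/cvdfusion/data/education_codes.csv`) are the
single source of truth; GED, some college and associate degrees count as
middle ("completed high school but no Bachelor's"), Bachelor's and above as
high. Unknown codes map to `unknown` and, at tabulation, unknown-education
CVD deaths are redistributed proportionally to the known-education
distribution within (age, sex, year, obesity proxy). The policy is
switchable; dropping unknowns instead deflates Pr(O,E|CVD) denominators
when education is missing at random.

## Survey estimation

Estimators are weighted proportions with a weighted-binomial standard error
on the Kish effective sample size n_eff = (Σw)²/Σw². Full design-based
variance (clusters, strata, replicate weights) is deliberately out of
scope; the synthetic surveys carry informative weights but no cluster
design, so passing tests say nothing about design-effect estimation on real
survey files.

Obesity prevalence is estimated per two-year wave (the last wave may be a
single year), anchored at the wave-midpoint year, and bridged to an annual
series by piecewise-linear interpolation between midpoints with flat
extrapolation at the ends — the bridge from pooled waves to an annual Bayes
computation is otherwise unspecified, and this choice keeps wave-anchored
years exactly equal to their wave estimate. A two-period pooling mode
(2003–2010 / 2011–2019 style) is available; per-wave is the default for a
smoother annual series. Prevalence is clamped to (1e-6, 1−1e-6) before
entering the Bayes denominator to keep sparse desk-scale runs finite.

## Lee-Carter fitting and projection

Per (sex, obesity, education) stratum — twelve independent fits, no
cross-stratum coherence, so projected crossings between strata can occur —
the model log m_{x,t} = a_x + b_x κ_t + ε_{x,t} is estimated by the
classical SVD route: a_x is the per-age time mean, (b_x, κ_t) come from the
leading singular triple of the row-centered matrix, rescaled so Σb_x = 1
(which also centers κ and resolves the (b,κ) → (−b,−κ) sign ambiguity: the
fitted drift automatically carries the sign of the age-averaged log-rate
trend). A time-constant surface yields a flagged degenerate fit with
b_x = 1/8, κ_t = 0 and a flat projection. Surface cells with zero estimated
probability (possible in small synthetic runs, never in national data) are
floored at half the stratum's smallest positive value before logging. The
classical second-stage re-estimation of κ to match observed total deaths is
not applied: the modelled quantity is a conditional probability, not a
death count.

κ_t is forecast with a random walk with drift: d is the mean first
difference (so d̂ = (κ_T − κ_1)/(T−1), with sd exactly σ/√(T−1)); σ uses
denominator T−2. The h-step forecast variance is

    Var(κ_{T+h}) = h·σ² + h²·σ²/(T−1),

the second term being drift-estimation uncertainty — non-negligible at
h = 10 with T = 17 (it inflates the 10-year interval half-width by ~27%).
Log-scale bounds per age are central ± z·|b_x|·sd; probability-scale bounds
exponentiate. Forecasts anchor at the fitted final-year value by default
("observed" jump-off available). The all-ages series is aggregated from
age-specific projections by exposure-weighted means of central and bound
paths — exact for the quantiles because all ages within a stratum share the
single period shock (comonotonicity); a direct univariate RWD on the
aggregate log series is provided as an alternative mode. All-age
aggregation is crude (exposure-weighted), not age-standardized, matching
what the exposure table supports; the weighting is a config switch.

Annualized % change in the overall CVD rate is the slope of a log-linear
Poisson regression of death counts on calendar year with a log-exposure
offset, reported as 100·(e^β − 1) with Wald 95% intervals (a frequentist
reading of interval semantics).

## The synthetic world

The generator's defaults define the study conditions:

* **Span and structure**: years 2003–2019 (T = 17), eight 5-year age bands
  35–39 … 70–74, both sexes; projection horizon 2020–2029.
* **Exposures**: `pop_size` = 4,000,000 person-years per (age, sex, year)
  cell, split across (E, O) strata by largest-remainder integerization of
  exact expected counts — scaled down from the ~8–10 M of real US age-sex
  cells to keep hundred-seed studies tractable, large enough that every
  stratum is densely observed. Exposures are deterministic; deaths and
  surveys carry all the stochasticity.
* **Education shares** Pr(E): softmax of linear scores in age, sex and
  year — high-education shares rise over time and fall with age, low-education
  shares the reverse, females slightly higher at high education.
* **Obesity prevalence** Pr(O|E): logistic in year with a mild mid-age
  peak; low/middle education sit ~13 points above high education
  (≈47% vs ≈32% by 2019).
* **Conditional probabilities** Pr(CVD|O,E): log-linear in year from a 2003
  anchor (base 60 per 100,000 at 35–39/female/middle/non-obese; +0.28 per
  age band, +0.35 male, +0.45 obese, education effects +0.45/0/−0.55) with
  per-(E,O) drifts: obese strata rise (+0.6% to +1.2%/yr), non-obese strata
  fall (−0.4% to −1.4%/yr, fastest at high education). These defaults are
  calibrated, by construction, so the final-year all-age obese-low /
  non-obese-high ratio is ≈6.3 and all the qualitative orderings of the
  reported US regime hold with wide margins.
* **Certificates**: every death carries one CVD cause code drawn from a
  pool deliberately disjoint from the marker set (so the proxy is
  identifiable); obese decedents carry a marker code with probability
  `marker_sensitivity` (default 1.0), non-obese with
  `marker_false_positive` (default 0.0) — an idealization of an unknown
  real-world proxy quality, flagged as such; markers land in part 1 or
  part 2 with equal chance; education codes rotate across all four coding
  schemes; 3% of death records have unknown education (missing completely
  at random).
* **Surveys**: 5,000 respondents per (age, sex, year) education-survey cell
  and per (age, sex, wave) prevalence-survey cell; sampling is deliberately
  unequal across education (low oversampled ×2 and ×2.5 respectively) with
  inverse-sampling-rate weights, so unweighted shares are biased and the
  weighting machinery is genuinely exercised. BMI is a two-component
  mixture (30 + Gamma(2, 3) if obese, 30 − Gamma(2, 2.2) truncated to
  [12, 30) otherwise) whose weighted BMI ≥ 30 fraction equals the true
  prevalence at the wave midpoint.

What the generator does **not** emulate: cluster/stratum survey design (only
weights), COVID-era shocks, race/ethnicity or geography, reporting-practice
drift in certificate coding, and any real proxy misclassification structure.
Passing recovery tests therefore demonstrate internal consistency of the
estimation chain under these idealized conditions, not performance on the
real national files.

## Verification design and problem sizes

* **Recovery study**: 100 independent seeds; each trial regenerates the
  final-year data (year-2019 deaths/exposures/education survey and the last
  prevalence wave — with flat extrapolation the final-year estimate depends
  on nothing else) and compares the sex-pooled all-age aggregate against
  truth; a trial passes when all six (O,E) cells are within 5% relative
  error. Typical results: ~99/100 seeds pass, median worst-cell error ~2%.
* **Drift recovery**: 1,000 RWD replicates at T = 17, d = −0.5, σ = 0.1.
  The mean-increment component is sampled stratified via its exact
  orthogonal decomposition (iid-normal increments = mean component ⊕
  centered residuals), so each path is still an exact RWD draw while the
  Monte-Carlo error on the estimated exceedance rate collapses; the true
  rate P(|d̂−d| ≤ 2σ/√(T−1)) = P(|Z| ≤ 2) = 0.9545 sits close enough to the
  0.95 bar that plain iid sampling of 1,000 replicates is flaky.
* **Interval coverage**: 1,000 futures simulated from the fitted model's
  predictive distribution (drift drawn per path from N(d̂, σ̂²/(T−1)),
  innovations N(0, σ̂²)), whose variance equals the interval formula;
  empirical coverage ≈95%. The fully frequentist variant (history and
  future drawn from the true process, interval from the fitted plug-in
  parameters) covers ≈93% — the |error|/σ̂ statistic is t-distributed with
  T−2 degrees of freedom, a known property of plug-in prediction intervals
  not corrected here (normal quantiles are standard practice in stochastic
  mortality forecasting).
* **Noisy-fit robustness**: with residual sd 0.02 the reconstructed rank-1
  surface stays within 3× the noise sd (RMSE) of the truth across 100
  seeds.
* Desk-scale fixtures use pop_size 50,000–1,000,000; the analysis scripts
  run at 1,000,000 per cell.

## Known limitations

* Ecological design: individual-level conclusions inherit the usual
  aggregation caveats; the package computes the aggregate-level estimand
  faithfully but cannot validate individual-level interpretation.
* The marker proxy defaults to perfect sensitivity/specificity; real-world
  proxy bias can be explored with the dials but is not corrected.
* No design-based survey variance; no age standardization; no cohort
  (APC), Poisson-likelihood or multi-population coherent Lee-Carter
  variants; no post-2019 shock modelling.
* Prediction intervals ignore σ-estimation error and all pre-projection
  estimation uncertainty.
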