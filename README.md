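# cvdfusion

Joint modelling of premature (35–74 y) cardiovascular-disease mortality by
obesity status and educational attainment: multiple-cause-of-death ICD-10
classification, survey-weighted prevalence estimation, Bayes-theorem fusion
of four data sources, and Lee-Carter projection with 95% prediction
intervals.

## The problem

US premature CVD mortality has stopped declining, obesity prevalence is high
and rising, and both show strong educational gradients — but no single data
source observes death, obesity and education together at the individual
level. The national sources each see a piece:

* a multiple-cause death file (every condition on the certificate, plus the
  decedent's education),
* census population exposures,
* a household survey measuring educational attainment with weights,
* an examination survey measuring BMI and education in two-year waves.

`cvdfusion` fuses these at the (age group, sex, year) level via Bayes'
theorem,

```
Pr(CVD | O, E) = Pr(O, E | CVD) · Pr(CVD) / ( Pr(O | E) · Pr(E) )
```

where `O ∈ {0,1}` is obesity and `E ∈ {low, middle, high}` education.
`Pr(O, E | CVD)` uses obesity-related CVD mortality — an any-mention CVD
death (ICD-10 I00–I45, I47–I99, cardiac arrest excluded) that also carries a
marker code (diabetes E10–E14, chronic kidney disease N18, obesity E65–E66,
lipidemias E78, hypertension I10–I15) — as a proxy for CVD death of an obese
person.

Each of the 12 (sex × obesity × education) strata of the resulting surface
is then fitted with the Lee-Carter model

```
log m_{x,t} = a_x + b_x·κ_t + ε_{x,t},   Σ_x b_x = 1,  Σ_t κ_t = 0
```

and κ_t is forecast ten years ahead by a random walk with drift
(ARIMA(0,1,0)), with prediction intervals that include drift-estimation
uncertainty.

Because the real national files are restricted-access, the package ships a
first-class synthetic generator: a parametric ground-truth world with known
`Pr(E)`, `Pr(O|E)` and `Pr(CVD|O,E)` surfaces emits all four datasets
(death certificates with part-1/part-2 code lists and rotating education
coding schemes, exposures, and two informatively-weighted surveys), so every
pipeline stage can be checked against the truth and against individual-level
counting oracles.

## Worked example

```sh
cvdfusion run-all --seed 0 --outdir results/run0        # full pipeline
python analysis/01_generate_data.py                     # or step by step
python analysis/02_classify_deaths.py
...
python analysis/05_fit_project.py
```

At one million person-years per (age, sex, year) cell the analysis scripts
print, among other things:

```
all-age Pr(CVD | O, E) per 100,000, 2019:
  female Lob= 548.3  Lno= 265.1  Mob= 371.7  Mno= 178.0  Hob= 205.1  Hno=  87.3
         obese-low vs non-obese-high disparity: 6.3x
  male   Lob= 780.7  Lno= 415.7  Mob= 526.1  Mno= 251.0  Hob= 267.0  Hno= 128.4
         obese-low vs non-obese-high disparity: 6.1x

projected 2029 all-age rates per 100,000 (95% PI):
  female middle  obesity=1:  424.0 (371-485)
  male   middle  obesity=1:  576.5 (481-693)
```

Reading: in the final observed year the conditional probability of premature
CVD death is ~6× higher for the obese low-education population than for the
non-obese high-education population, and the obese middle-education strata
carry positive drift (rates projected to keep rising through 2029) while the
non-obese high-education strata decline — the qualitative regime the default
world is calibrated to.

Library surface: `cvdfusion.build_world`, `cvdfusion.synth.*` (generators),
`cvdfusion.icd` / `cvdfusion.education` (classification, harmonization),
`cvdfusion.prevalence` (weighted estimation), `cvdfusion.fusion` (Bayes
fusion and aggregation), `cvdfusion.leecarter` (fits, projection, annualized
trends), `cvdfusion.pipeline.run` (orchestration).

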