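# curesurv

Survival and biomarker analysis for cancer cohorts that contain a
substantial fraction of long-term survivors, built around the gastric /
esophagogastric-junction adenocarcinoma setting: HER-family
immunohistochemistry (IHC) marker agreement, positivity-by-stage
association, and parametric survival modelling with a cured subpopulation.
It is aimed at biostatisticians and clinical researchers who need a
Cox-free, fully parametric analysis when the proportional-hazards
assumption fails and the Kaplan–Meier curve plateaus.

## The model

When a cohort contains patients who will never experience the event, the
population survival is a two-component mixture

    S(t) = π + (1 − π) · S_W(t),      S_W(t) = exp(−(t/λ)^k),

where π is the **cure fraction** (the plateau of the survival curve) and
the susceptible subpopulation follows a Weibull with shape k and scale λ
(months).  Setting π = 0 gives the plain Weibull model and additionally
k = 1 the exponential, so the three candidates form a nested family, all
fitted by maximum likelihood to right-censored data:

    ℓ = Σ_deaths log[(1 − π) f_W(t_i)] + Σ_censored log[π + (1 − π) S_W(t_i)]

Covariates can enter the cure probability (logit link) and/or the Weibull
scale (log link), giving a prognostic-factor regression that remains valid
when hazards are non-proportional.  The nonparametric side provides the
Kaplan–Meier product-limit estimate with Greenwood variance, median
follow-up by reverse KM, and an Epanechnikov-kernel smoothed empirical
hazard.

The marker battery covers Cohen's kappa and the (uncorrected) McNemar test
for agreement between dichotomized IHC calls (0/1+ negative, 2+/3+
positive), and Pearson's chi-square for marker-by-covariate association.

Because the patient-level data of the emulated study were never deposited,
`curesurv.simulate` generates cohorts with the published statistical
structure: correlated binary markers with prescribed marginals and
pairwise kappas (by inverting the kappa formula), cure-mixture survival
with covariate effects, and a deterministic 201-patient "study replica"
whose summary tables match the published ones exactly.

## Worked example

```sh
curesurv simulate --seed 2 --out cohort.csv
# wrote 201 records to cohort.csv
curesurv fit --cohort cohort.csv --model weibull_cure --out fit/
# {"cure_fraction": 0.5748..., "shape": 1.5305..., "scale_months": 12.657...}
```

The fit excludes the 12 flagged postoperative deaths (n = 189 analyzed)
and reports, in `fit/fit_weibull_cure.json`, the cure fraction with its
delta-method 95 % CI on the logit scale.  On the replica cohort with seed
1 the estimate is π̂ = 0.50 (CI 0.42–0.58): about half the cohort is
modelled as long-term survivors, and the CI width (~0.17) is what ~83
deaths among 189 patients can support.  The same library calls are
available programmatically:

```python
from curesurv import study_replica_cohort, exclude_postoperative_deaths, fit_mle

cohort = exclude_postoperative_deaths(study_replica_cohort(seed=1))
t = cohort.df["time_months"].to_numpy(float)
e = cohort.df["event"].to_numpy(int)
fit = fit_mle(t, e, "weibull_cure")
print(fit.params)   # CureModelParams(pi=0.501, shape=1.483, scale=13.239)
```

`curesurv report --cohort cohort.csv --out report/` runs the whole
pipeline: pairwise agreement and positivity tables, KM curve, the three
parametric fits with AIC ranking, hazard curves, the cure-fraction CI and
the covariate cure regression, each as TSV/JSON with a digest manifest.
Column semantics for cohort files are in
`curesurv.cohort.data_dictionary()`.

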