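# Methods

## Scientific setting

The package reproduces, as tested software, a survival-and-biomarker
analysis of a 201-patient gastric / esophagogastric-junction
adenocarcinoma cohort (stages 0–IV, primary tumor resection, accrued over
roughly three years) in which HER-family receptors (HER1–HER4) were scored
by immunohistochemistry on tissue microarrays.  Two features shape the
statistics: a large group of long-term survivors makes the Kaplan–Meier
curve plateau near 50 % — so a mixture cure model, not a Cox model, is
the appropriate survival machinery — and the IHC scores are analyzed as
dichotomized calls (0/1+ negative, 2+/3+ positive) through an agreement
and association battery.  The patient-level data were never deposited;
only summary tables are public, so a synthetic generator provides the
patient-level inputs and the printed tables serve as numeric anchors.

## The mixture cure model

Population survival is `S(t) = π + (1 − π) exp(−(t/λ)^k)` with cure
fraction π ∈ [0, 1), Weibull shape k > 0 and scale λ > 0 (months).  The
parameterization `S_W = exp(−(t/λ)^k)` is stated explicitly on every
output because the Weibull has several common conventions.  The population
hazard `h(t) = (1 − π) f_W(t) / S(t)` decays to zero as the at-risk pool
becomes dominated by cured patients.

The right-censored log-likelihood (deaths contribute `log[(1 − π) f_W]`,
censored records `log[π + (1 − π) S_W]`) is maximized on the
unconstrained transforms (logit π, log k, log λ) by BFGS with five starts:
the base start takes π from the last Kaplan–Meier value, λ from the
median event time and k = 1; the others jitter these (SD 0.5 on the
transformed scale, seeded).  Multi-start matters because mixture
likelihoods can be multi-modal.  Tolerances: gradient 1e-8, parameters
1e-6.  Events recorded at t = 0 (where the Weibull density is degenerate)
are shifted to half the smallest positive time with a warning; in the
intended workflow they never reach the fitter because postoperative
deaths are excluded upstream.

Standard errors come from the central-difference observed information on
the transformed scale; the cure-fraction CI is delta-method on the logit
scale (bounds therefore always inside (0, 1)), with a profile-likelihood
fallback when the information matrix is not positive definite.  Model
choice across the nested family (exponential ⊂ Weibull ⊂ Weibull cure)
is summarized by AIC; the boundary identities (π = 0, k = 1) hold to
machine precision and are enforced by tests.

### Covariate regression

Covariates act on logit(π_i) and/or log(λ_i) with a single shared shape k
— the simplest model consistent with a "cure regression adjusted for
clinicopathological factors" analysis.  Treatment coding against explicit
reference levels; continuous covariates optionally standardized; Wald
inference; no variable selection.  Which parameters the covariates should
enter is genuinely open in this kind of analysis, so both links are on by
default and either can be selected alone; an intercept-only design
reduces exactly to the plain mixture-cure fit (tested to 1e-6 in
log-likelihood).  Separation in the cure part (a covariate level with no
events) is detected and warned about rather than silently inflating Wald
intervals.

## Nonparametric side

Kaplan–Meier with Greenwood variance, deaths preceding censorings at tied
times.  Median follow-up uses the reverse-KM convention (censoring as the
event); how the emulated study computed its 30.26-month figure is
unstated, so reverse KM is a documented assumption and a naive
median-of-censored-times alternative is provided for comparison.  The
smoothed empirical hazard kernels the Nelson–Aalen increments d_i/n_i
with an Epanechnikov kernel (default bandwidth 3 months), reflected about
t = 0 as boundary correction.  The published "instantaneous risk" curve
shows local peaks that no smooth three-parameter mixture hazard can
produce, so the package exposes both the parametric mixture hazard and
this empirical smoother and claims fidelity for neither shape.

## Agreement and association battery

Cohen's kappa is computed unweighted on the dichotomized calls;
the McNemar statistic is `(b − c)²/(b + c)` **without** continuity
correction — on the discordant pair (12, 29) the uncorrected test
reproduces the published p = 0.008 while the corrected one gives ≈ 0.012,
which fixes the convention; Pearson's chi-square uses no Yates correction
and no exact tests, with small expected counts logged (the IV M1 column
has expected counts below 5) but not fatal.  Pairwise analyses use
pairwise complete cases, so denominators vary by marker
(198/201/200/199).  P-values display as three decimals with `<0.001`
below 0.0005.  No multiple-testing adjustment is applied, matching the
emulated analysis.

Of the printed agreement table, 13 of 15 kappas recompute exactly from
their own cells; the HER1-membrane × HER4-membrane kappa (printed 0.279)
recomputes to ≈ 0.074 and HER1-cytoplasm × HER4-membrane (printed 0.0)
to ≈ −0.069 — both are carried as documented discrepancies, never used as
oracles.  Likewise two of six stage-association p-values (printed 0.258
and 0.321) recompute to ≈ 0.856 and ≈ 0.505 from the printed counts and
are flagged, not matched.

## Synthetic data

`solve_joint_2x2` inverts the kappa definition: given margins (p₁, p₂)
and a target κ, observed agreement is `p_o = p_e + κ(1 − p_e)` and
`p₁₁ = (p_o − 1 + p₁ + p₂)/2`, validated against the Fréchet bounds with
the feasible κ range reported on error.  Markers are simulated by a chain
construction anchored on membrane HER2: each marker is drawn
conditionally on the anchor from the solved pairwise law, so marginals
and anchor-pairwise kappas are honored; higher-order structure is
unspecified, and reproducing all 15 printed pairwise tables jointly is
not attempted (their joint feasibility is unverified).

Survival defaults are the study conditions, calibrated once by
quadrature before any testing: cure fraction 0.51; Weibull shape 1.4 and
scale 14 months for the susceptible group; censoring uniform on
(12.3, 48.3) months, i.e. 36 months of accrual with an administrative
cutoff placed so the expected death count is 82.9 of 189 (published: 83)
and the reverse-KM median follow-up is ≈ 30 months (published: 30.26).
Cured subjects can only be censored.

`study_replica_cohort` builds a deterministic 201-record cohort: exact
categorical marginals (categories whose printed counts do not sum to 201
— location 198, Laurén 197, radicality 199, nodal status 197, stage 198 —
leave the remainder missing rather than being reconciled), exact
per-marker denominators and positives per stage group, the published
2+/3+ ordinal splits, 12 flagged postoperative deaths, and survival from
the calibrated cure model.  Within those hard constraints the
row-assignment is seeded: positive calls lean toward HER2-positive rows
(using the published conditional rates) and HER2/HER3-positive rows lean
toward intestinal Laurén type and older age, so the replica reproduces
the published qualitative associations.  Ages are a fixed grid spanning
27–88 with median 62, assigned by noisy rank-matching.

What the generator does **not** emulate: real joint dependence between
covariates and survival beyond the calibrated model, within-patient
biological correlation among all 15 marker pairs simultaneously, staging
drift, or informative censoring.  Passing tests therefore demonstrate
that the implementation recovers the truth of this generative model at
the study's scale — not that the model is true of any real cohort.

## Recovery experiments and problem sizes

The cure-fraction experiment runs 200 cohorts at n = 189 (the analyzed
sample size): the MLE's mean is within 0.03 of π = 0.51, the 95 % CI
covers the truth 90–98 % of the time, and the mean CI width (~0.17)
matches what ~83 deaths can support.  The regression experiment runs 100
replicas with one true stage-group effect (logit-cure coefficients −1.2
and −2.5 for the two advanced-stage indicators, baseline cure 0.75) among
8 covariates at n = 189, covariates on the cure link only to keep the
design at the data's scale: the stage covariate's 95 % CI excludes zero
in ~100 % of replicas while every null covariate stays at its nominal
~5 % false-positive rate.  Note that the rate at which stage is the
*sole* flagged covariate is bounded by power × 0.95⁷ ≈ 0.70 for seven
null terms — an arithmetic consequence of nominal coverage, not an
implementation defect — so "only stage is prognostic" is assessed
per-covariate, exactly as a reader of a multivariable table would.
These sizes keep the full suite under a minute of simulation time while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Non-mixture (promotion-time) cure models, Bayesian fitting,
  time-dependent covariates, and Cox diagnostics are out of scope.
* Wald intervals near the π boundary (very high or very low cure
  fraction) can be unstable; the profile-likelihood fallback mitigates
  but does not remove this.
* The smoothed hazard's reflection boundary correction is first-order;
  very short follow-up with heavy early mortality will still bias the
  estimate near t = 0.
* Date arithmetic is out of scope: input times are already months since
  surgery.
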