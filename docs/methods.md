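# Methods

`gastropd` reimplements, as a tested library, a population pharmacodynamic
analysis of neoadjuvant therapy in locally advanced gastric and
gastroesophageal-junction (GEJ) adenocarcinoma: an ordered-categorical
mixed-effects model of clinical tumor response with first-order Markov
elements, coupled to a parametric time-to-event model of metastasis
appearance and overall survival, together with the surrounding machinery —
likelihood-ratio covariate screening, visual predictive checks, a
nonparametric bootstrap, descriptive concordance analyses, and a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes.

## Clinical response model

At each assessment visit `j` (diagnosis, on-treatment, pre-surgery,
surgery/pathology) patient `i` is in one of three ordered categories derived
from the TNM stage change since the previous assessment: 0 = partial
response (downstaging), 1 = stable disease (no change), 2 = disease
progression (upstaging).  All patients are category 2 at diagnosis by
construction.  Cumulative probabilities follow a proportional-odds logistic
model with a shared subject-level random effect:

    P(Y_ij >= m | eta_i) = expit(L_m),   m = 1, 2
    L_m = sum_{k<=m} beta_k  -  theta_PVR(j)  +  sum_c theta_c x_ci  +  eta_i
    eta_i ~ N(0, omega^2)

`beta_1` and `beta_1 + beta_2` are the diagnosis-visit logits (monotonicity
of the cumulative probabilities requires `beta_2 <= 0`; parameter values
violating it yield a likelihood of zero rather than silently reordered
categories).  `theta_PVR` is the first-order Markov element: a
previous-visit-response effect, one value per previous category
(PR / SD / DP), applied at follow-up visits only.

**Sign convention.**  The previous-state effects are *subtracted* from the
logit.  With the reference estimates (baseline logit 19.7, previous-state
effects 18.1–19.4) the subtraction yields follow-up logits of order 1 and
realistic transition probabilities, whereas addition would drive every
follow-up probability of response to zero.  The convention is a modelling
choice, exposed as `ResponseParams.markov_sign` (default −1).

Optional covariate terms (CRT arm, HER2, linitis plastica, dose intensity,
chemotherapy backbone indicators supplied externally) enter the logit
additively and are available for the screening stage; in the reference
analysis they collapse to the Markov terms alone.

### Marginal likelihood

The conditional trajectory likelihood given `eta` is the product of
per-visit category probabilities, each visit conditioning on the previously
*observed* category (missing visits contribute nothing and do not update the
Markov state; subjects with only the deterministic diagnosis visit
contribute a likelihood of ~1 and are retained).  The subject's marginal
likelihood integrates `eta` out of this product.  Three routes are
implemented:

* **Laplace** — damped Newton search for the per-subject mode of
  `l_i(eta) − eta²/(2ω²)` followed by the one-term Gaussian approximation
  `log m_i = l_i(η̂) − η̂²/(2ω²) − ½ log(1 − ω² l_i''(η̂))`.  The mode search
  uses analytic first and second derivatives (closed forms in the expits of
  the two logits) and a *fixed* count of 12 damped Newton iterations rather
  than a data-dependent stopping rule: iteration counts that vary with the
  parameters make the outer objective non-smooth at the 1e−3 level, which
  corrupts simplex convergence and finite-difference information matrices.
  Twelve iterations drive the Newton step below 1e−10 in these unimodal
  one-dimensional problems.
* **Adaptive Gauss–Hermite quadrature** — nodes centred at the Laplace mode
  and scaled by the local curvature, 21 nodes by default (configurable); at
  64 nodes it matches brute-force adaptive integration to ~1e−15 per
  subject on test fixtures.
* **Monte Carlo** — plain sampling of `eta`, vectorized over draws, with a
  delta-method standard error on the log scale; used only as a stochastic
  oracle.

**Accuracy of the Laplace route, and the choice of fitting objective.**  The
one-term Laplace expansion carries a truncation error that grows like
`omega^4` (measured against brute-force integration: ~2e−4 per subject at
ω² = 0.05, ~1e−2 at ω² = 1 for four-visit subjects).  This error is a
property of the approximation — any correct implementation, including the
estimation software used in the original analysis, shares it.  Two
consequences shape the package:

* Cross-validation of the three routes against each other is performed at
  ω² = 0.05, a regime where the expansion is valid, so that the test
  separates implementation bugs from approximation error; the residual
  ~3e−2 total discrepancy at ω² = 1 on a 5-subject fixture is asserted at a
  loose bound and documented here.
* `ClinicalResponseModel.fit()` maximizes the *quadrature* objective by
  default.  With only two or three informative observations per subject,
  maximizing the Laplace objective systematically shrinks the
  random-effect variance (the Laplace deficit is largest at large ω², so
  the optimizer buys spurious likelihood by reducing it; in simulation at
  the reference parameter values the Laplace-objective estimate of ω² was
  ~0.14 against a truth of 1.0).  AGH-21 costs roughly three Laplace
  evaluations here and removes the bias.  `integration="laplace"` remains
  available for likelihood evaluation and ranking.

### Fitting, uncertainty, identifiability

Optimization is quasi-Newton (L-BFGS-B with finite-difference gradients) on
transformed scales (`log omega²`); the smoothness engineered into the inner
mode search is what makes those gradients reliable.  A gradient-based
search is used deliberately instead of a simplex: along the near-flat shift
direction described below a simplex random-walks over tens of units while
gaining less than the function tolerance, whereas the quasi-Newton step in
a zero-gradient direction is zero.  Any subset of parameters can be
frozen through the `free` mask; an empty mask evaluates the OFV at the
initial values without searching.  The covariance of the estimates is the
inverse observed information from a central finite-difference Hessian of
the OFV, mapped back to natural scales by the delta method.  Eigenvalues of
the information below 1e−10 of the largest are floored, so near-flat
likelihood directions map to very large — rather than negative or infinite
— variances.

One such flat direction is intrinsic to this design: because every subject
starts in category 2 with probability ≈ 1, a common shift of
`beta_1` and all three previous-state effects leaves every follow-up logit
unchanged and is resisted only by the (nearly saturated) diagnosis-visit
term.  The four parameters are therefore individually weakly identified
(their reported standard errors are honest, i.e. large — of order 14 at
n = 1000) while their pairwise differences, `beta_2` and `omega²` are
estimated precisely.  Simulation–estimation experiments initialize at the
generator values, the standard practice for stochastic
simulation-and-estimation studies.

## Survival model

Metastasis appearance and death are parametric time-to-event processes.
The death hazard is

    h(t) = [lambda0 + delta_stage·1(cTNM ≥ III) + delta_linitis·1(linitis)]
           · b(t) · exp(beta_met · 1(t ≥ t_met))

with `b(t) = 1` (constant/exponential; the selected family), `k t^(k−1)`
(Weibull) or `e^(γt)` (Gompertz), and `S(t) = exp(−HZ(t))`.  Baseline
covariates act *additively* on the rate — the reference estimates put the
stage and linitis effects on the same 1e−4 /day scale as the baseline —
while metastasis acts *multiplicatively* from the observed metastasis time
onward (`beta_met` is a log hazard ratio; `e^3.43 ≈ 31`).  Time is measured
in days from diagnosis.

Cumulative hazards use exact closed forms in all three families, piecewise
across the metastasis switch; a quadrature-based route is retained and
tested to agree within 1e−8.  The censored-data log-likelihood is
`Σ_obs log h(t_i) − Σ_all HZ(t_i)`.  Fitting is Nelder–Mead (the survival
likelihood has no flat ridge) with `lambda0`
(and the Weibull shape) on the log scale and the additive increments in
units of the initial baseline rate, so every internal coordinate is O(1);
this scaling matters both for the simplex and for the finite-difference
information (raw steps of 1e−3 on a 1e−4 /day increment would leave the
admissible region).  Event times are simulated by inverse-CDF sampling —
closed-form piecewise inversion for the constant family, bracketed
root-finding otherwise — with administrative right-censoring.

Kaplan–Meier estimation is the standard product-limit estimator with
events preceding censorings at tied times; it is cross-checked against an
independent implementation (lifelines) in the test suite.

## Covariate screening

Nested models are compared on the OFV scale.  For one degree of freedom the
published decision ladder 3.86 / 6.63 / 7.88 / 11.87 (5 / 1 / 0.5 / 0.1 %)
is applied verbatim by default — its 0.1 % entry is slightly more
conservative than the exact χ²₁ quantile 10.828 — with exact quantiles as an
option and always for df > 1.  The boundary counts as significant.  The
screen itself is greedy forward addition at α = 0.05 (configurable): each
round refits every remaining single-covariate addition and admits the
largest significant OFV drop; failing or non-convergent inner fits are
recorded in the trace and skipped for the round.  No backward-elimination
step is performed.

## Model evaluation

* **Categorical VPC** — `n_sim` (default 500) replicate cohorts are
  simulated under fixed parameters on the observed visit pattern; per visit
  and category, the observed proportion is compared with the 2.5/50/97.5
  percentile envelope of the simulated proportions.
* **Kaplan–Meier VPC** — replicate event datasets are simulated under the
  fitted hazard (optionally re-simulating the metastasis process at a given
  rate) and the observed KM curve is compared with the percentile envelope
  of simulated KM curves on a time grid, optionally stratified by
  metastasis status, stage or linitis.  Each subject's potential follow-up
  is taken from the design (for real data it defaults to the observed time
  for censored subjects — an approximation appropriate for administrative
  censoring).
* **Bootstrap** — subjects are resampled with replacement (visits and
  events travel with the subject, preserving within-subject correlation),
  the model is refit per replicate (200 by default), and 2.5/50/97.5
  percentiles of each parameter are reported with the convergence count;
  more than 50 % failures flags the result unreliable.  Percentiles use the
  linear-interpolation empirical quantile convention throughout.

Parameter uncertainty is deliberately not propagated into the VPCs
(fixed-parameter simulation).

## Descriptive statistics

Spearman correlations are Pearson correlations of midranks
(pairwise-complete; undefined for constant vectors).  Clinical–pathologic
concordance compares baseline clinical T rank with ypT rank, clinical nodal
status (cN±, rank 0/1) with ypN rank, and the final clinical response
category with a *pathologic response category* obtained by applying the
same downstage / no-change / upstage rule to the clinical-to-pathologic
stage change (any upstaging in T or N dominates; ordinal codes 0/1/2).
Cohort summaries report counts and percentages per characteristic block,
median (range) age, and the complete-pathologic-response (ypT0 ypN0) count.

## Synthetic cohort generator

The generator defines the study conditions for every simulation experiment:

* **Covariates** — independent draws matching the published cohort
  characteristics (70.4 % male, 65.2 % cT3, 72.2 % cN+, 69.6 % stage III,
  24.3 % linitis, 56.5 % CRT arm, …); age is triangular(31, 62, 83),
  reflecting the published median and range.  HER2 prevalence (15 %) and
  the dose-intensity range (0.7–1.0) are not published and are configurable
  generator choices.  Correlations *among* baseline covariates are not
  modelled; the only injected dependence is the clinical–pathologic link
  below, because it is the quantity the concordance analysis measures.
* **Response trajectories** — simulated from the response model at a fixed
  visit schedule (0/42/84/120 days — an invented schedule consistent with a
  5-week chemoradiotherapy course and surgery 4–6 weeks later;
  configurable), diagnosis forced to category 2.
* **Events** — a latent metastasis time from a constant hazard
  (default 2e−4 /day, a generator truth value: no metastasis-model
  parameters were published), a death time from the survival model with the
  metastasis switch, and censoring from uniform accrual over 5 years with a
  10-year administrative cutoff.  Metastasis records are censored at the
  death/censoring time when the latent time exceeds it, so the
  metastasis-before-death ordering holds by construction.
* **Pathology** — ypT and ypN ranks are drawn from the published marginal
  distributions through a Gaussian copula against clinical T and N.  The
  latent correlation is calibrated so that the *midrank Spearman
  correlation of the discretised pair* equals the configured target
  (default 0.32 for T, 0.19 for N): the discretised Spearman is computed in
  closed form from bivariate-normal cell probabilities (Owen's T function)
  and inverted by root-finding, which the tests verify to ±0.03 at
  n = 10⁴.  Enforcing a third target — the clinical-response /
  pathologic-response correlation — simultaneously would over-determine the
  copula; that correlation is therefore emergent and merely reported.
  Every ypT0 draw is assigned ypN0, mirroring the reference cohort in which
  all complete pathologic responders were the ypT0 patients; the injected
  pCR count therefore equals the ypT0 count (at the cost of slightly
  inflating the ypN0 marginal).

What passing tests on these cohorts do **not** show: robustness to
correlated baseline covariates, informative censoring, irregular visit
timing, or misclassified response categories — none of which the generator
emulates.

## Problem sizes and numerical choices

Simulation experiments use n = 1000 subjects and 20 replicates for
parameter recovery (response: 3-visit schedule; survival: full design),
20-seed batteries for VPC envelope coverage (n_sim = 500 at the study size
of 115) and bootstrap coverage (200 replicates each), sizes at which the
recovery and coverage criteria are statistically meaningful while the full
suite runs in minutes on one core.  Ties in the KM estimator resolve events
first; probabilities are clipped at 1e−300 before logs; `omega² = 0` is
handled as the degenerate conditional likelihood at `eta = 0`; the
comonotone (ρ = ±1) copula limits bypass the latent-normal draw entirely.

## Known limitations

* The published transition-to-partial-response percentages (29.1 / 84.7 /
  5.9 %) are not reproducible from the published parameter table under any
  sign convention; the package treats them as narrative illustrations, not
  checkable quantities.
* The pathological baseline logits are published without a stated model
  structure; the package models pathology as a single post-treatment
  observation and makes no use of those two values.
* Published hazard ratios (33 / 2.9 / 2.8) differ slightly from the closed
  forms implied by the published parameters (30.9 / 3.0 / 2.0); the package
  computes the closed forms from whatever parameters it estimates.
* No FOCE-interaction or SAEM estimation, no continuous-time Markov
  intensities between visits, no competing risks, no interval censoring,
  no semiparametric (Cox) fitting.
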