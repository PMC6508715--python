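# gastropd

Population pharmacodynamic modelling of neoadjuvant therapy in locally
advanced gastric and gastroesophageal-junction (GEJ) adenocarcinoma.

Patients with locally advanced gastric/GEJ cancer receive chemotherapy or
chemoradiotherapy before surgery, and the clinical question is whether the
trajectory of clinical response during that treatment — together with
baseline tumor characteristics — predicts metastasis and death.  `gastropd`
implements the modelling framework used to study that question on a
115-patient cohort, as a reusable, tested library for biostatisticians and
pharmacometricians:

* **Clinical response** is an ordered categorical variable per visit
  (0 = partial response, 1 = stable disease, 2 = disease progression,
  derived from TNM down-/up-staging), modelled with cumulative logits,
  a first-order Markov dependence on the previous visit's category, and a
  subject-level random effect:

  `P(Y_ij ≥ m | η_i) = expit( Σ_{k≤m} β_k − θ_PVR(j) + Σ_c θ_c x_ci + η_i )`,
  `η_i ~ N(0, ω²)`.

  The marginal likelihood integrates η by Laplace approximation, adaptive
  Gauss–Hermite quadrature, or Monte Carlo.
* **Metastasis and overall survival** follow a parametric time-to-event
  model, `S(t) = exp(−HZ(t))`, with a constant (exponential), Weibull or
  Gompertz baseline hazard, additive baseline-hazard increments for cTNM
  stage ≥ III and linitis plastica, and a multiplicative time-dependent
  effect `exp(β_met)` switching on at the observed metastasis time.
* **Covariate screening** uses likelihood-ratio tests on the −2LL scale
  with the decision ladder 3.86 / 6.63 / 7.88 / 11.87 (5/1/0.5/0.1 %, df=1)
  and greedy forward selection.
* **Evaluation**: categorical and Kaplan–Meier visual predictive checks
  (500 simulated replicates, 2.5/50/97.5 percentile envelopes) and a
  subject-resampling nonparametric bootstrap (200 replicates).
* **Synthetic cohorts**: a generator reproducing the study's covariate
  frequencies, visit schedule, Markov response trajectories, event
  processes with censoring, and clinical–pathologic staging concordance
  injected through a calibrated Gaussian copula — so the entire pipeline is
  testable without any patient data.

See `docs/methods.md` for the model details, numerical choices, and known
limitations.

## Worked example

```python
import numpy as np
from gastropd import (SimulationConfig, simulate_cohort,
                      ClinicalResponseModel, ParametricSurvivalModel,
                      ResponseParams, HazardParams, hazard_ratio)

# a 115-patient synthetic cohort under the reference study conditions
cohort = simulate_cohort(SimulationConfig(n_patients=115, seed=42))

# fit the ordered-categorical Markov response model
init = ResponseParams(beta=(19.7, -4.62),
                      theta_markov={"PR": 18.1, "SD": 19.4, "DP": 18.8},
                      omega2=1.0)
res = ClinicalResponseModel(cohort).fit(init=init)
print(res.summary())

# fit the constant-hazard survival model with the metastasis switch
os_fit = ParametricSurvivalModel(cohort, family="constant").fit(
    init=HazardParams(lambda0=1e-4, delta_stage=1e-4, delta_linitis=2e-4,
                      beta_met=3.43),
    free=["lambda0", "delta_stage", "delta_linitis", "beta_met"])
print(os_fit.summary())
print("metastasis HR:", round(hazard_ratio(os_fit.estimates, "metastasis"), 1))
```

Output:

```
Clinical response model (ordered categorical, first-order Markov)
  subjects: 115   observations: 460
  OFV (-2LL): 546.4126   converged: True

          estimate     se  rse_percent  lower95  upper95
beta1        19.64  47.01        239.4   -72.51    111.8
beta2       -4.552 0.4403        9.671   -5.415   -3.689
theta_pr     18.11  47.01        259.6   -74.04    110.3
theta_sd     19.43  47.01          242   -72.72    111.6
theta_dp     18.83  47.01        249.7   -73.32      111
omega2       1.691 0.8111        47.95   0.1017    3.281
Parametric survival model (constant baseline hazard)
  subjects: 115   events: 79
  OFV (-2LL): 1217.0701   converged: True

               estimate        se  rse_percent   lower95   upper95
lambda0       0.0001297 3.705e-05        28.57 5.705e-05 0.0002023
delta_stage   0.0001298  5.02e-05        38.68 3.138e-05 0.0002282
delta_linitis 0.0001766  9.43e-05        53.39 -8.21e-06 0.0003615
beta_met          3.328    0.2275        6.835     2.882     3.774
metastasis HR: 27.9
```

Reading the response block: the follow-up logits depend on the parameters
only through differences such as `beta1 − theta_sd` (≈ 0.2 here), so those
four estimates are individually weakly identified — the honest ~47-unit
standard errors flag exactly that — while `beta2` (the spacing of the two
cumulative logits) and `omega²` (between-patient variability) are precise.
In the survival block, the baseline death hazard is ~1.3e−4 per day for a
stage-II patient without linitis before metastasis; stage III and linitis
plastica each add roughly the same again; metastasis multiplies the hazard
by `e^3.33 ≈ 28`.  The relative standard errors reflect the modest event
count (79 deaths) at this cohort size.

The same pipeline is scriptable from the shell:

```bash
gastropd all --seed 1 --n-sim 500 --n-boot 200 --out results/
```

which simulates a cohort, fits both models, runs the covariate screen, the
visual predictive checks, the bootstrap and the descriptive analyses, and
writes every artifact as CSV plus a `run_log.yaml`.

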