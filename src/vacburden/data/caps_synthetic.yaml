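# Default synthetic youth-panel cohort: known log-RRs on the scale of
# the pooled published effects, wage reductions 11.7%/9.2%, probit
# participation with selection correlation rho = 0.5.
# partner_employed enters selection only (exclusion restriction).
n_individuals: 50000
exposure_prevalences:
  physical: 0.261
  emotional: 0.126
confounders:
- name: female
  family: bernoulli
  params:
    p: 0.5
- name: childhood_poverty
  family: bernoulli
  params:
    p: 0.35
- name: mother_edu
  family: standard-normal
- name: partner_employed
  family: bernoulli
  params:
    p: 0.4
outcomes:
  alcohol_abuse:
    intercept: -2.3025850929940455
    exposure_log_rr:
      physical: 0.4382549309311553
      emotional: 0.30010459245033816
    confounder_coefs:
      female: -0.2
      childhood_poverty: 0.15
      mother_edu: -0.05
  anxiety:
    intercept: -2.5257286443082556
    exposure_log_rr:
      physical: 0.45107561936021673
      emotional: 0.62057648772511
    confounder_coefs:
      female: 0.25
      childhood_poverty: 0.2
      mother_edu: -0.05
wage_model:
  intercept: 8.006367567650246
  reductions:
    physical: 0.117
    emotional: 0.092
  confounder_coefs:
    female: -0.25
    childhood_poverty: -0.2
    mother_edu: 0.1
  sigma: 0.6
selection_model:
  intercept: 0.3
  coefs:
    female: -0.4
    childhood_poverty: -0.3
    partner_employed: 0.5
    mother_edu: 0.1
  rho: 0.5
seed: 20150901
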