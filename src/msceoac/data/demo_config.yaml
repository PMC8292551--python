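# Demo / ground-truth configuration for the synthetic-data pipeline.
# Values echo the order of magnitude of US OAC epidemiology (male lifetime
# risk ~1%, cancer-free BE prevalence 1-2% by age 60, male:female baseline
# BE conversion 4:1); they are deliberately NOT registry-calibrated
# estimates.
seed: 0
grid:
  step: 0.1
  max_age: 100
age_range: [40, 90]
biology:
  mu0: 1.0e-2      # first hit, per BE stem cell per year
  mu1: 1.0e-2      # second hit, per one-hit cell per year
  alphaP: 2.0      # premalignant division rate
  betaP: 1.9      # premalignant death/differentiation (supercritical clone growth 0.1/y)
  mu2: 2.0e-3      # malignant transformation per premalignant cell
  alphaM: 3.0      # malignant division rate
  betaM: 2.5       # malignant death/differentiation
  rho: 0.1         # detection rate per malignant cell
segment:
  beta_a: 2.0
  beta_b: 6.0
  length_max: 10.0   # cm; Beta(2,6) gives mean segment length 2.5 cm
  cells_per_cm: 100.0
  n_quad: 16
onset:
  nu0:
    M: 2.6e-4
    F: 6.5e-5      # male:female 4:1
  cohort_multipliers:
    1930: 0.6
    1940: 0.8
    1950: 1.0
gerd:
  rr: 5.0
  curve:
    p_max: 0.25
    k: 0.15
    t0: 40.0
calibration:
  free: [nu0, mu2, cohort_multipliers]
  n_starts: 5
  maxiter: 2000
  tol: 1.0e-8
  seed: 0
  tie_mu01: true
  n_draws: 1000
  bounds:
    nu0: [1.0e-6, 1.0e-2]
    mu0: [1.0e-4, 1.0e-1]
    mu2: [1.0e-5, 1.0e-1]
    cohort_multiplier: [0.05, 20.0]
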