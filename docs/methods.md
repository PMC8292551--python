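# Methods

## Model structure and assumptions

The package implements a multistage clonal expansion model of oesophageal
adenocarcinoma (OAC) in which every cancer arises through Barrett's
oesophagus (BE). The natural history has two layers:

1. **Tissue level.** BE onset is a single conversion event with
   age-dependent hazard `nu(t) = nu0 · m_cohort · [1 + (RR−1) p_GERD(t)]`,
   so the unconditional probability of carrying BE by age t is
   `1 − exp(−Λ(t))` with `Λ = ∫ nu`. This treats the general population
   rate as the prevalence-weighted mixture of a GERD subgroup (rate
   `RR · nu0 · m`) and a non-GERD subgroup (`nu0 · m`), exactly:
   `nu_pop = (1−p) nu_non + p nu_gerd`. An alternative would be a filtered
   Poisson "patch" process with multiple independent conversions per
   oesophagus; the single-conversion form is used because prevalence then
   has the simple exponential form that the subgroup decomposition
   requires, and because nothing in an incidence calibration can separate
   the two at these prevalence levels.
2. **Cell level, conditional on onset.** A segment of length L
   (L ~ length_max · Beta(beta_a, beta_b), default mean 2.5 cm) carries
   `N(L) = cells_per_cm · L` stem cells. Each stem cell spawns one-hit
   cells at rate μ₀ (the parent persists), one-hit cells spawn
   premalignant clone founders at μ₁, premalignant cells divide/die at
   α_P/β_P and seed malignant founders at μ₂, malignant cells divide/die
   at α_M/β_M, and a malignant clone of n cells is detected at rate n·ρ
   (size-based detection). These semantics define both the backward ODE
   system solved analytically and the event loop of the stochastic
   simulator; the two are different evaluations of the same process, which
   is what makes the simulator a genuine oracle.

The backward survival system (see README for the equations) is the
standard MSCE construction: S_M solves an autonomous Riccati equation
whose constant-coefficient closed form (roots of
`α_M x² − (α_M+β_M+ρ)x + β_M`) is kept in `msceoac.reference` as an
independent cross-check, and with all clonal-expansion rates zero the
per-stem-cell hazard reduces to the classical Armitage–Doll power law
`h ∝ μ₀μ₁μ₂ρ τ³/6`, which the tests verify as a log–log slope of 3.

**Continuous stem-cell exponent.** Because cells act independently,
whole-segment survival is `S_0^N(L)` and N need not be an integer; the
simulator correspondingly uses `N · μ₀` as the (continuous) aggregate
spawning propensity of the stem-cell compartment. The two layers are
therefore exactly consistent, not approximately.

**Mortality and competing risks are out of scope**: `S_pop` is survival
free of detected OAC, and person-year tables carry the demography.

## Key parameters (units: per cell per year unless noted)

| parameter | meaning | demo default | why |
|---|---|---|---|
| μ₀, μ₁ | two-hit initiation rates | 1e-2 | tuned once so male lifetime OAC risk ≈ 1% |
| α_P, β_P | premalignant birth/death | 2.0 / 1.9 | supercritical clone growth 0.1/yr |
| μ₂ | malignant transformation | 2e-3 | with μ₀ fixes the BE→OAC lag scale |
| α_M, β_M | malignant birth/death | 3.0 / 2.5 | fast-growing preclinical cancer |
| ρ | detection per malignant cell | 0.1 /yr | preclinical sojourn of a few years |
| nu0 (M/F) | baseline BE conversion /yr | 2.6e-4 / 6.5e-5 | male:female 4:1; BE prevalence 1–2% at 60 |
| m_cohort | cohort multiplier on nu0 | 0.6/0.8/1.0 for 1930/40/50 | rising cohort trend |
| RR | GERD relative risk for BE | 5 (sweeps 2–6) | conventional screening assumption |
| p_GERD(t) | GERD prevalence | logistic, p_max 0.25, k 0.15, t0 40 | plausible adult reflux prevalence |
| segment | Beta(2,6) on [0,10] cm, 100 cells/cm | | mean length 2.5 cm |

The demo configuration is a *synthetic ground truth*, chosen once so that
its outputs echo the order of magnitude of US OAC epidemiology (male
lifetime risk ~1%, cancer-free BE prevalence 1.45–2.1% across ages 50–70
in men, ~0.4% in women, GERD-male prevalence ~5–6%, progression
0.7–1%/yr). It is deliberately not a registry calibration; registry-scale
clonal parameters (division rates ~10/yr, μ₂ ~1e-5) would describe the
same hazards but make exact event-driven simulation of 10⁵ individuals
needlessly expensive, so the demo trades cell-level rate realism for a
tractable oracle while keeping the population-level epidemiology in
range.

## Numerical choices

* Backward ODEs: adaptive LSODA, rtol 1e-8, atol 1e-10; survival values
  clipped to [0,1] and rejected if they leave it by more than 1e-6. The
  Armitage–Doll check tightens tolerances (rtol 1e-12, atol 1e-20)
  because the deficits being measured are ~1e-13.
* Length marginalisation: 16-node Gauss–Legendre over the Beta law with
  weights renormalised to sum to 1 (observed agreement with a 10⁶-sample
  Monte Carlo to ~1e-5, and node-count insensitivity to machine
  precision).
* Outer age mixing: trapezoid-rule convolution on a uniform 0.1-year grid
  to age 100; halving the step to 0.01 changes cumulative incidence by
  <1e-4 relative. `S_pop` has an underflow floor of 1e-12 (error, not
  clamp).
* Age conventions: continuous years, age 0-based; census single-age rows
  [a, a+1) are evaluated at the midpoint a+0.5; incidence age bins use the
  midpoint rule (switchable in principle to bin averages — with 5-year
  bins the difference is far below sampling noise).
* Calibration: Nelder–Mead in log-parameter space (positivity for free),
  soft quadratic penalty outside configured bounds, multi-start (default
  5: the current configuration values plus seeded log-uniform draws),
  loglik tolerance 1e-8; estimates landing on a bound are flagged.
* Uncertainty: observed information by central finite differences
  (relative step 1e-4) on the natural scale; 1000 multivariate-normal
  draws truncated to bounds; nonparametric bootstrap over table rows as
  the logged fallback for a singular information matrix. Intervals are
  2.5/97.5 percentiles.
* Simulator: aggregated per-compartment propensities with exponential
  waiting times; per-individual substreams derived from
  `SeedSequence((master_seed, index))`, so histories are independent of
  simulation order; event-count safety cap 1e7 per individual (an error,
  never silent truncation). When any of ρ, μ₀, μ₁, μ₂ is exactly zero,
  detection is unreachable and the post-onset loop is skipped — this is
  exact, and avoids simulating unbounded undetectable clones.

## Design decisions that were genuinely open

* **Free parameters in calibration.** Only rate combinations are
  identifiable from incidence alone, so growth and detection rates
  (α, β, ρ, cells/cm) stay fixed at configured values and the default
  free set is {nu0 per sex, μ₂, cohort multipliers}; μ₀ (=μ₁ tied) can be
  freed, but μ₀ and μ₂ lie on a near-ridge (leading-order hazard depends
  on μ₀²μ₂) and freeing both mainly inflates their joint uncertainty.
* **GERD timing.** The GERD subgroup applies RR at all ages (the upper
  band of the subgroup-prevalence sweep); individual-level heterogeneity
  by reflux-onset age would lie inside the RR 2–6 band that
  `sweep_scenarios` reports. In the simulator, a GERD onset age is drawn
  from the increments of p_GERD(t) for the history record, while the
  population-subgroup BE onset uses the exact mixture hazard; the
  (second-order) selection effect of carriers acquiring GERD is therefore
  attributed consistently with the analytic model.
* **Attribution cap.** When the model predicts more cases than observed,
  the attributable fraction is capped at 1 and the surplus reported as
  `excess` — a >100% "attribution" has no epidemiological meaning.
* **Cohort lookup in projection.** Census cohorts outside the fitted
  decade range clamp to the nearest fitted cohort (logged); the
  alternative, extrapolating multipliers, would invent trend.
* **BE carrier counts** use the cancer-free conditional prevalence
  p_be_cf (not the unconditional `1 − e^{−Λ}`), since a census population
  is by construction alive and overwhelmingly cancer-free.

## What the synthetic data do and do not emulate

The generators reproduce the *shape* of the study inputs: Poisson case
counts given person-years and model rates in 5-year bins for ages 40–89
(each table row carrying its own person-years at registry scale),
a plateau-then-decline age pyramid summing to a chosen total, logistic
GERD prevalence curves, and Bernoulli screening yields by age/sex/GERD
cell. They do not emulate demographic realism (migration, race strata,
period effects), registry reporting artefacts (delay, miscoding),
endoscopy referral selection, or record-level screening schemas. Passing
tests therefore demonstrate that the pipeline is *internally correct and
statistically calibrated* — estimator consistency, interval coverage,
test size, oracle agreement — not that the demo parameters describe any
real population.

## Known limitations

* No competing mortality: hazards are conditional on being alive, and
  projections inherit whatever demography the census table encodes.
* Single-conversion BE onset cannot represent multifocal segments.
* The likelihood treats bins as independent Poisson counts; registry
  overdispersion (period effects, reporting) would need a quasi-likelihood
  extension.
* Wald-type draws for intervals rely on a locally quadratic likelihood;
  near-boundary fits fall back to the bootstrap but remain approximate.
* Exact event-driven simulation becomes expensive for strongly
  supercritical clones with small μ₂/ρ; the event cap makes this an
  explicit error rather than a bias.
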