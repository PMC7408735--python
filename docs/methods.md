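# Methods

## Model

Disease natural history is a progressive three-state Markov chain:
disease-free → pre-clinical detectable phase (PCDP) → clinical phase
(CP), with time-homogeneous exponential intensities λ₁ (pre-clinical
incidence, per person-year) and λ₂ (progression, per year). The mean
sojourn time is MST = 1/λ₂ and the cumulative risk of surfacing within
t years of PCDP entry is 1 − e^(−λ₂t); the median time to CP is
ln 2 / λ₂. Each feature stratum — stellate, circular, powdery/crushed
stone-like (all < 15 mm) and a single ≥ 15 mm size stratum — carries its
own triple (λ₁, λ₂, S), where S is the per-screen detection probability
while in PCDP. Casting calcifications and architectural distortion
(ductal-type appearances) are recognised on input but excluded from
every fit.

Assumptions worth stating explicitly:

* **Exponential sojourns, age-free rates.** Rates are constants within a
  calendar period; age enters only the screening-schedule rules of the
  synthetic designs. Time is continuous, in years, from each woman's
  disease-free entry.
* **Independent feature processes.** The likelihood factorises over
  features: a woman with a cancer of feature f contributes f's event
  term and every other fitted feature's no-event term. Per-feature λ₁ is
  of order 10⁻³/yr or less, so synchronous cancers of two features are
  negligible; mixed-appearance tumours are out of scope.
* **Disease-free entry with a lead-in.** Women are disease-free at entry
  and the first screen occurs after a configurable lead-in (default 2 y),
  which builds the prevalence pool the first round harvests. The
  steady-state alternative (initialising the first-screen pool at λ₁/λ₂)
  is available in the renewal I/E machinery; the cohort likelihood uses
  the disease-free convention throughout.
* **Attendance is missing-at-random**: unattended invitations simply do
  not appear in a woman's screen list.

## Likelihood

With screens attended at 0 < t₁ < … < t_k and the kernel

A(a, b; T) = ∫ₐᵇ λ₁e^(−λ₁u) e^(−λ₂(T−u)) du
  = λ₁/(λ₂−λ₁) · [e^(λ₂(b−T)−λ₁b) − e^(λ₂(a−T)−λ₁a)],

(the probability of entering PCDP in (a, b] and remaining pre-clinical
at T; l'Hôpital form λ₁e^(−λ₁T)(b−a) when |λ₂−λ₁| < 10⁻⁹, the switch
point chosen to avoid catastrophic cancellation), the four detection
modes have the closed forms given in `sojourn/likelihood.py`: a
screen-detected case at round j sums PCDP-entry windows weighted by
(1−S) per intervening miss and S for the detecting screen; an interval
cancer's density is λ₂ times the sum of a false-negative component
(missed at ≥ 1 screen) and a newly-arising component (onset after the
last screen) — the two-component decomposition of interval cancers;
censoring collects the disease-free and undetected-PCDP mass. These
masses sum to one over the outcome space for any schedule; the test
suite verifies this to 10⁻⁸ by adaptive quadrature, and each kernel to
10⁻¹⁰ against brute-force integration.

The overflow-safe kernel form above keeps every exponent non-positive
for T ≥ b, so no rescaling is needed anywhere in the parameter ranges
the fitter explores.

For fitting, identical histories are grouped and all kernel terms laid
out in flat arrays (`CompiledCohort`), making one cohort log-likelihood
evaluation a few vectorised operations; equality with the naive
per-record sum is tested to 10⁻¹⁰.

## Estimation

Parameters are transformed to (log λ₁, log λ₂, logit S) per feature.

* **MLE**: L-BFGS-B on the per-record-scaled negative log-likelihood
  (scaling makes convergence tolerances independent of cohort size);
  95% intervals are Wald intervals from a central-finite-difference
  observed information on the transformed scale, mapped through
  exp/expit. MST intervals are the reciprocal λ₂ interval, endpoints
  swapped. A sensitivity whose transformed-scale standard error exceeds
  5 (or whose information is non-positive) is flagged as weakly
  identified — S and λ₂ are only weakly jointly identified from the
  screen-detected/interval split, a known property of this model class.
* **MCMC**: component-wise random-walk Metropolis. Priors default to
  Normal(0, 10) on both log-rates and Beta(1, 1) on S (the sampler works
  in logit S and carries the Jacobian); all are configurable and echoed
  into the results provenance. Proposal scales adapt every 100
  iterations toward 30% acceptance during burn-in only and are frozen
  afterwards, preserving detailed balance. Defaults are 4 chains ×
  20,000 iterations, 5,000 burn-in, thinning 5; an explicit seed is
  required and draws are bit-reproducible given it. Point estimates are
  posterior medians; intervals are percentile intervals. Effective
  sample size uses the initial-positive-sequence autocovariance
  estimator.

"Sensitivity-adjusted MST" means 1/λ₂ from the *joint* (λ₂, S) fit.
Fixing S = 1 attributes missed cancers to fast progression and biases
MST downward; the package exposes the comparison via
`fix_sensitivity={feature: 1.0}`. The effect is material only when
sensitivity is genuinely imperfect: at S = 0.95 the induced bias (~5% of
MST) is below sampling noise at cohort sizes of order 10⁴–10⁵, which is
why the demonstration experiment in the test suite runs at S = 0.7.

## Interval-cancer (I/E) engine

The performance metric is proportional interval-cancer incidence:
interval cancers as a fraction of the expected background incidence
without screening. Under steady-state repeated screening every Δ years,
condition on a tumour entering PCDP; by stationarity its onset is
uniform on a cycle of length Δ, so the first screen occurs Δ−U after
onset (U ~ Uniform(0, Δ)) and the m-th at mΔ−U. With per-screen
detection Bernoulli(S), the first successful screen index M is
geometric(S), independent of the sojourn X ~ Exp(λ). The tumour becomes
an interval cancer iff it surfaces first, X < MΔ − U, and every tumour
would surface absent screening, so

I/E = P(X < MΔ − U) = 1 − E[e^(−λ(MΔ−U))]
    = 1 − E[a^M]·E[e^(λU)]  (a = e^(−λΔ))
    = 1 − [Sa/(1−(1−S)a)] · [(e^(λΔ)−1)/(λΔ)]
    = 1 − S(1−a) / [λΔ(1−(1−S)a)].

At S = 1 this is 1 − (1−a)/(λΔ); at S = 0 it is exactly 1. The same
construction, simulated directly (`simulate_renewal_ie`), is the
independent oracle. A woman-level multi-arm randomised-design simulator
(`simulate_rct`) provides the finite-horizon, imperfect-attendance
counterpart, with empirical I/E defined as interval cancers per
person-year over clinical cancers per person-year in the unscreened arm.

Two estimators exist because the generative procedure behind the
published sub-unit-sensitivity grid cells is not fully pinned down by
the printed inputs; only the perfect-sensitivity block is arithmetically
determined by the printed MSTs, and only that block is treated as an
equality target. Display rounding is half-away-from-zero to integer
percent; unrounded values are always retained.

`policy_threshold_search` inverts the closed form by bisection: for each
interval it returns the minimal S for which every supplied feature meets
a stated I/E ceiling (the fastest-progressing feature — circular — always
binds).

## Synthetic cohorts

The generator draws competing feature-specific onsets (exponential,
earliest wins), an exponential sojourn, a schedule (trial preset:
24-month interval under age 50, 33 months at 50+, entry ages uniform
40–74, half uninvited; service preset: fixed interval, default
biennial), Bernoulli attendance per invitation and Bernoulli(S)
detection per attended in-phase screen, then classifies the outcome.
Latent onset/sojourn values go to a separate truth table, never into the
cohort file. Generated detection-mode frequencies match the likelihood's
masses within binomial error — the generator and the likelihood describe
the same process — and unscreened sojourns pass a Kolmogorov–Smirnov
test against Exp(MST).

Default rates (per 100,000 woman-years, chosen once to respect the
documented constraints on the two study periods — small-tumour incidence
rising ~26% between periods, large-tumour incidence falling ~44%, the
calcification-type share roughly doubling, period-2 sensitivities
≥ 0.95, longer period-1 MSTs with lower stellate sensitivity):

| stratum | period 1 λ₁ | period 1 MST / S | period 2 λ₁ | period 2 MST / S |
|---|---|---|---|---|
| stellate | 75 | 4.50 / 0.75 | 78 | 3.76 / 0.95 |
| circular | 57 | 3.30 / 0.85 | 66 | 2.65 / 0.95 |
| powdery/crushed-stone | 18 | 4.30 / 0.85 | 46 | 4.26 / 0.95 |
| ≥ 15 mm | 100 | 1.80 / 0.65 | 56 | 1.50 / 0.95 |

Period-2 MSTs and sensitivities are published values; everything else is
a package choice (the period-1 rate/sensitivity figures appear only in
an unprinted figure of the source study) and is overridable per
scenario. What passing tests show is therefore *internal* consistency —
the estimators recover the generator's parameters and the policy engine
matches its own closed form — not agreement with the original registry
data, which is not public. Real screening data add features the
generator deliberately omits: age-dependent rates, non-progressive
(overdiagnosed) lesions, misclassified detection modes, correlated
attendance, and calendar-time drift in sensitivity.

## Experiment sizes and numerical choices

* Transition probabilities are validated against a Kolmogorov-forward
  ODE oracle (50 random (λ₁, λ₂, t) points, 10⁻⁸) and the degenerate
  λ₁ = λ₂ branch against the limit of the general branch.
* Parameter recovery: 10 replicate cohorts of 100,000 women at the
  period-2 values under biennial screening; mean MST within 15% and mean
  λ₂ bias under 10% per feature.
* MCMC calibration: 50 single-feature replicates of 20,000 women; 90%
  percentile intervals cover the true (λ₂, S) in ≥ 80% of replicates.
  Chains for this experiment are 7,000 iterations (2,000 burn-in,
  thinning 2, one chain): shorter chains visibly under-cover λ₂ because
  autocorrelated tails narrow the percentile intervals.
* The renewal simulation uses 2 × 10⁶ tumours per cell where it is an
  equality check (Monte-Carlo SE ≈ 0.03 pp) and 10⁶ for grid-wide
  agreement at 1.5 pp.
* Ties/degenerates: Δ ≤ 0 rejected; S = 0 returns I/E = 1 exactly;
  screens exactly at the censoring time contribute a zero-width
  newly-arising window; a feature with zero observed cancers is fitted
  with λ₁ at the boundary and flagged, not silently dropped.

## Known limitations

Non-exponential sojourns, age-dependent rates, tumour-size growth
models, overdiagnosis, survival/lead-time analysis and covariates beyond
the feature/size strata are out of scope. The likelihood assumes exact
surfacing dates for interval cancers (matching date-of-diagnosis data
collection); interval-censored variants are not implemented. The
published median-time and five-year-risk figures for the early period
are mutually inconsistent under any single exponential rate; the package
implements the exponential forms and makes no attempt to match both.
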