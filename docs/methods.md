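# Methods

## Problem and model

In a clinical trial, the risk of an adverse event (AE) of a given type is
naturally a cumulative probability in a time-to-first-event analysis: the
probability that a patient experiences the AE by an evaluation time τ.
Observation of that time is complicated by two distinct mechanisms:

* **Censoring** — follow-up ends without any event (e.g. trial closure),
  so only a minimum event-free time is known.
* **Competing events (CEs)** — events that preclude later observation of
  the AE: death before the AE, and disease- or safety-related end of AE
  recording such as treatment discontinuation.

The package implements six one-sample estimators of the cumulative AE
probability and the machinery to compare them. With n patients, t_i the
follow-up time of patient i truncated at τ, and counting events on the
closed window [0, τ]:

* **Incidence proportion (IP)** — #AE / n. Handles CEs correctly (a
  patient with a CE correctly contributes a full denominator) but treats
  censored patients as fully observed, biasing downward under censoring.
* **Probability transform of the incidence density, ignoring CEs** —
  1 − exp(−ID·τ) with ID = #AE / Σ min(t_i, τ). A constant-AE-hazard
  model that lets the AE probability approach 1, ignoring that CEs cap
  it; biased upward, often severely.
* **One minus Kaplan-Meier (1-KM)** — product-limit with the AE as the
  sole event type and everything else censored. Valid under censoring
  but treats CEs as censoring, again converging to the "net" risk
  1 − exp(−∫α) rather than the cumulative incidence; biased upward.
* **Probability transform accounting for CEs** — with AE density a and
  CE density b, a/(a+b) · (1 − exp(−τ(a+b))). The constant-hazard
  analogue of the cumulative incidence function; 0 when a = b = 0, and
  algebraically equal to the one-density transform when b = 0.
* **Aalen-Johansen (AJE), death-only scheme** — the nonparametric
  cumulative incidence estimator, but treating only death as competing
  (other CEs recoded to censoring).
* **AJE, all-CE scheme** — the gold standard: accounts for censoring,
  makes no hazard-shape assumption, and handles the full CE definition.
  It equals 1-KM when no CEs exist and equals IP when no censoring
  exists; together with the CE cumulative incidence it decomposes one
  minus the all-event Kaplan-Meier.

Sample-path orderings follow from mass redistribution and hold for every
dataset, not just asymptotically: 1-KM ≥ AJE(all-CE) ≥ IP, and
AJE(death-only) ≥ AJE(all-CE). The test suite asserts them on hundreds of
randomly generated datasets including heavy ties.

## Numerical conventions

* Events at time exactly τ count as observed (closed window), and an
  event tied with a censoring time is an event; at tied times events are
  processed before censorings, i.e. records censored at t_j stay in the
  risk set Y_j. Tied AEs and CEs share the same risk set.
* Evaluation times: the maximum observed time, or a nearest-rank
  (ceiling) empirical quantile of observed times (100/90/60/30%); with
  several arms, the minimum of the per-arm quantiles. Nearest-rank was
  chosen because it is deterministic, exact on small samples, and free
  of interpolation choices.
* Step curves are right-continuous; estimates at τ read the curve at the
  largest jump ≤ τ.
* Internal time unit is days; the meta-regression covariate "evaluation
  time" uses 365.25 days/year.
* Zero estimates are legal. A comparator/gold ratio with a zero
  numerator or denominator is flagged undefined, excluded from pooling,
  and counted — never imputed, and log(0) is never taken.

## Ratio comparison and bootstrap

Each comparator is divided by the gold-standard AJE on the same unit
(one (trial, AE-type) pair) and carried on the log scale. The standard
error of the log-ratio comes from a patient-level bootstrap (default
B = 1000): patients are resampled with replacement, the evaluation time
is re-derived under the active rule on each replicate (keeping the
estimand consistent under resampling), and both estimators are
recomputed. Degenerate replicates (zero numerator or denominator) are
dropped and counted. The SE is the sample SD of the valid replicate
log-ratios; the reported interval is the 2.5/97.5 percentile interval of
the replicate ratios. Percentile intervals were chosen over normal
approximations because ratio distributions on small units are markedly
skewed.

The composite-endpoint analysis recodes AE and all CEs as one event
type, a single-endpoint survival setting where one minus Kaplan-Meier is
the valid reference; IP/(1-KM) on the composite then isolates the effect
of censoring alone and is ≤ 1 on every dataset.

## Meta-analysis

Log-ratios y_i with bootstrap SEs se_i are pooled with the normal-normal
hierarchical model y_i ~ N(μ + x_iᵀβ, se_i² + τ²); exp(μ̂) is the average
ratio of the two estimators. τ² is estimated by REML (profiled restricted
likelihood, bounded scalar optimisation with an explicit check of the
τ² = 0 boundary); a generalised DerSimonian-Laird moment estimator and a
pure fixed-effect fit are available for sensitivity analyses, and the
Knapp-Hartung small-sample adjustment is optional. CIs are Wald on the
log scale by default. The REML and DL paths are verified in the tests
against metafor (R) and statsmodels on a frozen fixture.

Meta-regression covariates (censoring %, CE %, gold-standard AE
probability, evaluation time in years) are centered at their sample
means, so the exponentiated intercept is the average ratio at covariate
means; slopes are reported as multiplicative changes per conventional
increment (10 percentage points, 0.1 probability, 1 year). The default
multivariable model excludes CE % because it is strongly collinear with
censoring % and the AE probability (the three observed-state fractions
sum to one with the AE fraction).

## Synthetic data generator

Real per-patient safety data of this kind are proprietary, so the
generator stands in for a trial portfolio with known truth. Each patient
gets independent latent AE and CE times (exponential or Weibull — for
independent latent times the observed (min, cause) pair has exactly the
specified cause-specific hazards), the CE is split into death vs other
CE (default fraction 0.25/0.75, reflecting that treatment
discontinuation-type CEs dominate deaths in practice), and censoring is
the minimum of an administrative time and an optional independent
exponential drop-out time. Under constant hazards the true AE cumulative
incidence has the closed form α/(α+β)(1 − e^{−(α+β)τ}), the analytic
oracle for all consistency tests.

Portfolio defaults emulate an oncology-heavy collection of completed
trials: per-trial sizes drawn log-uniformly from 200–7000, administrative
censoring at 1000 days, baseline hazards α = 2.5·10⁻⁴/day and
β = 9·10⁻⁴/day (≈ 15% observed AEs, ≈ 53% CEs, ≈ 32% censored at
closure), 8 AE types per trial, between-trial log-hazard SD 0.3 and
between-AE-type log-AE-hazard SD 0.5. These calibrations match aggregate
descriptives of such portfolios approximately, not any specific trial.
Randomness flows through a seed hierarchy (portfolio → trial → unit) so
any unit is reproducible from the portfolio seed.

What the generator does **not** emulate: dependent censoring,
informative correlation between CE and censoring processes, staggered
accrual with calendar-time cutoffs, recurrent AEs, or within-patient
correlation across AE types (units are simulated independently, whereas
real AE types within a trial share patients). Passing tests therefore
demonstrate correctness of the estimators and the direction and
mechanism of their biases, not the magnitude of bias in any particular
real portfolio.

## Problem sizes used in tests and the acceptance script

Property suites run on hundreds of small random datasets (n ≤ 12, with
forced ties); brute-force oracle comparisons on n ≤ 8 at 10⁻¹² tolerance;
consistency checks at n = 10⁴ (tolerance 0.015 on the cumulative
incidence scale) and n = 10⁵ for event-frequency goodness of fit; the
bootstrap calibration check compares the mean bootstrap SE over 25
simulated units (n = 200, B = 200) to the empirical SD over 400
independent simulations, because the bootstrap SE of a single small unit
has sampling variability of the same order as the 15% tolerance. The
acceptance script's portfolio uses 10 trials × 6 AE types with B = 200
bootstrap replicates.

## Known limitations

* Variances/CIs for single estimators are not provided outside the
  bootstrap ratio machinery.
* No left truncation, stratification, or covariate adjustment.
* The meta-regression treats units from the same trial as independent
  given the covariates; a three-level model (units within trials) is not
  implemented.
* The Weibull family is simulated but the analytic truth table is only
  emitted for constant hazards (Weibull truth requires numerical
  integration, which tests do on the fly where needed).
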