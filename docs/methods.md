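# Methods

## Model structure and assumptions

The model is an individual-level state-transition microsimulation with two
health states, "no caries" and "caries", cycled annually. Every individual
starts caries-free; in each yearly cycle a new lesion occurs with the
stratum's annual incidence probability, is diagnosed at the next dental
visit, and receives a 1-surface restoration that returns the individual to
the no-caries state within the cycle. Consequences of this construction:

- at most one lesion per person-year (multiple same-year lesions and
  surface-level bookkeeping are not modelled);
- person-year outcomes are independent Bernoulli trials, so the yearly
  lesion count in a cohort of *n* is Binomial(*n*, *p*) and the closed-form
  expectation *n*·*T*·*p* (`cohort_expectation`) is an exact oracle for the
  stochastic engine — the suite checks the engine against it to 3 standard
  errors over 30 seeds;
- strata are closed cohorts: no mortality, migration, or ageing across
  bands over the 10-year horizon.

The intervention scenario differs only in its incidence. Sugar intake is
reduced by a constant fraction (no heterogeneity by stratum, constant over
the horizon) and mapped to incidence by a linear absolute-risk dose-response
clamped to [0, baseline]. A relative-risk form (`dose_response: relative`)
is available as a robustness switch. Baseline incidence is taken to already
correspond to baseline intake; only the labeling scenario is adjusted.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| horizon | 10 | years | standard in sugar-policy evaluations |
| n_individuals | 500,000 | persons/stratum | published design |
| effect_fraction | 0.066 (0.044–0.088) | fraction of intake | meta-analytic labeling effect on intake, with CI bounds for the one-way analysis |
| sugar_caries_slope | 0.002 | probability per g/day | calibrated stand-in for the longitudinal dose-response (not publicly tabulated); order of magnitude consistent with the published population totals |
| unit_cost | €74.10 | € per restoration | statutory 1-surface fee; presets `copayment` €118.11 and `restoration_failure` €148.73 are derived from published scenario totals ÷ total lesions |
| discount_rate | 0.03 | per year | guideline rate for costs and benefits; convention (1+r)^−(y−1), year 1 undiscounted |
| per-lesion DALY | 2.8583·10⁻⁴ | DALY/lesion | implied by 677.62 DALYs / 2,370,715 lesions; factored as disability weight 0.010 (GBD symptomatic-caries convention) × duration 0.1 y × proportion symptomatic ≈ 0.2858, each independently configurable |
| gdp_per_capita | €40,332 | €/DALY | implied by €27.33M / 677.62 DALYs (2017 German GDP per capita; CMH valuation) |
| implementation_cost_range | €5.29–9.56M | € | pass-through reporting constant; the estimation method behind it is not reproduced |

The per-lesion DALY and €/DALY defaults are calibrated stand-ins derived
from published totals, not the original appendix inputs, which are not
publicly tabulated. They reproduce the published DALY/productivity ratios
exactly (455.15 DALYs at the 4.4% bound; €36.24M from 898.55 DALYs).

## Synthetic inputs

The generator emulates the *structure* of the German inputs, not their
values: 12 strata; male sugar intake above female within each band
(`male_excess` 1.15); intake highest in the youngest band, declining with
age through 51–64 and rising slightly for 65–80 so that women 51–64 are the
strict minimum — the reported German pattern (highest: boys 15–18, lowest:
women 51–64), which a strictly monotone gradient cannot produce. Intakes are
anchored to a uniformly drawn youngest-band value and interpolated toward
the range floor by the gradient, which keeps every value inside
`sugar_range` for any valid spec. Incidences are drawn independently per
stratum within `incidence_range` (0.15–0.35/year); populations are uniform
within ±20% of 10⁶ persons per stratum (the order of magnitude of German
age bands — population-scaled outputs are linear in this choice).

What passing tests therefore show: the machinery (engine calibration,
valuation identities, monotonicity, additivity, discounting, PSA quadrant
behaviour) is correct on inputs with the right structure and plausible
magnitudes. What they do not show: agreement of absolute population totals
with the published German figures, which depend on the confidential survey
intakes, GBD incidences, and census populations. The published totals are
instead checked as arithmetic identities (`verify_paper_identities`): every
printed cost must equal printed lesions × €74.10, which holds for 10 of 12
stratum rows, the total, and both one-way bounds; the two violating rows
(women 51–64: €14.17M recomputed vs €16.95M printed; women 65–80: €9.82M vs
€13.16M) are treated as suspect and excluded from any matching.

## Numerical and design choices

- **Randomness.** One substream per (seed, stream key) via
  `numpy.random.SeedSequence` spawn keys; every (stratum, scenario, PSA run)
  is independent and bit-reproducible. Scenario pairs use common random
  numbers by default (the same uniforms thresholded against both
  incidences), so incremental counts are non-negative year by year and the
  one-way analysis is exactly monotone in the effect; a config switch
  disables CRN.
- **Discounting and the headline convention.** The published per-stratum
  costs equal printed lesions × €74.10 exactly, which is only possible if
  lesions and costs share the same (or no) discounting; the reporting layer
  therefore defaults to undiscounted headline lesions/costs — preserving
  that identity to machine precision by computing undiscounted costs from
  the scaled lesion count — and carries the 3%-discounted variants
  alongside (CLI `--discount`). No half-cycle correction; events are
  valued at integer year ends.
- **PSA.** Parameters (per-stratum incidence, effect, slope, unit cost) are
  drawn from independent normals, sd = 20% of the mean for all four — the
  stated convention for the unit cost, extended to the others for lack of
  reported sds; each is overridable. Truncation to valid domains
  (probabilities to [0,1], costs/slope non-negative) is by rejection with a
  bound-clamp fallback after 100 tries; at sd = 20% an out-of-domain draw is
  a ~5σ event, so the fallback is effectively never exercised. Correlations
  among parameters are not modelled (none are reported). Simulation streams
  are fixed across PSA runs, so the plane scatter isolates parameter
  uncertainty and a zero-sd spec reproduces the base case bit-identically;
  Monte Carlo noise is controlled separately by the per-run cohort size.
  The PSA covers the two extreme-consumption strata as published
  (`all_strata` extends it). Plane ties go to the favourable side: zero
  incremental cost counts as cost-saving, zero effect as effective.
- **Problem sizes.** The analysis scripts use the published per-stratum
  cohort of 500,000; the PSA driver, the acceptance script, and the test
  suite use a scaled-down design (200 runs × 20,000 individuals, and
  5,000-person cohorts in unit tests). Outcome expectations are linear in
  cohort size, so scaling changes Monte Carlo noise, not means; the 100%
  bottom-right-quadrant result is stable across seeds at the scaled-down
  size because the incremental effect is ~5σ from zero under every drawn
  parameter set.
- **Degenerate inputs.** Zero effect, zero slope, or zero disability weight
  are legal and propagate to exactly-zero outcomes; incidence 0/1 produce
  deterministic trajectories; equal incidences under CRN give identical
  scenarios.

## Limitations

Only 1-surface restorations are costed (no copayments, failures, or complex
treatment cascades in the base case — alternate unit-cost presets
approximate the published scenario totals); long-term sequelae such as tooth
loss are excluded from DALYs, so burden is likely underestimated; labeling
implementation costs are reported as a pass-through constant, not modelled;
industry reformulation, price responses, and SES-differential responses are
out of scope. Synthetic inputs mean absolute totals are illustrative, not
German estimates.
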