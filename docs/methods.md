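# Methods

## Model structure

Progression of chronic kidney disease secondary to type 2 diabetes is
modelled as a discrete-time Markov chain over five albuminuria-defined
states: normoalbuminuria (A), microalbuminuria (B), macroalbuminuria (C),
end-stage renal disease on renal replacement (D) and cardiovascular death
(E). One cycle is one calendar year. Only seven moves are possible — the
stepwise nephropathy sequence A→B→C→D and a death transition from each
living state — so a patient cannot skip a stage within a year, and death
is the single absorbing state. There is no background (non-cardiovascular)
mortality, no age- or sex-specific rates, and no regression to less severe
stages; these are structural assumptions inherited from the source
transition estimates, not simplifications added here.

The seven annual transition probabilities are consumed directly as
one-cycle probabilities (no hazard/rate conversion): the UKPDS estimates
are themselves annual probabilities, and the published intervals are narrow
enough that each row's outgoing sum stays well below one. Competing risks
within a cycle are therefore resolved by direct row construction — the
diagonal is one minus the row's outgoing sum — and a load-time guard
rejects any parameter set whose upper bounds sum to ≥ 1 for some row.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| transition bounds | shipped CSV (7 pairs) | fraction/yr | UKPDS 95% CI per move |
| rate policy (controlled / uncontrolled) | min / max | — | bound selection per stratum |
| control fraction | 0.187 | fraction | share with HbA1c < 7 in 2016 |
| age-band profiles | shipped CSV (6 bands, 20–79) | — | prevalence, weight mass, duration median + IQR |
| cohort sizes 2016–2032 | shipped CSV | persons | accumulated diabetic cohort without social security |
| horizon | 16 years from 2016 | years | projection window |
| error bound | 10,000 | persons | microsimulation sample-size rule |
| seed | 20160101 | — | any sampling step |

The uncontrolled majority progresses at the upper bounds to reflect the
quality-of-care argument that an uncontrolled population tracks the worst
published trajectory; controlled patients take the lower bounds — the only
other stated bound — making the control split a bracketing device rather
than a treatment-effect estimate. A `midpoint` policy is available for
sensitivity analysis.

## Initialization of the prevalent cohort

Patients prevalent at baseline are already part-way through their disease.
Each age band contributes in proportion to its survey-weight mass; within
a band, years since diagnosis follow a fitted duration law, and a patient
diagnosed *d* years ago is represented by a pure-normoalbuminuria vector
advanced ⌊d⌋ annual cycles (a patient "5 years since diagnosis" has
completed five cycles). The expected baseline mix integrates this over the
duration law via P(⌊d⌋ = k) weights, truncated at 120 years.

Two baseline conventions are implemented. The default, `carry_deaths`,
keeps the death mass accumulated during the pre-baseline burn-in as part of
the baseline cohort, so the baseline year already shows a substantial
cumulative-death share and the cohort denominator equals all cases ever
accrued. The alternative, `condition_on_survival`, renormalises the
baseline mix over living states — appropriate when the prevalent cohort is
defined by surviving survey respondents. The carry-forward convention is
the default because the projection's natural bookkeeping (state counts
summing to the accumulated cohort, deaths included in the published-style
denominators) requires it; conditioning is kept for scenario analysis.

Incident cases enter at normoalbuminuria on January 1 of their incidence
year and take their first transition at the end of that year. Cohort
accrual follows prevalence-plus-cumulative-incidence: the at-risk
population each year is the total adult population minus the *baseline*
prevalent count (a fixed subtraction), new cases are the incidence rate
times the at-risk population, and how incident cases distribute across age
bands is irrelevant to progression because entry is always at
normoalbuminuria under band-independent rates.

## Duration laws

With only a median and interquartile range per band available, the fitted
family is a two-parameter gamma: positive support and right skew match the
band summaries, and two parameters are exactly identified by two
constraints. The scale is solved analytically so the fitted median is
exact; a bounded 1-D search over log-shape matches the IQR *width* in
least squares. The achieved quantiles are reported back on the fitted
object. Note the endpoints themselves cannot always be reproduced — some
band summaries are left-skewed around the median, which no gamma is — so
the width, not the endpoints, is the fitting target. A zero-width IQR
degenerates to a point mass (with a warning).

When record-level durations exist (synthetic surveys), a weighted Gaussian
KDE is used instead: Silverman's rule on the weighted sample (effective
sample size (Σw)²/Σw²), a bandwidth floor of 0.1 years against tied
samples, and reflection at zero so no mass lies below zero duration. The
kernel, bandwidth rule and weighting are declared choices, not estimates
from any source.

## Microsimulation and validation

The default engine propagates expectations analytically (deterministic,
exact to float precision). The microsimulation assigns each simulated
individual a stratum, entry year and initial state, then draws categorical
transitions year by year (one uniform per individual per year, in
individual order, so fixed seeds are portable). The sample size follows
the binomial rule: the smallest n with cohort × √(p(1−p)/n) below the
error bound at worst-case p = 0.5, rounded up to the next 10,000 — for the
baseline cohort of 5,449,204 and a 10,000-person bound, n = 80,000.
Bootstrap resampling of individuals yields per-year means, variances and
the 2.5/25/50/75/97.5 percentiles; because deaths are retained, per-year
marginal bootstrap counts are multinomial draws on the year's empirical
occupancy, which is how they are generated. The test suite cross-validates
simulation against analytic expectation (the model's own validation
design), recovers matrix entries from simulated one-step frequencies, and
checks the geometric-sojourn closed form 1/p for ESRD.

## Synthetic data

The synthetic survey emulates the *statistical structure* the pipeline
assumes — band-wise prevalence, band-wise duration laws, positive weights
with band totals proportional to the configured masses, a social-security
flag — with ages uniform within bands (only band membership matters
downstream) and durations capped at age − 18 (adult-onset assumption). It
does not emulate complex survey design (strata, PSUs, clustering), item
nonresponse, or diagnosis-age cohort effects, so passing tests demonstrate
pipeline correctness under the assumed structure, not robustness to real
survey artefacts. The population projection is geometric (default
calibrated to 22% total growth over 16 years) and the incidence schedule
constant, with a root-finding helper that calibrates the constant rate to
reproduce a target accumulated-cohort trajectory (it matches the shipped
cohort row within ~1% at every year).

## Numerical choices

Probabilities are stored as fractions (files carry percents, converted once
at load). Row-stochasticity is enforced to 1e-12; probability vectors to
1e-9; projection state counts must sum to the cohort size within 0.5% and
cumulative deaths must be non-decreasing. Counts are rounded to whole
persons and shares to 0.01% only at write time. Floor-weights use left
limits of the CDF so a point mass at an integer duration counts the full
number of completed cycles. Degenerate inputs (zero-width IQR, zero-rate
tables, frozen chains) are handled explicitly and tested.

## Known limitations

* Single-death-state structure: no non-cardiovascular mortality, so death
  counts are "deaths associated with cardiovascular risk", not all-cause.
* Band-independent rates: age enters only through the duration law at
  initialization; no sex stratification.
* Normoalbuminuric diabetic kidney disease (progressive renal decline
  without albuminuria) is outside the state structure, as is regression
  from microalbuminuria.
* The baseline state mix is only as good as the duration summaries and the
  carry-forward convention; published baseline stocks for rare states
  (ESRD) are sensitive to initialization details that summaries cannot
  pin down, and the ESRD trajectory implied by the shipped transition
  bounds (fast exit to death at 14–24.4%/yr) keeps the ESRD stock small
  relative to its inflow history.
* Undiagnosed diabetics are included in prevalence while duration
  summaries describe diagnosed cases; both strata share the same duration
  law, which likely overstates elapsed progression for the undiagnosed.
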