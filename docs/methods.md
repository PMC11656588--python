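# Methods

## Model structure

A simulated cow is a bundle of stochastic draws shared across two housing
scenarios ("control" = 3 m² living space, "high" = 6.5 m²): milk-curve
coefficients, conception times, gestation and dry-period lengths, exit
timings, and the economic draws of each comparison. A lifetime is defined
up front by its exit parity p ∈ {1..10} and the days in milk at exit in
the final lactation; for parities before exit, the next calving falls at
`conception + gestation` days after the last and dry-off at `next calving
− dry period`. Calving day is day 0; the first milking day is days-in-milk
1; all timings are whole days (real-valued draws are rounded at draw
time). Each cow is run through the full 10 × 5 exit design, so one cow
yields 50 paired comparisons; the emulated study design used 40,000 cows
per group (2,000,000 comparisons) and the default desk scale is 2,000
cows, configurable up to full scale.

### Milk yield

Daily yield is a Wilmink curve per parity class plus additive effects:

    y(t) = a + b·e^(−k·t) + c·t + space·1[high] + g(stage),

floored at 0. The five gestation-stage effects g apply from the day after
conception, with stages binned at 56-day intervals of days pregnant
(1–56, 57–112, 113–168, 169–224, ≥225); whether the original trial used
trimester-like or other bins is not public, so the edges are
configuration. Per-cow heterogeneity perturbs every curve coefficient and
the space effect independently (Normal, configurable sds); the
root-mean-square of the standardized perturbations is the single
"coefficient deviation" covariate carried into the regression — the
original trial's equivalent covariate is not defined publicly, so this
stand-in is a documented design choice.

### Reproduction

Time to conception is normal per scenario × parity class with the trial's
published means and sds; the multiparous value is reused for every parity
≥ 2. One gestation and one dry-period draw serve the entire lifetime of
both scenarios (the downstream regression has exactly one covariate for
each). Draws below a 21-day floor (earliest plausible post-calving
conception; the source is silent on how impossible values were handled)
are replaced by the next deviate in the stream.

The two scenarios share the underlying standard-normal deviate within a
parity class (common random numbers). Marginals are unchanged — each cell
is exactly its configured normal — but scenarios configured identically
then receive identical draws, which makes the paired design exactly
self-cancelling when the space effect is zero. This is both a
variance-reduction device and the property that the cancellation tests
exercise.

### Replacement

When the scenarios' exit days differ, the earlier-exiting cow is replaced
immediately by a heifer with the same coefficients and draws, parity
restarting at 1, continuing through further lactations if the gap demands
and truncated at the later exit day (milking stops at dry-off if the
truncation falls inside a dry period). Both timelines then span the same
horizon, making the comparison a per-cow-place comparison. Replacement
calvings incur transition costs like any other calving.

### Partial budget

Only scenario-dependent items are priced: lifetime milk at a margin over
purchased feed (one U(0.17, 0.23) £/liter draw per comparison, shared by
both scenarios) and transition-period disease costs per calving event (one
primiparous and one multiparous cost draw per comparison, reused across
events and scenarios). Cull income and all other costs are taken as
identical between scenarios and excluded. The per-year figure divides by
the shared horizon at 365.25 days/year; whether the source normalized by
the shared or per-scenario span is unstated, and the shared span is the
recorded choice (after replacement the two coincide anyway).

### Financing

The repayment model is not named in the source material; equal annual
principal installments with interest on the outstanding balance reproduce
every published total exactly (total = P(1 + r(n+1)/2)), so that model is
the default, verified in tests against an explicit year-by-year schedule.
An annuity (equal-payment) alternative is available via
`LoanTerms(model="annuity")` and is flagged as *not* reproducing those
totals. Percentiles use linear interpolation between order statistics;
"probability of positive net return" counts strictly positive values.
Arithmetic is carried at full precision; currency is rounded half-up to
pennies at display only, with per-year figures derived from unrounded
totals. One published inconsistency is surfaced rather than resolved: the
outdoor-extension narrative quotes a +£59.58 median net return at 4%,
while the published sensitivity table's own arithmetic gives £62.57
(= 87.61 − 25.04); the table's arithmetic is implemented.

### Regression

OLS of the per-cow-per-year difference on exit parity (dummy-coded,
reference 3) and the standardized continuous inputs, with lifetime days
excluded as collinear with exit parity. Standardization uses the sample
(n−1) sd; the response is standardized too by default (consistent with the
magnitudes of the published coefficient table), with scaling constants
stored so estimates can be converted back to GBP. Confidence intervals and
p-values are classical OLS t-statistics, two-sided, uncorrected.
Estimation is delegated to statsmodels; tests cross-check against a
normal-equations solve.

## Calibration of the synthetic milk model

The trial's fitted mixed-model coefficients are not public, so absolute
outputs (e.g. the published £87.61 median) cannot be derived from first
principles. The shipped defaults were instead calibrated, once, to a
pre-registered objective: emulate the study's *qualitative* findings —
the high-space advantage positive in the large majority of comparisons
and declining monotonically with exit parity — under plausibility
constraints (305-day base-lactation totals ≈ 7,700 L primiparous and
8,100 L multiparous, near the UK average; peak yields 23–41 L/day;
non-negative base yield over the milking range). The search evaluated the
deterministic (zero-noise) expected parity profile on a grid of curve and
effect values. Defaults: primiparous Wilmink (29, −8, 0.050, −0.022),
multiparous (44, −16, 0.060, −0.110), space effect 1.8 ± 0.35 L/day,
gestation effects (−1.5, −1.5, −2.0, −2.0, −2.5) L/day.

A structural fact discovered during calibration and worth knowing when
re-calibrating: gestation-stage penalties cancel between scenarios in
*completed* lactations, because days pregnant always spans 1 to
(gestation − dry period) regardless of conception day. Stage effects
therefore act only through truncated spans (final lactations and
replacement tails), and the parity profile is governed by the base curves:
the flat, persistent primiparous curve keeps long replacement tails
valuable (suppressing the late-parity upturn) while the steep multiparous
decline keeps the high-space cow's extra late-lactation days cheap. The
multiparous 305-day total consequently sits near the UK average rather
than at elite-herd levels; raising it flattens the parity decline.

What passing tests show — and do not show — about real data: the pipeline
reproduces the published financing arithmetic exactly, and under the
shipped calibration reproduces the qualitative simulation findings
(positive share well above 90%, monotone parity decline, positive margin
effect). It does not certify the absolute simulated medians, the published
99.58% positive share, the published regression coefficients, or
probability-of-positive-net-return percentages; those depend on the
unpublished trial model. The generator also omits features of real herds:
no pregnancy loss or service-level reproduction, no seasonality, no
disease incidence beyond the aggregate transition cost, no heifer-rearing
cost or genetic gain in replacements, and no milk-price dynamics.

## Numerical and interface choices

- One master seed; each cow receives three child streams (milk,
  reproduction, economics) via `numpy` `SeedSequence.spawn`, so runs are
  bit-reproducible end to end and module draws are decoupled.
- Lifetime milk sums are memoized per cow on span features (scenario,
  parity class, conception day, end day); memoized and direct evaluation
  agree exactly and are tested to.
- Degenerate inputs: zero-width uniforms and zero sds are valid and
  reproduce their point values exactly (used throughout the tests);
  zero-length spans, empty samples, empty rate grids, constant predictors
  and rank-deficient designs raise typed errors naming the offender.
- Desk-scale test sizes: the cancellation check runs 10,000 comparisons;
  distributional checks use 100,000 draws; the qualitative pattern check
  runs 30,000 comparisons (600 cows). At that scale adjacent high-parity
  regression contrasts differ by ~0.01–0.03 response-sd — flat within
  sampling noise, as in the published table, where adjacent high-parity
  contrasts differ by 0.01 — so the pattern test asserts strict decline
  where the structure is steep (parities 4–7), no significant adjacent
  increase (3 SE) across the parity 8–10 plateau, and the exact strict
  decline on the noise-free structural profile.

## Known limitations

- The published figures tied to "the UK average cow lactation of 3.7" are
  not reproduced; the interpolation or weighting behind them is unstated.
- The five-stage gestation binning and the coefficient-deviation covariate
  are reconstructions; alternative definitions would change regression
  magnitudes (not the tested qualitative pattern).
- Transition costs attach to every calving, including the first and
  replacement calvings; if the source charged them only to completed dry
  periods, parity-1 comparisons would differ by one cost draw.
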