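# Methods

## Model structure

`microenv` is a discrete-time (annual-cycle) stochastic multistate model
run independently per small area. Individuals occupy one of three states —
H1 (no diagnosed disease), H2 (ever diagnosed; absorbing until death), H3
(dead; terminal) — and transition through sequential Bernoulli trials.
Only three state-conditional probabilities are needed per (age, sex,
area, year) stratum, derived from published population-level rates by
conditional-probability inversion:

* `P(I|H1) = P(I) / (1 − P(H2))` — incidence rates are published per
  100,000 of the *total* population, so the denominator removes the
  prevalent pool;
* `P(M~d|H1) = P(M_all) − P(M_d)` — other-cause mortality, under the
  assumptions that (i) non-disease death rates are equal in H1 and H2 and
  (ii) disease-specific death occurs only from H2;
* `P(M|H2) = P(M_d) / P(H2) + P(M~d)` — excess (case-fatality) hazard plus
  other-cause mortality.

Relative risks are applied to the population-level probabilities *before*
the subtraction, so the (larger) case-fatality multiplier is removed from
the all-cause channel rather than double-counted. The identity
`P(H2)·P(M|H2) + (1−P(H2))·P(M~d) = adjusted P(M_all)` holds exactly
wherever no clamp binds, and is property-tested.

Stay-in-state probabilities are complements; recovery from H2 to H1 has
probability zero (diagnosis, not symptom status, defines the state).
Sudden cardiac death from H1 is not modelled: H1 mortality excludes the
disease-specific channel entirely.

## Risk channels and parameters

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| `rr_incidence_per10` | 1.08 | – | IHD incidence RR per 10 µg/m³ PM2.5 |
| `rr_case_fatality_per10` | 1.21 | – | IHD case-fatality RR per 10 µg/m³ |
| `rr_allcause_per10` | 1.06 | – | all-cause mortality RR per 10 µg/m³ |
| `depr_ratio_male` | 1.7 | – | decile-1 : decile-10 male mortality ratio |
| `depr_ratio_female` | 1.5 | – | same for females |
| `reference_mean` | *required* | µg/m³ | population-weighted mean μ at which RR = 1 |
| `ihd_lag_tau` | 5 | years | time constant of the exponential IHD lag |
| `allcause_lag` / `ihd_lag` | `epa_smooth` / `exponential` | – | lag-curve kinds |

Exposure scaling is the power law `RR(x) = RR_per10^((x−μ)/10)`, which is
multiplicative in concentration increments. μ has no sensible universal
default and must be supplied; the synthetic/demo configurations use
10 µg/m³ as a realistic national-scale annual mean. Deprivation scales
mortality as `r^((5.5−j)/9)` about the average decile 5.5, giving a unit
geometric mean across deciles; it is deliberately not applied to
incidence (no adequate empirical basis) nor to prevalence initialisation.

### Cessation lags

Lags are cumulative benefit fractions `f(t)` with `f(0)=0`, non-decreasing,
`f→1`. The EPA-style curve realises the 30/50/20 tranche totals (year 1,
years 2–5, years 6–20) as uniform annual increments — piecewise-linear in
continuous time — because an annual-cycle model needs yearly values and
only the tranche totals are specified. The IHD case-fatality lag is
exponential, `f(t) = 1 − exp(−t/τ)`; τ is a config parameter (default
5 years) because published evidence motivates the shape but not a
constant. The lag is applied by interpolating the *concentration*,
`x_eff(t) = x_base − f(t)(x_base − x_scn)`, which under the power-law RR
is exactly log-linear interpolation of the relative risk and keeps the
three channels consistent. Lags apply only to the two mortality channels
and only to reductions; incidence responds immediately, as do
concentration increases (a cessation lag describes benefit accrual, not
harm onset).

## Engine conventions

* **Trial order.** H1: incidence trial first; a newly incident individual
  faces the *diseased-state* mortality probability in the same year (the
  sequential-trial reading in which the first outcome selects the second
  trial's probability). The alternative — keeping the healthy-state
  probability in the incidence year — is available via
  `incident_rule="healthy"`.
* **Aging.** Rates are looked up at age at year start; survivors age +1
  after the trials. Ages cap at 110; ages above the top rate band use the
  open-ended 95+ band.
* **Prevalence denominator.** The P(H2) in the case-fatality term is the
  baseline *table* prevalence for the stratum, not the evolving simulated
  prevalence: the excess hazard is derived from published statistics, and
  a state-dependent transition matrix is not part of the model.
* **Births.** Each alive female aged 15–44 at year end bears a child with
  probability GFR/1000; newborns enter at age 0, H1, male with
  probability 0.512 (standard sex ratio at birth, configurable), and face
  no trials in their birth year. Migration is zero; baseline rates are
  held at base-year values throughout.
* **Rate → probability.** Annual rates per 100k are used directly as
  Bernoulli probabilities (`r/1e5`, clamped at 1) without the actuarial
  `1 − e^{−r}` transform; at table magnitudes the difference is far below
  Monte-Carlo noise. Band-to-single-year expansion is piecewise constant.
* **Clamping.** Adjusted probabilities above 1 and negative other-cause
  subtractions are clamped/floored and counted in the run log rather than
  raised: extreme-but-legal parameter combinations (very high exposure,
  very old ages) must not abort a long simulation. The reconstruction
  identity is exact only where no clamp binds.
* **Randomness.** One `SeedSequence` per area from
  `(master_seed, crc32(area_id))`, split into initialisation, trial and
  birth streams. Scenario runs reuse the same streams by default (common
  random numbers), so a null scenario produces exactly zero deltas and
  paired contrasts have sharply reduced variance; `rng_mode="independent"`
  salts the stream with the scenario name. Trial uniforms are drawn for
  the full roster (including the dead), keeping draws person-aligned
  across scenarios. Per-area runs share no state and are order-independent
  (embarrassingly parallel).

## Scenario analysis

Scenario transforms never return below the area's non-anthropogenic
component — in particular the uniform decrement floors there rather than
at zero, since no emissions policy removes natural background. Delta
metrics are ratio-of-totals: counts are aggregated to the requested
stratification first, then differenced as proportions × 10⁵ (not averaged
over per-area deltas). The reporting denominator is alive-at-year-start.
The 5-year running mean is centred with symmetric truncation at the
series edges; display smoothing only.

## Synthetic data

The generator emulates the *structure* of the model's inputs: Poisson
area populations (mean 1500) with a young-urban age mixture (children,
an adult bulk peaking near age 30 sampled from a truncated normal, an
elderly tail), uniform deciles (optionally Gaussian-copula-correlated
with pollution for inequality experiments), total PM2.5 uniform on a
configurable range (default 8–16 µg/m³) with a non-anthropogenic
component near a 2 µg/m³ floor, and GFRs of 50–70 per 1000. Rate tables
use Gompertz all-cause mortality and logistic age profiles for disease
metrics with parameter-level jitter, so the constructed orderings
(disease ≤ all-cause mortality; male ≥ female disease rates; monotone
adult age gradients) hold for every seed.

What passing tests on these data do **not** show: agreement with any real
city's marginals, spatial autocorrelation of pollution, real
deprivation–pollution joint structure, migration effects, or secular
trends in baseline rates. The synthetic results demonstrate mechanism
and internal consistency, not calibrated magnitudes.

## Verification and problem sizes

The suite checks the analytic constants exactly; the probability calculus
against randomized reconstruction identities; and the engine against an
independent closed-form Markov recursion (single-stratum cohort of 10⁵,
constant probabilities, 20 replicate seeds, 30 years, 3σ multinomial
bounds each year). The scenario-level behaviour — benefit signs, male >
female benefit, the ~30% year-one share from the cessation lag, and the
uniform-decrement > partial-cap ordering — is checked on CRN-paired runs
of 100 (resp. 30) synthetic areas × ~1500 residents over 50 (resp. 30)
years, averaged over 20 seeds. The year-one lag share is measured against
a no-lag reference run at the same epoch rather than a late-horizon
delta, because late-window benefits mix lag accrual with mortality
displacement and demographic drift.

## Known limitations

Single disease, single exposure channel (the config is generic but only
PM2.5 is wired); no migration; no intra-year time steps; no
concentration–response nonlinearity (log-linear RR only); baseline rates
static over the horizon; deaths "saved" by a scenario later return as
mortality displacement, so long-horizon mortality deltas understate the
instantaneous hazard reduction; per-area independence excludes any
between-area interaction.
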