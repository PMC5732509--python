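# Methods

## The model

`nephrosim` implements an aging-chain system-dynamics model of the
adult (20+) population of a country, stratified by sex, six age bands
(20–29, 30–39, 40–49, 50–59, 60–69, 70+) and three health states:

* **NDM** — no diabetes;
* **DM** — diabetes, not on dialysis;
* **DMDi** — on dialysis due to diabetic nephropathy (ages 40+ only).

Per sex this gives 16 stocks (6 NDM + 6 DM + 4 DMDi).  The flows are

* **entry at 20**: an exogenous cohort series split between NDM and DM
  by the entry diabetes prevalence (default 0.2%);
* **aging**: first-order outflow `stock / 10` per year from each closed
  ten-year band into the next band of the same state; the 70+ bands
  are terminal (death only).  The first-order form is the standard
  aging-chain formulation and keeps the system linear in the stocks;
  it trades cohort-wave fidelity for robustness, which matters because
  calibration explores extreme rate values;
* **diabetes incidence**: NDM→DM at a constant band-specific hazard
  `DM<band>ir` (1/yr);
* **dialysis initiation**: DM→DMDi at a constant band-specific hazard
  `DMDi<band>ir` for bands 40+.  DM stocks under 40 have *no*
  initiation outflow: under-40 dialysis patients are outside the model
  (their counts are two to three orders of magnitude below the 40+
  stocks and would destabilize the fit), and the survivors of that
  group enter DMDi4049 through an exogenous age-40 inflow;
* **death**: state/band/year-specific exogenous mortality rates.

There are no feedback loops, no migration, no remission and no
transplant outflow.  Exogenous series are step functions, constant
within each calendar year; values beyond the last tabulated year hold
the final value (entry cohorts are tabulated through the horizon).
The age-40 dialysis inflow is continuous rather than an annual pulse.

Integration is explicit Euler with `dt = 1/16` year and annual output
sampling, matching system-dynamics tooling conventions.  A convergence
test guards accuracy (halving `dt` moves every 2035 aggregate by less
than 0.1%), and a single-compartment run reproduces `e^{-rt}` within
0.5%.  Stocks that undershoot zero are clipped to zero with a logged
warning; with rates inside the calibration bounds this never triggers.
Aggregates follow the conventional definitions: `TotalDM = DMover20 +
DMDiover40`, adult prevalence = `TotalDM / popover20 × 100`.

For calibration the same Euler scheme is evaluated through per-year
one-step operators (`P = (I + dt·A)^16` by squaring): the system is
linear in the stocks, so this is algebraically identical to the
stepper and about 60× faster; a test pins the equivalence at 1e-9
relative.  Time-varying rate multipliers (scenario ramps, drift) use
per-substep operator products, again identical to the stepper.

## Data derivation rules

The `data_prep` module implements the processing steps applied to the
published national statistics before calibration:

* prevalence anchors at 2000/2005/2010 are interpolated linearly and
  extrapolated past 2010 on the 2005–2010 slope (the most recent
  trend; the sources state only that values were interpolated and
  extrapolated), clipped to [0, 100]%, then multiplied by band
  population to give counts;
* pre-2011 dialysis counts per band are back-cast as `allcause ×
  mean 2011–15 nephropathy share`, rescaled so bands sum exactly to
  the known yearly total;
* all-cause mortality is decomposed into non-DM and DM rates assuming
  a DM:non-DM hazard ratio of 2 (`m_ndm = m_all / (1 + p)` at that
  year's interpolated prevalence `p`); for bands 40+ the DM rate is
  further corrected by removing dialysis-patient deaths
  (`(m_dm·n_dm − m_di·n_di) / (n_dm − n_di)`, floored at 0 with a
  warning);
* the age-40 dialysis inflow is `(n_35–39 + n_40–44) / 2 / 5`;
* dialysis mortality observed 2012–15 is extrapolated backward to
  2000–11 on an OLS line, clipped to [0, 1].

All clipping/flooring events are logged with context.

## Calibration

Per sex, the fitted variables are the 16 annual observed series (pop,
DM and DMDi per band) over 2000–2015.  The payoff is

```
Σ_v Σ_t ( w_v · (model_v(t) − data_v(t)) )²,   w_v = 1 / mean_t data_v(t)
```

with the weight inside the square so residuals are scale-free; the
sources state the inverse-mean weights but not their placement, so
tests rely only on properties invariant to this choice (the noise-free
argmin, scaling invariance).  Variables with zero mean are excluded
with a warning (mirroring the exclusion of unstable small stocks).

Unknowns: 10 hazards (bounds: diabetes incidence [0, 0.05]/yr,
dialysis initiation [0, 0.02]/yr — an order of magnitude above any
plausible value) and the 16 initial stocks, bounded within ±20% of the
values implied by the first-year observations, which keeps the
26-parameter problem identified.  The optimizer is bounded Powell with
8 restarts (one low-rate/data-centred start plus 7 seeded uniform
draws); the best payoff wins, ties to the first found.  On the fixture
the optimum is reproducible across seeds to three decimals in the
reported reductions.

Recovery behaviour, measured by the test suite: on noise-free
synthetic data all ten hazards return to the truth essentially exactly
(≪1% error, incl. hazards whose truth is 0, which hit the zero bound);
with 1% multiplicative observation noise the median error over ten
seeds stays below 15%.

## Scenarios

Interventions are multipliers on the rate families: 1.0 up to 2015,
linear to 0.5 at 2025, then flat (the ramp shape between the stated
endpoints is assumed linear).  DMP scales all diabetes-incidence
hazards; ESRDP scales all dialysis-initiation hazards *and* the
exogenous age-40 dialysis entry (that stream is an initiation pathway;
at ~165 vs ~10⁵ persons/yr the choice is numerically negligible);
DMP+ESRDP scales both.  Comparisons report levels and percent
reductions of `TotalDM` and `DMDiover40` at the report year (default
2035) plus each run's `TotalDM` peak (earliest tie).

## Sensitivity analyses

* **Rate sweeps** re-run the base projection over a strictly
  increasing grid of one hazard, all else bit-identical (verified by
  parameter hashing).  The two stock grids are the female 30–39
  diabetes and 40–49 dialysis-initiation hazards, swept from 0 to the
  published next-band values (0.00138225, 0.00136167).
* **Entry-prevalence sweep**: 0%, 0.2%, 0.4% diabetes at age 20.
* **Horizon 2055**: all four scenarios with held exogenous values.
* **Drift**: effective rate(t) = calibrated rate × e^{g(t−2000)} with
  one coefficient per family per sex, |g| ≤ 0.05/yr (per-family rather
  than per-band to keep the optional joint recalibration identified);
  drift never scales the exogenous age-40 entry (it is data, not a
  hazard).  `calibrate_with_drift` optionally fits both g jointly with
  the rates.

## The synthetic-data generator

`generate_synthetic_country` forward-simulates a known ground truth
over 2000–2015 and emits the observation cross-table, optionally with
independent multiplicative log-normal noise of a given coefficient of
variation (mean-one correction applied; cv = 0 reproduces the model
output exactly).  The default truth uses Japan-like demography and
age-increasing hazards; the female 30–39 diabetes and 40–49
dialysis-initiation hazards are zero and the published female 40–49
diabetes and 50–59 dialysis-initiation values are used verbatim.

`build_japan_like_fixture` is the deterministic desk-scale stand-in
for the national statistics.  Published endpoint anchors reproduced
exactly: diabetes totals 4.19M→5.32M (males) and 2.90M→3.39M (females)
over 2000–2015; 40+ dialysis 34,672→83,858 and 17,219→35,048.
Everything else is a documented construct chosen for realism once and
frozen: decelerating monotone cubic interpolation between anchors
(end slopes 1.5×/0.5× the mean slope — the published series flatten
late); fixed age-allocation shares (diabetes skewed to 50+, dialysis
skewed even older); band populations resembling the Japanese age
pyramid with a shrinking young-adult base; entry cohorts declining
0.8%/yr; all-cause mortality rising steeply with age and declining
slowly over time; dialysis mortality roughly 3.5–16%/yr by band, far
above diabetic mortality.  Mortality schedules are built through the
`data_prep` decomposition at hazard ratio 2, so the fixture exercises
the same derivation code as real inputs would.

What the fixture does **not** emulate: the true (unpublished) sex/age
composition of the national tables, cohort waves within bands,
migration, and share drift over time.  Absolute projections from the
fixture therefore approximate rather than reproduce published absolute
projections — they land within a few percent (e.g. male 2035 dialysis
~112k) because the anchors pin the totals — whereas ratio-type results
(percent reductions, orderings, gap directions) are driven by model
structure and ramp shape and are the quantities the acceptance checks
target.

## Numerical and design notes

* Euler `dt = 1/16` yr; output at integer years; `1/dt` must be an
  integer and `dt ≤ 1`.
* Powell options: `maxfev = 30000`, `xtol = 1e-6`, `ftol = 1e-10`
  per start.  Unit-cube parameterization (rates scaled by their
  bounds, stocks by the ±20% window) equalizes step sizes across the
  very different parameter magnitudes.
* Ties in peak detection resolve to the earliest year; peak detection
  operates on annual samples.
* Degenerate inputs: empty trajectories aggregate to empty tables;
  zero-mean variables are excluded from the payoff rather than given
  infinite weight; all-zero back-cast with positive total is an error.
* Problem sizes: calibration fits 256 observations (16 variables × 16
  years) per sex; projections run 35–55 years at 16 substeps/yr.  The
  full pipeline (fixture, two calibrations, four scenarios each)
  completes in well under a minute on one CPU.

## Known limitations

* Constant hazards over 2000–2015 are an idealization; the drift mode
  exists precisely to probe it.
* First-order aging cannot reproduce sharp cohort waves (e.g. a baby
  boom traversing a band); band-level fits inherit this smoothing.
* The DMDi state has no vintage structure, so dialysis-initiation
  interventions act instantaneously on the whole DM stock; real
  nephropathy progression would add delay.
* Under-40 dialysis dynamics are exogenous by construction.
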