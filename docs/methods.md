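# Methods

## Model structure

The simulator is a Markov macro-simulation of a closed cohort aged 35+
at the 2011 baseline, advanced in annual cycles to death or age 100.
The cohort is stratified by sex × ethnicity (Māori / non-Māori) ×
thirteen 5-year age bands (35–39 … 95–99; the open-ended "95+" band is
treated as 95–99 with a hard stop at age 100).  Internally each 5-year
band is expanded into its five single-year starting ages with equal
population splits; the band's rates apply to every constituent age and
each single-age cohort ages exactly one year per cycle.

Seven states are tracked: healthy, CHD (first year / subsequent years),
stroke (first year / subsequent years), CVD death and other-cause
death.  The first-year states are tunnel states existing solely so that
first-year costs (and, where supplied, first-year case fatality) can
differ from subsequent years; survivors move deterministically to the
subsequent-year state after one cycle.  There are no CHD↔stroke
transitions and no combined-disease state: a healthy person acquires at
most one disease, a deliberate simplification of the four-primary-state
design.  Baseline prevalent cases are seeded into the subsequent-year
states (prevalence is dominated by non-incident cases); the remainder
starts healthy.

### Competing risks

Within a cycle, rates compete jointly: total exit probability is
1 − exp(−Σ rates), apportioned among causes proportionally to their
rates.  This is the standard exponential conversion for annual-cycle
models; it guarantees row-stochastic transition matrices for any
non-negative rates.  No half-cycle correction is applied — state
membership is evaluated at cycle end, and QALYs/costs accrue on the
end-of-cycle occupancy for the full year.  At the end of the age-99
cycle any remaining alive occupancy is absorbed into other-cause death
(recorded as an age-100 row that accrues nothing).

### Secular trends

CHD and stroke incidence and case fatality decline at 2.0 %/year;
background (non-CVD) mortality declines at 1.75 %/year for non-Māori
and 2.25 %/year for Māori.  All trends run from 2011 to 2026 and are
frozen thereafter.  No trend is applied to morbidity weights, baseline
blood pressure or sodium intake.

## Interventions and the risk pathway

An intervention is (name, reduction fraction of total daily sodium at
full implementation for the average adult, phase-in years, one-off
cost).  Built-ins: salt substitution at 59 % (reduction 51.5 %) and
25 % (21.8 %), bread limits of 280 mg/100 g (7.9 %) and 400 mg/100 g
(2.3 %), and the null comparator.  The printed reduction fractions are
taken as authoritative inputs; the share arithmetic behind the bread
fractions (post-law/baseline concentration ratio × 20.6 % bread share)
is exposed separately via `bread_share_shift`.  Phase-in proceeds in
equal annual steps, step k covering the whole of calendar year
baseline + k − 1 (an annual-cycle model admits no partial-year steps);
the 400 mg limit is fully implemented in the baseline year.  The
one-off legislation cost (NZ$3.68 M) is charged once, undiscounted, at
the baseline year — the cost is incurred at legislation, and at the
baseline year the discount factor is 1 regardless.

Sex-specific doses rescale the average-adult fraction by the ratio of
the sex's baseline intake (4013/3115 mg/d men/women) to the average
adult's 3544 mg/d, which collapses to fraction × sex intake.  The rule
is applied uniformly to all four interventions.  Doses convert to
mmol/day at 23.0 mg/mmol, then to a systolic-BP reduction linearly via
the age-specific response table (5.5 / 6.6 / 9.2 / 10.3 mmHg per
100 mmol/day for ages 30–39 / 40–49 / 50–59 / 60–69).  Ages 35–39 use
the youngest row; the 60–69 value is carried forward to all ages 70+ —
a conservative extension of a table that ends at 60–69.

Incidence multipliers follow the log-linear BP–risk relation
HR₂₀^(ΔsBP/20).  The published evidence gives only the age ranges of
HR₂₀ (0.49–0.67 for CHD, 0.38–0.67 for stroke), so the per-band
defaults interpolate log-linearly between the most protective value at
the youngest bands (up to 40–44) and 0.67 from 85+, matching the known
age attenuation while keeping every value inside the printed interval
(invariant-checked).  Multipliers apply to incidence from the healthy
state only: the modelled chain links blood pressure to first-event
probability, not to case fatality, background mortality or recurrence
among prevalent cases.

## Economics

Utilities: healthy = 1 − pYLD (the stratum's prevalent-YLD per capita);
disease states subtract the disability weight (0.081 CHD, 0.226
stroke); death is 0.  Costs: healthy-state annual cost by sex × age
band (already net of the CVD-attributable component, to avoid double
counting), first/subsequent-year disease costs, all multiplied by the
1.2 public-share scale-up and by 1.1 / 1.2 / 1.3 at ages 65–74 / 75–84
/ 85+.  All costs are 2011 NZ$.  End-of-life costs are not modelled as
a separate parameter; they are folded into the state costs.

Both streams are discounted at (1+r)^−(year−2011) with r = 0.03 by
default (0 and 0.06 as scenario settings).  Incremental results against
the do-nothing comparator are classified *dominant* (ΔQALY > 0,
Δcost < 0), *dominated* (the reverse), or by an ICER = Δcost/ΔQALY when
both deltas are positive.  Per-capita subgroup results divide the
subgroup's health-system cost delta, plus its population share of the
one-off intervention cost, by the subgroup's baseline population.

## Synthetic inputs

The generator emulates the structure of the study's administrative
inputs; it is a first-class, validated module, not a test fixture.

* **Exact anchors** (reproduced identically for every seed): sodium
  intakes 4013/3115/3544 mg/d and source shares (72 % processed food,
  15 % table salt, 20.6 % bread); cost anchors for a 60-year-old woman
  — healthy NZ$2381/yr, CHD NZ$16,258 / 5,395, stroke NZ$20,553 / 5,991
  (before scale-ups); disability weights 0.081 / 0.226 with 95 % bounds
  0.05–0.11 / 0.11–0.23; all trend rates; the BP-response table.
* **Emulated surfaces**: rate curves are log-linear in age (Gompertz-
  like), pinned at age 60 for the non-Māori female reference —
  CHD incidence 0.003/yr, stroke 0.002, CHD case fatality 0.030, stroke
  0.050, background non-CVD mortality 0.004 — with age slopes of
  0.04–0.095 per year and multiplicative ratios for Māori (2.0 CHD,
  1.8 stroke, floored at 1.5) and men (1.8 CHD, 1.25 stroke).  These
  magnitudes were chosen once as epidemiologically plausible for a
  developed-country CVD burden; they are deliberately not fitted to any
  published total.  Prevalence is approximated as incidence × mean
  duration (7 y CHD, 5 y stroke, capped).  Background pYLD rises
  linearly with age from 0.03, Māori ×1.15.
* **Seed noise** enters only through curve parameters (lognormal, SD
  3–5 %) and population counts (SD 1 %), so age-monotonicity and the
  Māori ≥ non-Māori ordering hold by construction for every seed and
  anchors never move.  The population totals 2.3 M ± 1 %.

What passing tests on these inputs do and do not show: the qualitative
result pattern (scenario ranking, dominance, the equity gradient, the
old-age/late-time concentration of gains) follows from the modelled
structure and holds on the synthetic surfaces; absolute totals (e.g.
lifetime QALYs of a given scenario) depend on the unpublished real
surfaces and are only order-of-magnitude comparable.  The generator
also omits features of real data such as cohort-specific period
effects, non-monotone young-adult mortality, and correlation between
costs and comorbidity.

## Uncertainty analysis

Monte Carlo with 2000 iterations by default.  Distributions: normal
with SD = 10 % of the point estimate for intervention effect sizes and
hazard ratios ("±10 % of the point estimate" is read as SD = 0.10 ×
point estimate, consistent with the explicit hazard-ratio phrasing);
gamma with SD = 10 % of the mean for each cost component; disability
weights are beta, moment-matched to the stated 95 % intervals (mean at
the interval midpoint, SD = width/3.92).  Out-of-range draws (hazard
ratios outside (0,1), negative doses, weights outside their bounds) are
resampled, never clamped, to avoid mass spikes at the bounds.  With all
SD scales set to zero each draw equals the point estimates exactly.
Parameters are sampled independently (no correlation structure is
specified by the evidence), each from its own counter-based substream
keyed by (seed, parameter, iteration), so adding a parameter never
perturbs existing draws.  Intervals are empirical 2.5th/97.5th
percentiles of the draws; the central estimate is the expected-value
run, not the Monte Carlo mean.  Only parameters with stated
distributions vary; the epidemiological rate tables stay fixed.

## Numerical choices and problem sizes

* Occupancy conservation is maintained to ~1e−15 per cycle; the engine
  matches an explicit matrix-power solution to 1e−12 on
  constant-rate instances.
* Discounting is exactly the closed-form factor per calendar year;
  accrual ledgers are additive over strata by construction.
* League-table ties break lexicographically by scenario name.
* Rendered tables round to 2–3 significant digits with thousands
  separators; CSV exports keep full precision (floats are written with
  shortest-round-trip formatting and parsed in round-trip mode, so the
  on-disk parameter format is lossless).
* The default suite exercises full cohort runs (260 single-age cohorts,
  ≤ 66 cycles) and Monte Carlo batches of 40–200 iterations; a full
  2000-iteration PSA over all four scenarios completes in minutes on a
  single core.

## Known limitations

* No micro-simulation: cohort fractions only, no individual histories,
  recurrence or severity progression.
* No stomach-cancer or renal pathways, and no potassium/magnesium
  co-benefits of substitution — benefits flow through sodium → BP only.
* Health-system perspective: productivity and other societal costs are
  out of scope; no equity weighting of QALYs.
* Uncertainty intervals do not capture model-structure uncertainty.
* Whether baseline rates should be back-corrected for programmes
  already operating at baseline is not quantified; the generated
  baseline is taken as the do-nothing baseline.
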