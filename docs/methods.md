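# Methods

## Model structure

The model is an annual-cycle cohort Markov model.  A cohort with no prior
alcohol-related hospitalisation enters at its profile age and faces eight
competing first events per cycle: wholly alcohol-attributable
hospitalisation, partly alcohol-attributable hospitalisation,
alcohol-related death, non-alcohol-related death, and non-alcohol
hospitalisation split into four admission types (emergency vs
non-emergency, CVD vs non-CVD).  Hospitalisation events move the cohort
to a cause-specific post-event state; the two death causes are absorbing.

Each cause-specific hazard is `h_k(t) = [exp(x b_k) CF_k] exp(gamma_k t)`
with `t` the years since model entry.  Covariates are fixed at entry
(there is no covariate drift; ageing acts through `gamma_k t`), with one
exception: the prior-hospitalisation covariate advances 0 ("never") -> 1
("admitted within the last year") -> 2 ("longer ago") after a first
admission.  This is implemented as a one-cycle tunnel inside each
post-event state; the public trace aggregates the tunnel away.  A new
admission from a post-event state re-enters the destination state's
tunnel (prior hospitalisation resets to "last year").  Post-event cohorts
reuse the same hazard specifications — the minimal structure consistent
with prior hospitalisation being a model covariate.

Competing hazards convert to one cycle's transition probabilities with
the constant-within-cycle exponential formula: `stay = exp(-H dt)`,
`p_k = (h_k/H)(1 - exp(-H dt))`, exact when hazards are constant over the
cycle.  Cycle length is one year; no half-cycle correction by default
(exposed as a switch, `model.half_cycle_correction`).  The horizon is age
100, short-circuited when living occupancy falls below 1e-9.

A 28-day case-fatality split on hospitalisation transitions is available
(`model.case_fatality`, a per-event fraction routed directly to the
matching death state) but defaults to 0: short-term deaths already enter
as the two competing death causes, so a nonzero split would double-count
them unless the death hazards are re-calibrated accordingly.

## Intervention

Random breath testing added to mass media campaigns multiplies the
road-traffic-attributable share of the partly-alcohol hospitalisation
hazard by (1 - 0.106) and of the alcohol-death hazard by (1 - 0.171) —
the published efficacy at 4.6% checkpoint coverage with full media
coverage.  The reductions are applied on the hazard scale (the published
account does not say whether hazards, probabilities or counts were
scaled; the hazard scale keeps competing-risk consistency).  The
road-traffic-attributable share defaults to 1.0 for the binge-drinker
cohort and is configurable in [0, 1] (`model.rti_share`).

## Economics

Life years count living occupancy at cycle start; QALYs weight occupancy
by state utilities; costs add per-state annual costs plus programme
costs.  Discounting is annuity-due at 3%/year: cycle 0 is undiscounted,
cycle t carries (1+r)^-t.  Programme costs accrue every cycle alive
(checkpoints and campaigns are ongoing programmes; a `once` switch
restricts them to entry): media cost per drinker (10.48 THB/year) in both
arms — the intervention is breath testing *added to* the campaigns — plus
checkpoint unit cost x coverage (1,322 x 0.046 = 60.81 THB/year) in the
intervention arm.

ICER = incremental discounted cost / incremental discounted QALYs;
dominance labels replace the ratio when one arm is cheaper and more
effective (or costlier and less effective).  Person counts use floor
rounding; the media cost per beneficiary is reported to two decimals.
Published population totals derive from unrounded per-capita increments,
so totals recomputed from printed rounded increments differ in the last
digits (~0.1–1%).  The published female binge-drinker count (311,257)
is not exactly the published population x percentage (33,960,884 x 0.92%
= 312,440 after flooring); the package reproduces the male count exactly
and uses its own derived female count.

## Calibration

Each event's calibration factor CF is fitted by bracketed root search
(Brent, CF in [1e-6, 1e6]) so the modelled cumulative first-event
incidence by a target age matches an external target within relative
1e-6.  Cumulative incidence is strictly increasing in CF (the hazard is
linear in CF), so the root is unique; unreachable targets raise an error
reporting the achievable incidence range.  Which external targets (life
tables, road-safety statistics) map to which event types was never
published; the synthetic fixtures make the mapping explicit instead of
guessing it.

## Synthetic scenarios

`make_scenario(seed, difficulty)` draws a full ground-truth bundle:
per-event Dirichlet-weighted baseline hazards anchored so the age-20
all-cause first-event probability lies in [0.005, 0.05] ("realistic";
[0.05, 0.2] for "easy", which absorbs faster and keeps tests cheap);
death-cause slopes gamma in [0.05, 0.12] (mortality doubling every ~7–14
years); positive binge and AUDIT coefficients for alcohol-attributable
causes; living-state utilities in [0.6, 1.0] and annual state costs in
[5,000, 30,000] THB.  Population, economic and intervention parameters
keep the published Thai values — those are the study conditions, not free
parameters.  The default bundle (`default_bundle`) uses fixed constants
chosen on the same anchors (young-adult all-cause mortality of order
1e-3/year; life expectancy in the low 70s).

What the generator does *not* emulate: the real covariate joint
distribution (profiles are fixed vectors, not survey draws), secular
trends, within-cohort heterogeneity beyond the covariates, and the
original Scottish/Thai coefficient values themselves.  Passing tests
therefore demonstrate that the machinery is correct — conservation,
closed forms, parameter recovery, oracle agreement — not that any
specific hazard value matches Thai epidemiology.

## Probabilistic sensitivity analysis

The published per-parameter distributions were not available, so the PSA
defaults are documented synthetic stand-ins, fully overridable: beta for
[0, 1] parameters (moment-matched to the base value with 10% relative
SE), gamma for costs (10% relative SE), lognormal for calibration factors
(log-SD 0.1).  All parameters vary simultaneously; 5,000 iterations by
default.  Per-iteration streams derive from (seed, iteration), making
iterations order-insensitive.  Ties (net monetary benefit exactly 0)
count as cost-effective.  The WTP grid runs 0–400,000 THB/QALY in steps
of 2,000 and contains the 160,000 threshold exactly.  The published
probabilities of optimality (99% male, 91% female) depend on the
unpublished distributions and are not reproduction targets.

## Numerical choices

- Hazard-to-probability conversion absorbs the floating-point residue of
  the share normalisation into the stay probability, keeping row sums at
  exactly 1 (checked to 1e-12).
- Calibration uses Brent's method with xtol/rtol 1e-12, then verifies the
  relative tolerance on the achieved incidence.
- Config round trips are exact: hazard tables are written with 17
  significant digits and parsed with round-trip float precision.
- A structurally absent cause is represented by an intercept low enough
  that its hazard underflows to exactly 0 (used by test fixtures).
- The microsimulation oracle replays the cohort engine's per-cycle
  transition rows on sampled individuals; agreement within 3 Monte Carlo
  SE is the engine's primary correctness check.

## Problem sizes

Default analyses run one 80-cycle cohort per arm (milliseconds).  The
test suite uses 2x10^4-individual microsimulations in unit tests and
10^5 in the end-to-end checks; the full-size PSA check runs 5,000
iterations.  The acceptance script runs the complete synthetic pipeline
with a 2,000-iteration PSA.

## Known limitations

- No property-damage, legal or productivity costs (healthcare-cost
  perspective of the source inputs).
- No tunnel states beyond the prior-hospitalisation progression; no
  time-varying covariates other than ageing.
- Two strategies only: no frontier analysis, EVPI or correlated PSA
  sampling.
- Subgroup drinking levels map to representative AUDIT scores (low risk
  7, moderate 14, dependent 24) — the original band edges were not
  published; explicit AUDIT integers can be passed instead.
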