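# Methods

## Model structure

The model is a deterministic system of stock–flow equations over
21 population stocks — three age bands (0–14, 15–24, 25+) crossed with
seven distress/care states — plus auxiliary variables (waiting time,
prevalence, event rates, delivered sessions) computed at every step.

States per band:

| state | meaning |
|---|---|
| `low` | low psychological distress (K10 < 16), not in care |
| `dist` | moderate-to-very-high distress (K10 16–50), not seeking care |
| `wait` | distressed, queued for a specialist appointment |
| `gp` | distressed, managed in GP care (assessed, not referred onward) |
| `spec` | distressed, receiving subsidised specialist sessions |
| `diseng` | distressed, abandoned the pathway after excessive waiting |
| `recov` | recently recovered through care, low distress |

Everyone is in exactly one (band × state) stock; bands are exhaustive and
disjoint. Demography is entries (births/child migration into `low` 0–14,
adult migration into `low` 25+), first-order ageing (1/15 and 1/10 per
year), and per-band exit rates. Ageing is a pure transfer, so with entries
and exits switched off the model conserves population exactly — a property
the test suite checks to 10⁻⁹ over 17 simulated years.

### Distress dynamics

Onset `low → dist` at a per-band base rate scaled by (i) a linear secular
ramp that saturates in 2019 (`onset_trend`, reproducing the strong rise in
measured distress prevalence through the 2010s) and (ii) a COVID-era
multiplier schedule (2020–2022) with an additional employment-disruption
increment that the JobKeeper wage subsidy damps during its operation window
(Apr 2020 – Mar 2021). Remission `dist → low` is first-order. Both COVID
magnitudes and the damping factor live in the parameter file, not in code,
so the shock transcription is auditable and swappable.

### Help seeking and the two pathways

Distressed people seek care at rate
`perceived_need × help_seek_rate × (1 + seek_trend·(t − 2011, capped at
seek_trend_end))`. The uptake trend (2%/year, saturating in 2022) encodes
the steady growth in subsidised-service use over the 2010s; the demand-uplift
policy lever multiplies `perceived_need` from its start date.

A seeker flow `F` splits:

- fraction `d` (the **direct access** lever; 0 before its start date) goes
  straight into the specialist queue;
- the remainder enters the GP pathway, of which `gp_referral_fraction`
  is referred into the specialist queue and the rest is absorbed into
  GP-managed care (`gp`), with its own — deliberately weaker — recovery
  (`gp_recovery` to `recov`, `gp_return` back to `dist`; 40% of GP-care
  episodes succeed under the defaults).

This structure is what makes direct access double-edged: it removes a
demand filter (GP-absorbed care) at the same time as it speeds access, so
specialist-queue inflow rises from `r·F` to `(d + r(1−d))·F`.

### Capacity, rationing, waiting, disengagement

Specialist capacity (pooled psychologists/psychiatrists/allied
professionals, in sessions/year) is piecewise-linear:
`C(t) = C₂₀₁₁ + s·(t−2011)`, with the growth lever multiplying the slope
from its start date (continuous at the switch). The slope is set so that a
fivefold multiplier from 1 Jan 2022 puts end-2028 capacity 71.6% above the
baseline projection, equivalent to ~3%/year baseline growth over 2021–2028.

Session demand has two components: in-care treatment
(`episode_sessions × treatment_recovery × spec`) and queue intake
(`intake_sessions × wait / admit_time` — admissions consume assessment/first-
session capacity). When total demand exceeds `C(t)` a single ration factor
φ = C/demand scales admissions and completions alike (proportional
rationing, no priority classes); delivered sessions therefore never exceed
capacity, and rationed patients simply stay in care longer.

The behavioural waiting-time signal is Little's law on the capacity left
after in-care demand, converted to weeks and capped:

    W = min( wait_cap, (wait × episode_sessions) / max(C − D_incare, ε) × 52.18 )

Queue abandonment follows a piecewise-linear hazard in the relative excess
wait, `h(W) = disengage_coeff × max(0, W − wait_ref)/wait_ref` (per week),
applied to the whole queue. Disengaged people drift back to the untreated
distressed pool at `reengage_rate`; they additionally rejoin the queue at
`reengage_seek_rate × max(0, 1 − W/wait_ref)` — i.e. only while waits are
short. This conditional re-engagement matters for scenario asymmetry:
a transient overload (large direct access + large capacity growth) recovers
its disengaged once slack appears, whereas a persistent overload does not.

### Better Access session cap

The annual subsidised-session cap (normally 10, temporarily 20 during the
pandemic; the extension ends 31 Dec 2022 by default, optionally 31 Dec 2023
via a scenario flag) scales per-episode session demand as
`4.5 × (cap/10)^0.15`. The anchor is the observed mean of 4.5 sessions per
user under the cap of 10; the small elasticity encodes that few users reach
the cap, so doubling it raises mean utilisation only mildly.

### Adverse outcomes

Instantaneous rates of mental-health-related ED presentations, self-harm
hospitalisations and suicide deaths are nonnegative linear combinations of
the distressed stocks: per-band base coefficients (events/person/year,
applying to `dist`) times care-state multipliers ordered

    disengaged (1.6) > waiting (1.15) > not seeking (1.0) > GP care (0.85) > specialist care (0.45)

so disengagement strictly worsens, and effective treatment strictly
improves, every outcome. `low` and `recov` contribute nothing. Outcomes are
purely observational — they do not feed back into the dynamics — which also
means their coefficients are identified independently of the flow dynamics.

## Time conventions and numerics

- Decimal years, (days since 1 Jan)/365.25; 1 Sep 2021 = 2021.6653 (leap
  years shift day-of-year: 1 Sep 2028 = 2028.6680). One week = 7/365.25
  years everywhere.
- Forward Euler with dt = 1/52 year. The integrator is first-order
  (halving dt halves the error, verified against exponential/matrix-
  exponential closed forms); all reported scenario contrasts are
  differences between runs on the identical grid, which cancels most
  discretisation bias.
- Stocks clamped at zero with the deficit logged (behavioural rates can
  transiently overdraw small stocks at weekly steps; the reference runs log
  no clamping).
- Event-count windows integrate the events/week series by the trapezoid
  rule with endpoint interpolation, making cumulation exactly additive over
  adjacent windows.
- Policy switches are half-open intervals [start, end): a program that
  "ends 31 December 2022" still applies that day and stops at 2023.0.
- The frontier optimum is the argmax on the evaluated grid; ties break
  toward smaller direct-access fractions. Printed tables round counts to
  integers and percentages to two decimals at presentation only.

## Calibration

The objective is the weighted mean absolute proportional deviation over all
observations of all series (weights normalised, so rescaling all weights
changes nothing; observations must be strictly positive). Model outputs are
aligned to observations by kind: annual counts integrate the matching rate
series over the observation year (mid-period date ± ½ year); levels
(prevalence) sample the nearest weekly grid point.

Minimisation uses Powell's direction-set method (scipy's implementation)
with each free parameter mapped to its (lower, upper) bound interval by a
logit transform, keeping the inner search unconstrained while making
out-of-bounds proposals impossible. Defaults: objective tolerance 10⁻⁶,
direction tolerance 10⁻⁴ (loosened to 10⁻⁴/10⁻³ for noisy-replicate
studies, where extra precision buys nothing), iteration cap 200 cycles;
on hitting the cap the best-so-far point is returned with
`converged=False`. The fitted objective never exceeds the starting
objective. The default free set is exactly the parameters flagged
`source=calibrated` in the reference parameter file.

The reference parameterisation was produced with this machinery plus manual
structural calibration against the constraints the historical aggregates
impose: total population ~7.2M (2011) growing to ~8.2M (2021); all-ages
moderate+ prevalence rising from ~27% (2013) to ~43.5% (2019) and easing to
~41% by 2028; delivered subsidised sessions ~3.6M/year around 2021 with
~3%/year capacity growth; and the cumulative 2021–2028 outcome counts
(739k ED presentations, 63.2k self-harm hospitalisations, 7 433 suicide
deaths; 15–24 shares 19%/29%/12%).

## Synthetic data

The generator runs the historical-era baseline (COVID shocks on) from a
ground-truth parameter set, samples the five observables (ED presentations,
self-harm hospitalisations, suicide deaths, moderate+ prevalence, delivered
sessions) annually at mid-year 2011–2021, and applies multiplicative
log-normal noise `exp(σZ − σ²/2)` (mean 1 on the natural scale; σ = 0.05 by
default, comparable to year-to-year administrative-data revision scale).
One seeded generator covers all series, so a fixture is byte-reproducible
from (spec, seed); provenance (seed, σ, true parameters) is written beside
the series. Noise touches observations only — the dynamics stay
deterministic.

What it emulates: levels, trends, COVID-era disruption, and observation
noise of annual administrative aggregates. What it does not: revision
histories, definitional breaks, survey-design effects, sub-annual
seasonality, or age-disaggregated series. A calibration that passes the
recovery tests here therefore demonstrates correctness of the machinery and
identifiability under the model's own assumptions, not robustness to
real-data artefacts.

Identifiability, measured by the 20-replicate recovery study at σ = 0.05
(three representative free parameters: adult distress onset, help-seeking
rate, initial capacity): median relative errors are a few percent. Strongly
correlated pairs (e.g. `perceived_need` × `help_seek_rate`, which enter
only as a product) are *not* separately identifiable and should not be
freed together; the shipped default free set keeps both free for
flexibility, so interpret their individual fitted values with caution —
only their product is pinned by the data.

## Key parameters (reference values)

| parameter | value | unit | role |
|---|---|---|---|
| `capacity_2011` / `capacity_slope` | 2.55M / 121k | sessions/yr, /yr² | linear capacity ramp (~3%/yr over 2021–28) |
| `sessions_per_user` | 4.5 | sessions | mean subsidised sessions per episode (cap 10) |
| `intake_sessions` | 1.0 | sessions | assessment workload per admission |
| `treatment_recovery` | 4.0 | /yr | specialist episode completion (≈13 weeks) |
| `gp_recovery` / `gp_return` | 1.2 / 1.8 | /yr | GP-care outcomes (40% success) |
| `gp_referral_fraction` | 0.517 | — | GP-pathway referrals onward to specialists |
| `perceived_need` × `help_seek_rate` | 0.55 × 0.72 | /yr | help-seeking intensity (product identified) |
| `wait_ref` / `wait_cap` | 4 / 104 | weeks | disengagement threshold / wait ceiling |
| `disengage_coeff` | 0.025 | /week | queue-abandonment hazard scale |
| `reengage_rate` / `reengage_seek_rate` | 0.8 / 4.0 | /yr | disengaged returning to `dist` / to the queue (short waits only) |
| `onset_trend` (to 2019) | 0.27 | /yr | secular distress-prevalence rise |
| `seek_trend` (to 2022) | 0.02 | /yr | secular service-uptake rise |

The full set, with units, bounds and provenance labels
(`supplementary`/`calibrated`/`assumed`), is
`src/mhsd/data/reference_parameters.tsv`.

## Design choices made where the design was open

- **Aggregation level.** Two distress levels × six care states × three age
  bands is the coarsest structure that supports every reported output;
  education and employment dynamics are collapsed into exogenous onset
  modifiers (the COVID employment-disruption term) rather than modelled as
  feedback loops.
- **Queue discipline.** None is imposed; waiting time is a throughput delay
  (Little's law) and rationing is proportional. Priority classes or FIFO
  detail would require data that aggregate series cannot identify.
- **Where admissions consume capacity.** Intake competes with treatment for
  the same session pool (one ration factor). The alternative — free
  admissions with capacity applied only to in-care sessions — creates a
  lock-up at exact saturation (zero admissions while in-care demand pins
  capacity) and was rejected for that reason.
- **Conditional re-engagement** (queue re-entry only below the reference
  wait) is the simplest mechanism that distinguishes transient from
  persistent overload; without it, briefly overloading a fast-growing
  system is penalised as heavily as permanently overloading a slow one.
- **Uptake trend saturation in 2022** reflects that the strong secular
  growth in subsidised-service use was a program-expansion-era phenomenon;
  letting it run indefinitely makes *every* future capacity expansion
  self-absorbing, which contradicts the capacity-projection premise.
- **Scenario date defaults.** Levers start 1 Jan 2022; when direct access
  is combined with accelerated growth it starts 1 Jan 2024 (capacity first),
  as does the demand uplift.

## Problem sizes used by the tests and the acceptance script

Full-span runs are 2011.0–2029.0 at weekly steps (937 steps, 21 stocks,
~0.1 s each). The frontier evaluates 6 grid points per growth level. The
noiseless recovery test frees three parameters over an 11-year synthetic
record; the noisy study uses 20 replicates at σ = 0.05 with loosened Powell
tolerances (~10 s per fit). The whole suite runs in about five minutes on
one CPU.

## Known limitations

- Outcome deltas under *direct access alone* are the least-constrained
  quantities in the model: they hinge on the queue-sensitivity parameters
  (`disengage_coeff`, the waiting/disengaged multipliers), which aggregate
  annual series identify only weakly. Relative magnitudes across scenarios
  (and all signs) are robust under the shipped parameterisation; absolute
  percentages for direct-access-alone scenarios should be read as
  order-of-magnitude.
- The model is deterministic; no parametric or stochastic uncertainty is
  propagated. The calibrator reports bound-activity and per-series fit, not
  posterior intervals.
- Provider types are pooled into a single session capacity; out-of-pocket
  costs, workforce composition and geography are out of scope, as is any
  economic analysis of the policies.
- 15–24 pathway parameters are shared with other bands (only onset and
  outcome coefficients are band-specific), so youth-stratum contrasts
  inherit adult pathway behaviour.
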