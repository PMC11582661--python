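# Methods

## The model

`panelmsm` models residency histories in a demographic surveillance area
(DSA) as a continuous-time, time-homogeneous Markov chain on seven states:

| code | state | role |
|---|---|---|
| 1 | Enumeration | baseline census population (entered once, at day 0) |
| 2 | Birth | in-study births |
| 3 | Exit | left a household within the DSA |
| 4 | Entry | joined a household within the DSA |
| 5 | Out-migration | left the DSA (> 180 days away) |
| 6 | In-migration | returned to the DSA (> 180 days present) |
| 7 | Death | absorbing |

Movement is restricted to 14 permitted transitions (1→3, 1→5, 1→7, 2→3,
2→5, 2→7, 3→4, 4→3, 4→5, 4→7, 5→6, 6→3, 6→5, 6→7).  Disallowed transitions
are structural zeros of the generator, never estimated.  For a fixed
covariate vector *z* the intensity of each permitted transition follows a
proportional-intensity model

    q_ij(z) = exp(alpha_ij + z' beta_ij),

with time measured in days, `alpha_ij` the baseline log intensity and
`beta_ij` a transition-specific coefficient vector, so `exp(beta)` is a
hazard ratio for that specific transition.  Covariates are slum area,
ethnicity and area of birth (dummy-coded against the reference levels
Korogocho, Kamba and Nairobi non-slum) plus age in years, uncentred, fixed
at the individual's first observation — nine design columns in total.
Gender is a stratifier: the two strata are always fitted separately, and
gender never enters the design matrix.

## Likelihood

Individuals are observed at a finite set of times (panel observation).  A
consecutive pair (state *a* at *t*, state *b* at *t + dt*) contributes
`P_ab(dt | z) = [expm(dt·Q(z))]_ab`; intermediate jumps are integrated out
by the matrix exponential.  Two refinements:

* **Exact death dates** (default): a DSS records the day of death, so a
  terminal death record contributes `sum_m P_am(dt)·q_m7` — in some live
  state *m* just before the recorded day.  The interval-censored "panel"
  treatment is available as `death_mode="panel"`.
* **Right-censoring**: follow-up simply ends at the last record; censoring
  is assumed non-informative and adds no likelihood term.

The matrix exponential uses scipy's scaling-and-squaring Padé
implementation for single evaluations.  Inside the fitting loop each
individual's generator is eigendecomposed instead (one decomposition serves
every interval of that individual), and the score is computed exactly via
the Daleckii–Krein divided-difference form of the Fréchet derivative of
`expm` — the classic approach for panel multi-state models.  Individuals
whose generator is numerically non-diagonalizable (condition estimate >
1e12) fall back to `expm` / `expm_frechet`.  Divided differences switch to
their confluent limit `t·exp(t·(w_m+w_l)/2)` when two eigenvalues are
within 1e-9.

## Optimization and uncertainty

Maximum likelihood on the unconstrained scale (log intensities, raw
coefficients), by L-BFGS-B with the analytic score.  Numerical choices:

* crude-rate initialization `q0_ij = n_ij / (time observed in i)`, floored
  at 1e-6/day; all coefficients start at 0;
* design columns are rescaled to unit spread internally (the age column is
  O(50) and otherwise wrecks conditioning); results are reported in natural
  units;
* convergence when the relative log-likelihood change falls below 1e-8;
  the optimizer is restarted (curvature memory cleared) until the
  improvement per restart is below tolerance, with a total cap of 2000
  iterations — the 140-parameter covariate model typically needs ~900;
* box bounds (log intensities in [-20, 5], scaled coefficients in
  [-10, 10]) guard against overflow on flat likelihood directions;
* the covariance is the inverse observed information, obtained by central
  finite differences of the analytic score (step 1e-5·max(1,|theta|),
  symmetrized).  If the information is not positive definite the
  covariance is flagged unavailable rather than regularized.

Mean sojourn times are `-1/q_ii(z) = 1/(total exit rate)`; their standard
errors come from the delta method on the log scale and the 95% interval is
exponentiated, so the lower bound is always positive.  Hazard-ratio
intervals are Wald intervals `exp(beta ± 1.959964·se)` (the multiplier is
fixed for bit-reproducibility).  Nested models are compared by AIC and the
likelihood-ratio chi-square; with the full nine-column design against the
baseline-only model the test has 140 − 14 = 126 degrees of freedom.

## Synthetic cohorts

The generator emulates NUHDSS-like surveillance data so that every layer is
testable without restricted microdata:

* **Covariates** are drawn i.i.d. from marginals matching the surveillance
  population (39/61 across slum areas, 45.3% female, the five ethnicity
  shares renormalized, four birth-area shares).  Ages follow a
  piecewise-linear quantile curve through the reported quartiles (10, 22,
  34 years, capped at 80).
* **True parameters** default to magnitudes anchored in the reported
  results: baseline intensity = (destination share among observed
  transitions) / (mean sojourn time of the origin state), per gender, with
  the reported slum-area and per-year age hazard ratios on every
  transition; ethnicity and birth-area effects default to zero.
* **Trajectories** are exact Gillespie realizations (exponential holding
  times, embedded-chain destinations), one pseudo-random stream per
  individual keyed by (seed, index), so generation is reproducible and
  order-independent.
* **Observation records**: states are sampled at scheduled rounds every 180
  days (optional ±30-day jitter); deaths carry their exact day; follow-up
  is right-censored at the horizon (14 years by default).  By default the
  stream also contains one exactly dated record per demographic event
  (`record_events=True`), because a surveillance system dates every
  classified event — this is what makes observed direct transitions land
  exactly on the 14 permitted cells, as in the published transition table.
* **Entry into the cohort**: everyone starts in Enumeration at day 0
  (the 2002-style baseline census) except a configurable fraction (default
  15%) who enter as in-study births at uniform random dates.  A newborn is
  first registered at the next scheduled round, and its fixed age covariate
  is the age at that registration (0–0.5 years).  This mirrors field
  practice and is also what identifies age effects on Birth-state
  transitions — with exact age-0 entry that column would have zero variance
  in the only stratum that informs those rates.

### What the generator does not emulate

Household structure, mother–child linkage, seasonality, time-varying
covariates, and the 180-day residency-classification algorithm (events
arrive pre-classified).  Passing tests therefore demonstrate correctness of
the estimator and pipeline under the stated model, not robustness to the
ways real surveillance data violate it.

## Observation schemes and informative sampling

The panel likelihood assumes observation times are non-informative (fixed
in advance, or at least independent of the process).  Event-dated records
violate this: observing someone *at the moment they change state* carries
extra information the panel likelihood misattributes.  Empirically, fitting
event-dated data drives the fast Exit↔Entry cycle rates towards the
boundary (the likelihood increases indefinitely as both rates grow with
their ratio fixed).  The pipeline therefore fits the model on the
scheduled-rounds discretization of the same simulated trajectories —
deterministically derived from the same seed — while the event-dated stream
feeds the descriptive layers (transition counts, rates).  Users fitting
their own event-dated data should be aware the same caveat applies to any
panel multi-state fit of such records.

Under the scheduled-rounds design the fast Exit state (mean sojourn ~8
days) is only weakly identified: an individual is almost never *seen* in
Exit at a 180-day visit, so the Entry→Exit and Exit→Entry rates carry very
large standard errors, and some covariate effects on those transitions are
near-flat directions of the likelihood.  This is a property of the design,
not a defect of the optimizer; the analogous phenomenon appears in the
published Birth-state sojourn (estimate 680.3 days with standard error
198.8).  Reported standard errors honestly reflect it.

## Rates layer

Person-years of residency accumulate while an individual occupies a
resident state (Enumeration, Birth, Exit, Entry, In-migration);
out-migration closes a residency episode, in-migration reopens it, death
ends follow-up.  Annual event rates are `1000 × count / person-years`
within strata of calendar year, gender, slum area and age group (bins
[0,15), [15,20), [20,36), [36,51), [51,∞), ages evaluated at mid-year).
Day 0 maps to 2002-01-01 by default; events on a year boundary belong to
the later year.  Net migration is the in-migration count minus the
out-migration count over the same denominator — an exact identity
`net = in − out` holds row by row.  A mid-year head-count denominator was
considered and rejected in favour of person-years, consistent with the
person-time basis of the transition model.

## Tables

Composition and transition-count tables report counts with percentages
rounded half-up to one decimal, always recomputed from the emitted counts.
A consecutive same-state pair of records is not a transition; a consecutive
pair outside the 14 permitted cells is an input error (it cannot arise from
event-dated records, only from snapshot-style observation).

## Problem sizes used in checks

Simulation-based checks run at reduced scale chosen for tight feedback
loops: parameter recovery uses a 2,000-individual cohort observed over 20
rounds; interval-coverage uses 200 replicates of 500 individuals over 6
rounds; the acceptance script's end-to-end stage fits both strata of a
2,000-individual cohort.  These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the full suite fast.

## Known limitations

* Time-homogeneous intensities only; no calendar-time or duration effects,
  no piecewise-constant covariates, no frailty.
* Age is fixed at first observation, per the fixed-covariate model; over a
  14-year window this is a coarse approximation for age-sensitive
  transitions (mortality).
* Wald intervals and delta-method standard errors rely on asymptotic
  normality; they are poor for transitions with a handful of events.
* The likelihood treats observation times as non-informative (see above).
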