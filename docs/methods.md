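# Methods

## Model structure

The model is a deterministic Markov cohort model: real-valued expected
person-counts (not individuals) move through six health states — mild AR
[A], moderate/severe AR [B], moderate/severe AR + mild AA [C], severe AR
+ moderate/severe AA [D], healthy [E], death [F] — in one-year cycles.
The state order (A, B, C, D, E, F) is fixed everywhere (arrays, CSV and
YAML files); it is defined once in `scitsim.states`. Death is an explicit
absorbing state, so total persons (including the dead) are conserved by
every cycle; mortality sits inside the transition matrices rather than
being applied as an external attrition factor.

Sub-cohorts are stratified by age group × allergy type × treatment arm.
Arms are symptomatic therapy (ST), an ongoing SCIT course with its
therapy year (1–3), and a post-SCIT arm. The post-SCIT arm exists to
enforce one design rule: a patient completes at most one 3-year course.
After therapy year 3 a cohort keeps its current disease state but follows
ST transition dynamics and ST costs and is never re-enrolled. No
half-cycle correction is applied; occupancies are censused once per year
(after this year's SCIT enrollment, before transitions) and costs accrue
on that census.

## Yearly loop

For each calendar year: (1) incident entrants are added (every year after
the base year); (2) the scenario's supply rate moves eligible ST patients
into SCIT therapy year 1; (3) the census is taken and state costs plus
SCIT drug costs accrue and are discounted; (4) transitions are applied;
(5) SCIT therapy years advance (year-3 completers move to post-SCIT);
(6) cohorts age. Ageing uses a uniform-age approximation: each year 1/7
of children become adolescents, 1/6 of adolescents become adults, and
1/47 of adults leave the population under risk, identically across
states; single-year ages are not carried inside the Markov state space.

## Supply rates and allocation

Supply rates interpolate linearly from their 2011 level to a target level
in a target year and are constant afterwards. The rate is interpreted as
a *flow*: the fraction of the current ST pool in eligible states that
starts a course that year. The alternative *stock* reading — the rate as
a coverage target over everyone eligible, enrolling only the shortfall —
is available via `allocation: stock` in the config. Flow is the default
because rates change yearly and a stock reading would re-treat the same
patients repeatedly, overcounting courses. Allocation conserves persons
exactly for every rate and eligibility set.

## Initial pool, incidence and calibration

The base-year prevalent pool is built from age-group prevalences of AR
(4.7 / 16.9 / 17.95 % for children / adolescents / adults) and AA (3.6 /
5.7 / 3.9 %). AA patients occupy the asthma states C/D; because asthma
patients overwhelmingly also have rhinitis, the AR-only mass placed in
A/B is AR − AA (floored at zero), avoiding double counting. Within-
severity splits (A vs B, C vs D, and the onset split of new cases) are
not reported anywhere, so they are explicit parameters, default 50/50.
New cases enter in the children group, states A/B, arm ST; 60 % of every
cohort is seasonal, 40 % perennial. Sex is not modelled.

Yearly incident totals are calibrated so that, under a zero-uptake
baseline, the diseased total (states A–D) in every year relates to the
base year as the population under risk does — the stated incidence
assumption of the analysis. Calibration is a fixed-point iteration: an
entrant in year *y* adds one diseased person to the year-*y* census, so
each sweep adds the current shortfall to that year's entrant total
(floored at zero). The cross-year coupling is strictly triangular, so the
iteration terminates; the default tolerance is 0.5 % relative with a cap
of 100 sweeps, and a tolerance of zero is rejected as unattainable.

## Costs, discounting and ICERs

State costs per person-year (€, third-party-payer perspective, defaults):
children 27/119/282/446, adolescents 18/97/259/442, adults 8/79/227/442
for A/B/C/D; E and F cost nothing. SCIT drug costs default to the
arithmetic mean of the preseasonal (262/262/262 €) and perennial
(502/480/480 €) schedules — 382 € in year 1, 371 € in years 2–3 —
applied regardless of allergy type; `mean_mode: false` switches to
type-specific charging. Outpatient visits and indirect costs are outside
the payer perspective and excluded. Costs are discounted to the base year
at 2 %/a (PSA range 1.5–2.5 %).

"Healed" is operationalised as occupancy of state E, and scenario
comparisons use the *prevalence* difference (mean annual persons in E)
rather than newly-healed incidence; reported mean-annual figures are
arithmetic means over the 40 model years of *discounted* yearly values
(set `discounted=False` in `compare_to_status_quo` for undiscounted).
The ICER is the mean annual cost difference over the mean annual healed
difference versus the status quo, rounded to integer euro for reporting;
a negative cost difference with a positive health gain is reported as
"dominant", and a non-positive health gain has no defined ratio.

## Synthetic inputs

Two inputs of the original analysis are not public and are generated
synthetically.

*Population projection.* A full 2011–2050 × age 0–100 table whose 6–65
total follows an exact geometric path `base · (1 + trend)^(year−2011)`.
The desk default is 62 million persons under risk declining 0.3 %/a with
a youth-declining profile (ages 0–18 shrink an extra 0.4 %/a before
yearly renormalisation), mimicking the projected German demography in
broad strokes only — no migration, birth-rate or sex structure.

*Transition matrices.* Plausible placeholder dynamics per (age group,
allergy type, arm): from every symptomatic state both progression (one
severity step) and improvement (one step, or remission to E) are
possible, E can relapse to A, and every live row carries a small death
probability (0.03 % children, 0.05 % adolescents, 0.4 % adults per
year). Base yearly remission under ST is 6/4/2/1 % from A/B/C/D (scaled
×1.5 for children, ×1.2 for adolescents, ×0.8 for perennial disease);
progression is 10/6/5 % for A→B/B→C/C→D (×1.1 perennial). SCIT
multiplies remission by (1 + 4·s) and progression by (1 − 0.9·s), where
s ∈ [0, 1] is the effect size (default 0.75, i.e. roughly a four-fold
remission gain during therapy); s = 0 makes SCIT identical to ST. These
values were chosen once as clinically plausible magnitudes — sustained
remission under immunotherapy is far more likely than spontaneous
remission, and younger patients remit more readily — and every generated
matrix is self-checked against the validator and these qualitative
constraints before use.

What passing tests on these inputs do and do not show: they verify the
machinery (conservation, calibration, ordering, dispersion), and they
reproduce the published *qualitative* finding that extending SCIT to
milder states reduces patient numbers most. They do not reproduce the
published absolute figures (e.g. 5.9 M mean annual patients, 541.1 M€
annual cost), and with the default dynamics the cost-*saving* finding for
the C/D-only expansion scenarios does not emerge — the synthetic run
prices those scenarios slightly above the status quo. Both quantities
depend directly on the unpublished transition probabilities and
projection, and no attempt is made to tune the placeholders to hit them.

## Probabilistic sensitivity analysis

Each replicate draws every varied parameter independently and uniformly
from its declared [low, high] range (the defaults bracket the base-case
point values; uniform is the least-informative choice consistent with
printed bounds, and per-parameter distributions can be overridden by
supplying custom ranges). The draw is held constant over the whole run,
the model is fully re-prepared (including incidence re-calibration), and
all scenarios run on the same draw — common random numbers, so scenario
differences are never sampling noise. Transition-matrix perturbation is
available (seeded multiplicative jitter on non-zero off-diagonals,
renormalised through the stay probability) but defaults to off, since
nothing is known about how or whether the original analysis varied them.
The default replicate count is 1,000; the test suite and the acceptance
script use 50 (and the toy fixture 3–12) as scaled-down problem sizes.

## Numerical choices and edge cases

- Matrix validation: rows must sum to 1 within 1e-9, entries in [0, 1],
  row F exactly absorbing; violations name the offending row.
- Counts are floats (expectation semantics); fractional persons are
  intended. Ageing clips sub-1e-12 negative residues from floating-point
  cancellation to zero.
- Determinism: every run is a pure function of (config, seed); output
  files are byte-identical on re-run, and PSA replicate seeds are spawned
  from the master seed so a longer run extends a shorter one exactly.
- Degenerate inputs: empty cohort maps, zero prevalence and zero supply
  are all valid and produce all-zero results rather than errors.

## Known limitations

- The transition probabilities and the projection are synthetic; all
  absolute outputs are placeholders by construction.
- The uniform-age ageing approximation distorts cohort boundaries at the
  group edges; it was preferred over carrying 60 single-year ages in the
  state space.
- Post-SCIT relapse beyond ordinary ST dynamics is not modelled (no
  published relapse model to encode), which likely overstates long-term
  benefit; conversely, benefit only accrues during the 3 therapy years,
  which understates carry-over protection.
- Contraindications (e.g. severe asthma) and repeated courses are not
  modelled.
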