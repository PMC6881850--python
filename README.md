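# scitsim

A population-level Markov cohort model of allergic rhinitis (AR) and
allergic asthma (AA) progression in Germany, 2011–2050, under policy
scenarios for the supply of subcutaneous allergen immunotherapy (SCIT).
The package is written for health economists and epidemiological modellers
who want to run, vary and stress-test budget-impact and
cost-effectiveness estimates of immunotherapy from the perspective of
statutory health insurance.

## The model

Expected person-counts move through six health states in yearly cycles:

| state | meaning |
|-------|---------|
| A | mild AR |
| B | moderate/severe AR |
| C | moderate/severe AR + mild AA |
| D | severe AR + moderate/severe AA |
| E | no symptoms / healthy |
| F | death (absorbing) |

Separate 6×6 row-stochastic transition matrices `P(from → to)` govern each
sub-cohort, stratified by age group (children 6–12, adolescents 13–18,
adults 19–65), allergy type (seasonal 60% / perennial 40%) and treatment
arm (symptomatic therapy ST, or a 3-year SCIT course). One cycle is

```
n_{t+1} = n_t · P
```

which conserves persons exactly. Each year, a scenario-specific supply
rate moves the eligible fraction of ST patients into SCIT therapy year 1;
completed courses return to ST dynamics without re-treatment. The
population under risk (ages 6–65) comes from a projection table; yearly
incident cohorts are calibrated so that without SCIT the diseased total
tracks the demographic trend. Costs are yearly state costs (Table-level
defaults, e.g. adults: 8/79/227/442 € for A/B/C/D) plus SCIT drug costs
(382 € in therapy year 1, 371 € in years 2–3 — the mean of the
preseasonal 262 €/year and perennial 502/480/480 €/year schedules),
discounted to 2011 at 2 %/a. Scenario comparison reports the incremental
cost-effectiveness ratio (ICER)

```
ICER = Δ mean annual cost / Δ mean annual healed patients   [€ per additionally healed patient]
```

versus the status-quo scenario, with "dominant" marking scenarios that
save money while healing more. A probabilistic sensitivity analysis
(PSA) re-runs all scenarios under uniform draws from declared parameter
ranges (1,000 replicates by default) and reports mean ± SD.

Two original inputs were never published: the statistical-office
projection actually used, and the transition probabilities. The package
generates both synthetically (`scitsim.synthetic`), tags them
`provenance: synthetic`, and treats the published absolute outputs only
as qualitative calibration references.

## Worked example

```python
import scitsim as ss

ss.scit_mean_cost(ss.ScitCostSchedule(), 1)   # 382.0  (€, therapy year 1)
ss.icer(98_964_793, 288_213)                  # 343    (€ per additionally healed patient)

config = ss.make_fixture_config("desk", seed=0)   # full 2011-2050 synthetic setup
prepared = ss.prepare(config)                     # generate inputs, calibrate incidence
results = ss.run_scenarios(prepared)              # the five built-in scenarios
table = ss.compare_to_status_quo(results)
print(table.to_string(float_format=lambda x: f"{x:,.0f}"))
```

prints (synthetic inputs, seed 0):

```
            delta_mean_annual_cost  delta_mean_annual_healed  cost_per_additional_healed
scenario
scenario_1               7,408,109                    64,768                         114
scenario_2               8,659,040                   121,369                          71
scenario_3              79,263,885                   724,311                         109
scenario_4             150,003,117                 1,261,927                         119
```

Each row compares a scenario with the status quo: the extra mean annual
cost borne by the payer (€), the extra mean annual number of patients in
the healthy state, and their ratio. Widening SCIT eligibility to milder
states (scenarios 3–4) heals by far the most patients at a few hundred
euro or less per additionally healed patient; with these synthetic
transition dynamics scenarios 1–2 are not cost-saving, which is one of
the quantities that genuinely depends on the unpublished inputs (see
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
scitsim generate --outdir inputs --scale desk   # synthetic projection, matrices, config
scitsim run inputs/config.yaml --outdir results
scitsim psa inputs/config.yaml --n-reps 1000 --seed 1 --outdir results
scitsim icer results/summary.csv
```

## Layout

- `scitsim.states` / `scitsim.markov` — state space, strata, matrix
  validation, cycle propagation
- `scitsim.population` — projection tables, prevalent pool, ageing,
  incidence calibration
- `scitsim.scenarios` — supply schedules, eligibility, SCIT allocation
- `scitsim.economics` — cost accounting, discounting, scenario engine,
  ICERs
- `scitsim.psa` — probabilistic sensitivity analysis
- `scitsim.synthetic` — synthetic projections, transition matrices,
  fixture configs
- `scitsim.config` / `scitsim.pipeline` / `scitsim.cli` — declarative
  configs, orchestration, command line
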