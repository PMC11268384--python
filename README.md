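# nsaidburden

Cohort state-transition models of the patient harm and NHS cost caused by
hazardous oral NSAID prescribing in England.

Oral non-steroidal anti-inflammatory drugs remain widely prescribed to
people at high risk of serious adverse events. This package models five
hazardous prescribing events (HPEs), one per high-risk indicator:

1. an oral NSAID without gastroprotection in an adult aged ≥ 65,
2. an oral NSAID without gastroprotection after peptic ulcer,
3. an oral NSAID alongside an oral anticoagulant,
4. an oral NSAID in heart failure,
5. an oral NSAID in chronic kidney disease (eGFR < 45 mL/min).

For each indicator a pair of cohort Markov models is run over a 10-year
horizon: an **HPE arm** in which the hazardous prescribing continues
(until an adverse event stops it), and a **comparator arm** representing
the counterfactual (NSAID plus gastroprotection for the two
gastrointestinal indicators; paracetamol instead of an NSAID for the
others). Health states carry a utility $u \in [0,1]$ and an annual cost
$c \geq 0$; with occupancy $\pi_k$ at cycle $k$ and cycle length $\Delta$
years, discounted per-person totals are

$$\mathrm{QALY} = \sum_{k=1}^{N} (1+r)^{-k\Delta}\, \pi_k^\top u \,\Delta,
\qquad
\mathrm{Cost} = \sum_{k=1}^{N} (1+r)^{-k\Delta}\, \pi_k^\top c \,\Delta,$$

with $r = 3.5\%$ per annum in the base case. The increment
(HPE arm − comparator arm) gives per-person QALY loss and extra cost.
Probabilistic sensitivity analysis re-evaluates both arms over draws from
beta (probabilities, utilities) and gamma (costs) distributions
moment-matched to each parameter's mean and standard deviation (SD from a
reported SE, from 95% CI bounds as $(\mathrm{hi}-\mathrm{lo})/3.92$, or
20% of the mean when no measure is available). National burden multiplies
indicator prevalence — scaled from an audited sample of 1060 English
practices (10,906,453 patients) to the 63,049,603 GP-registered patients
of England — by the per-person increments, per PSA sample, to get totals
with 95% credibility intervals.

The original input evidence tables are not distributed; the
`synthetic` module generates complete, internally consistent stand-in
parameter tables with recorded ground truth (see `docs/methods.md`).

## Worked example

```python
from nsaidburden import EngineConfig, build_all_models, run_pair
from nsaidburden.synthetic import generate_parameter_tables

pset = generate_parameter_tables(seed=1, preset="paper_magnitude")
models = build_all_models(pset.tables)
for indication, spec in models.items():
    pair = run_pair(spec, EngineConfig())
    print(indication, round(pair.increment.delta_qalys, 4),
          round(pair.increment.delta_cost, 2))
```

prints

```
older_no_gpa -0.0316 164.93
peptic_ulcer_no_gpa -0.0291 126.86
oral_anticoagulant -0.0644 652.16
heart_failure -0.0355 123.86
chronic_kidney_disease -0.023 360.76
```

Each line is one indicator's discounted 10-year per-person increment:
e.g. prescribing an NSAID alongside an oral anticoagulant costs this
synthetic patient cohort 0.064 QALYs and £652 more per person than
switching to paracetamol. The `examples/` directory has one narrative
script per capability: the bare engine, the five deterministic models,
the PSA and cost-effectiveness plane, national burden scaling, and the
sensitivity-analysis scenarios (horizon 5/20 years, undiscounted,
overlap-minimised prevalence, weighted NSAID mix, exposure-duration
sweep).

A thin CLI wraps the same functions:

```sh
nsaid-burden synth params --seed 1 --preset paper_magnitude --out params.csv
nsaid-burden run --params params.csv --out deterministic.csv
nsaid-burden burden --params params.csv --n 10000 --seed 1 --out burden.csv
nsaid-burden report --config run.yaml
```

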