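"""Deterministic per-person harm for the five hazardous-prescribing models.

Generates a synthetic parameter set (the `paper_magnitude` preset keeps
deterministic increments within the published per-person ranges), builds
each indication's HPE/comparator model pair, and prints the discounted
10-year per-person differences.  Negative QALY deltas are harm; positive
cost deltas are extra NHS spend attributable to the hazardous prescribing.
"""

from nsaidburden import EngineConfig, build_all_models, run_pair
from nsaidburden.synthetic import generate_parameter_tables

pset = generate_parameter_tables(seed=1, preset="paper_magnitude")
models = build_all_models(pset.tables)
engine = EngineConfig()  # 10 years, annual cycles, 3.5% discount

print(f"{'indication':28s} {'delta QALYs':>12s} {'delta cost':>11s}")
for indication, spec in models.items():
    pair = run_pair(spec, engine)
    print(
        f"{indication:28s} {pair.increment.delta_qalys:+12.4f} "
        f"£{pair.increment.delta_cost:+10.2f}"
    )
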