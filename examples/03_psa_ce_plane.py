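"""Probabilistic sensitivity analysis and the cost-effectiveness plane.

Draws every parameter from its assigned beta/gamma distribution 1000
times, re-runs both arms of every model per draw, and summarises the
incremental cloud: the share of simulations showing extra cost and QALY
loss, and each indication's mean increment with its 95% credibility
interval (the empirical 2.5th–97.5th percentiles).
"""

from nsaidburden import EngineConfig, build_all_models, ce_plane_summary, run_psa, summarise_psa
from nsaidburden.synthetic import generate_parameter_tables

pset = generate_parameter_tables(seed=1, preset="paper_magnitude")
models = build_all_models(pset.tables)
draws = run_psa(models, n_samples=1000, seed=42, config=EngineConfig())

for indication, s in summarise_psa(draws).items():
    print(
        f"{indication:28s} dQALY {s.delta_qalys.mean:+.4f} "
        f"({s.delta_qalys.lower:+.4f} to {s.delta_qalys.upper:+.4f})  "
        f"dCost £{s.delta_cost.mean:+.0f} "
        f"(£{s.delta_cost.lower:+.0f} to £{s.delta_cost.upper:+.0f})"
    )

dq, dc = draws.pooled_delta()
plane = ce_plane_summary(dq, dc)
print(f"\nsimulations with extra cost: {100 * plane.prop_cost_increase:.2f}%")
print(f"simulations with QALY loss:  {100 * plane.prop_qaly_loss:.2f}%")
print(f"cloud inside fitted 95% ellipse: {100 * plane.fraction_within():.1f}%")
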