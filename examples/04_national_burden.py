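"""Scaling per-person harm to the population of England.

Uses the published indicator prevalence from the audited practice sample
(10.9m registered patients) to estimate national affected counts among
the 63.0m GP-registered patients in England, then multiplies each count
by per-person increments (from a synthetic-parameter PSA) per sample to
get national 10-year totals with credibility intervals.
"""

from nsaidburden import (
    EngineConfig,
    build_all_models,
    national_burden,
    rate_per_1000,
    run_psa,
    scale_to_population,
    share_of_total,
)
from nsaidburden.datasets import england_population, england_prevalence
from nsaidburden.synthetic import generate_parameter_tables

prevalence = england_prevalence()
population = england_population()

counts = {k: scale_to_population(r, population) for k, r in prevalence.items()}
shares = share_of_total(counts)
print("national affected counts (per year):")
for k, nc in counts.items():
    rate = rate_per_1000(prevalence[k])
    print(
        f"  {k:28s} {rate.rate:5.2f}/1000 -> {nc.count:7d} "
        f"({nc.lower}–{nc.upper})  share {shares[k]:4.1f}%"
    )

pset = generate_parameter_tables(seed=1, preset="paper_magnitude")
models = build_all_models(pset.tables)
draws = run_psa(models, n_samples=1000, seed=42, config=EngineConfig())
table = national_burden(counts, draws)
print("\nnational 10-year totals (synthetic parameters):")
print(table.to_frame().to_string(index=False))
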