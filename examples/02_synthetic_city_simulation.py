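"""Simulate a small synthetic city under baseline exposure.

Generates 20 areas of ~1500 residents with a young-urban age pyramid,
runs the annual-cycle simulation for 30 years, and prints the working-age
(15-64) disease prevalence and all-cause mortality per 100,000 with a
5-year running mean.
"""

from microenv import (
    BASELINE,
    RiskConfig,
    SynthConfig,
    aggregate,
    generate_area_profiles,
    generate_rate_tables,
    run_many,
    running_mean,
)

profiles = generate_area_profiles(SynthConfig(n_areas=20, seed=3))
tables = generate_rate_tables(seed=7)
cfg = RiskConfig(reference_mean=10.0)

tallies = run_many(profiles, tables, cfg, BASELINE, horizon_years=30, seed=1)
wa = aggregate(tallies, ("year",), age_filter=(15, 64)).sort_values("year")
prev = running_mean(wa["prevalence_per_100k"], 5)
mort = running_mean(wa["mortality_per_100k"], 5)

print(f"{sum(p.total_population for p in profiles)} simulated residents, "
      f"{len(profiles)} areas, 30 years\n")
print("year  working-age prevalence/100k  working-age mortality/100k  (5y mean)")
for i, year in enumerate(wa["year"]):
    if year % 5 == 0:
        print(f"{year:4d}  {prev[i]:27.1f}  {mort[i]:25.1f}")

print(
    "\nPrevalence drifts upward as the young bulge of the pyramid ages into\n"
    "the high-incidence bands; mortality stays low because deaths are\n"
    "concentrated above working age."
)
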