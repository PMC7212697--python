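"""Counterfactual exposure scenarios against a common baseline.

Runs the base case and the removal of all anthropogenic PM2.5 over the
same synthetic city with common random numbers, averages the paired
deltas over 5 replicate seeds, and prints the working-age prevalence
benefit by sex plus the year-one share of the mortality benefit implied
by the cessation lag.
"""

import pandas as pd

from microenv import (
    BASELINE,
    RiskConfig,
    ScenarioSpec,
    SynthConfig,
    delta_mortality,
    delta_prevalence,
    generate_area_profiles,
    generate_rate_tables,
    run_many,
)

profiles = generate_area_profiles(SynthConfig(n_areas=20, seed=3))
tables = generate_rate_tables(seed=7)
cfg = RiskConfig(reference_mean=10.0)
nolag = RiskConfig(reference_mean=10.0, allcause_lag="none", ihd_lag="none")
noanth = ScenarioSpec(name="noanth", kind="remove_anthropogenic")

dp, lag_pairs = [], []
for seed in range(5):
    base = run_many(profiles, tables, cfg, BASELINE, 30, seed)
    scn = run_many(profiles, tables, cfg, noanth, 30, seed)
    dp.append(delta_prevalence(scn, base, ("year", "sex"), age_filter=(15, 64)))
    base1 = base[base.year == 1]
    scn_nolag = run_many(profiles, tables, nolag, noanth, 1, seed)
    lag_pairs.append((
        delta_mortality(scn[scn.year == 1], base1)["delta_mortality_per_100k"].iloc[0],
        delta_mortality(scn_nolag, base1)["delta_mortality_per_100k"].iloc[0],
    ))

dp = pd.concat(dp).groupby(["year", "sex"])["delta_prevalence_per_100k"].mean().unstack()
late = dp.loc[20:30]
print("Removing anthropogenic PM2.5 (mean of 5 CRN replicates):")
print(f"  working-age prevalence change, years 20-30 mean:")
print(f"    males   {late['male'].mean():8.1f} per 100k")
print(f"    females {late['female'].mean():8.1f} per 100k")
lagged = sum(p[0] for p in lag_pairs) / len(lag_pairs)
nolag_d = sum(p[1] for p in lag_pairs) / len(lag_pairs)
print(f"  year-1 mortality benefit: {lagged:6.1f} per 100k "
      f"({lagged / nolag_d:.0%} of the unlagged {nolag_d:.1f})")

print(
    "\nNegative deltas are benefits. Males gain more because their baseline\n"
    "disease rates are higher; the year-1 share near 30% reflects the\n"
    "programmed cessation lag on the mortality relative risks."
)
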