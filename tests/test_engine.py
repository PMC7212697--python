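"""Annual-cycle engine: initialization, trials, births, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from microenv import (
    BASELINE,
    ScenarioSpec,
    aggregate,
    apply_births,
    initialize_population,
    run_many,
    run_simulation,
)
from microenv.engine import H1, H2, DEAD, area_seed_sequence

from conftest import constant_tables, single_stratum_profile


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestInitialization:
    def test_zero_prevalence_all_healthy(self):
        ts = constant_tables(allcause_mortality=1000)
        cohort = initialize_population(single_stratum_profile(5000), ts, _rng())
        assert np.all(cohort.state == H1)

    def test_certain_prevalence_all_diseased(self):
        ts = constant_tables(prevalence=100000)
        cohort = initialize_population(single_stratum_profile(500, age=62), ts, _rng())
        assert np.all(cohort.state == H2)

    def test_binomial_prevalence_seeding(self):
        # 10,000 males at 10,000/100k: expect ~1000 within 3 sigma = 90
        ts = constant_tables(prevalence=10000)
        cohort = initialize_population(single_stratum_profile(10000, age=60), ts, _rng(3))
        n_h2 = int(np.count_nonzero(cohort.state == H2))
        assert abs(n_h2 - 1000) <= 3 * np.sqrt(10000 * 0.1 * 0.9)

    def test_empty_population_rejected(self, tables):
        with pytest.raises(ValueError, match="empty population"):
            initialize_population(single_stratum_profile(0), tables, _rng())


class TestDynamics:
    def test_zero_rates_nobody_moves(self, neutral_cfg):
        ts = constant_tables()
        profile = single_stratum_profile(2000, age=40)
        out = run_simulation(profile, ts, neutral_cfg, BASELINE, 10, seed=1)
        agg = aggregate(out, ("year",))
        assert (agg["n_deaths_allcause"] == 0).all()
        assert (agg["n_incident"] == 0).all()
        assert (agg["n_alive"] == 2000).all()

    def test_certain_mortality_kills_everyone_in_year_one(self, neutral_cfg):
        ts = constant_tables(allcause_mortality=100000)
        profile = single_stratum_profile(1500, age=40)
        out = aggregate(run_simulation(profile, ts, neutral_cfg, BASELINE, 3, seed=1), ("year",))
        year1 = out[out.year == 1].iloc[0]
        assert year1["n_deaths_allcause"] == year1["n_population"] == 1500
        assert (out[out.year > 1]["n_population"] == 0).all()

    def test_geometric_incidence_accumulation(self, neutral_cfg):
        # P(I|H1) = 0.01, no deaths: prevalent fraction after t years is
        # 1 - 0.99^t; binomial 3-sigma bound at n = 100,000, t = 10
        n, t = 100_000, 10
        ts = constant_tables(incidence=1000)
        profile = single_stratum_profile(n, age=30)
        out = aggregate(run_simulation(profile, ts, neutral_cfg, BASELINE, t, seed=5), ("year",))
        expected = 1 - 0.99 ** t
        prevalent = out[out.year == t]["n_prevalent"].iloc[0]
        assert abs(prevalent - expected * n) <= 3 * np.sqrt(n * expected * (1 - expected))

    def test_aging_advances_each_year(self, neutral_cfg):
        ts = constant_tables()
        profile = single_stratum_profile(100, age=40)
        out = run_simulation(profile, ts, neutral_cfg, BASELINE, 10, seed=1)
        last = out[(out.year == 10) & (out.n_alive > 0)]
        # started in band 40-44; ten years later tallied in 45-49 or 50-54
        assert set(last["age_group"]) <= {"45-49", "50-54"}

    def test_state_sequence_is_h1_h2_dead_prefix(self, tables, risk_cfg):
        from microenv.engine import _step
        from microenv.transitions import transition_table

        profile = single_stratum_profile(3000, age=70, decile=2, pm25=14.0)
        cohort = initialize_population(profile, tables, _rng(2))
        trans = transition_table(2, 14.0, 14.0, 14.0, tables, risk_cfg)
        prev_states = cohort.state.copy()
        dead_sets = [set(np.flatnonzero(cohort.state == DEAD))]
        for year in range(1, 16):
            _step(cohort, trans, year, _rng(100 + year))
            # no resurrection, H2 absorbing until death
            assert np.all(cohort.state[prev_states == DEAD] == DEAD)
            assert np.all(np.isin(cohort.state[prev_states == H2], [H2, DEAD]))
            dead_sets.append(set(np.flatnonzero(cohort.state == DEAD)))
            assert dead_sets[-2] <= dead_sets[-1]
            prev_states = cohort.state.copy()
        died = cohort.state == DEAD
        incident = cohort.year_of_incidence > 0
        both = died & incident
        assert np.all(cohort.year_of_incidence[both] <= cohort.year_of_death[both])


class TestBirths:
    def _female_profile(self, n, gfr):
        return single_stratum_profile(n, age=29, sex="female", gfr=gfr)

    def test_expected_birth_count(self, neutral_cfg):
        ts = constant_tables()
        profile = self._female_profile(1000, gfr=60.0)
        cohort = initialize_population(profile, ts, _rng(1))
        cohort.age += 1  # as at year end
        counts = apply_births(cohort, profile, 1, _rng(7))
        births = counts.sum()
        assert abs(births - 60) <= 3 * np.sqrt(1000 * 0.06 * 0.94)
        assert np.count_nonzero(cohort.age == 0) == births

    def test_zero_gfr_and_no_eligible_females(self, neutral_cfg):
        ts = constant_tables()
        profile = self._female_profile(1000, gfr=0.0)
        cohort = initialize_population(profile, ts, _rng(1))
        assert apply_births(cohort, profile, 1, _rng(2)).sum() == 0
        males = single_stratum_profile(1000, age=30, sex="male", gfr=900.0)
        cohort_m = initialize_population(males, ts, _rng(1))
        assert apply_births(cohort_m, males, 1, _rng(2)).sum() == 0

    def test_invalid_gfr_rejected(self):
        ts = constant_tables()
        profile = self._female_profile(10, gfr=0.0)
        cohort = initialize_population(profile, ts, _rng(1))
        profile.gfr = 1500.0
        with pytest.raises(ValueError):
            apply_births(cohort, profile, 1, _rng(2))

    def test_birth_sex_ratio(self, neutral_cfg):
        ts = constant_tables()
        profile = self._female_profile(20000, gfr=500.0)
        cohort = initialize_population(profile, ts, _rng(1))
        counts = apply_births(cohort, profile, 1, _rng(3))
        frac_male = counts[1] / counts.sum()
        assert abs(frac_male - 0.512) < 3 * np.sqrt(0.512 * 0.488 / counts.sum())


class TestReproducibility:
    def test_identical_seed_identical_tallies(self, tables, risk_cfg, small_profiles):
        a = run_many(small_profiles, tables, risk_cfg, BASELINE, 8, seed=42)
        b = run_many(small_profiles, tables, risk_cfg, BASELINE, 8, seed=42)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_run_order_independence(self, tables, risk_cfg, small_profiles):
        fwd = run_many(small_profiles, tables, risk_cfg, BASELINE, 5, seed=9)
        rev = run_many(list(reversed(small_profiles)), tables, risk_cfg, BASELINE, 5, seed=9)
        fwd = fwd.sort_values(["area_id", "year", "sex", "age_lo"]).reset_index(drop=True)
        rev = rev.sort_values(["area_id", "year", "sex", "age_lo"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_seed_material_distinguishes_areas_and_salt(self):
        base = area_seed_sequence(1, "A00001").entropy
        assert area_seed_sequence(1, "A00002").entropy != base
        assert area_seed_sequence(2, "A00001").entropy != base
        assert area_seed_sequence(1, "A00001", "scn").entropy != base

    def test_conservation_chain(self, tables, risk_cfg, small_profiles):
        out = run_many(small_profiles, tables, risk_cfg, BASELINE, 12, seed=4)
        for _, area in out.groupby("area_id"):
            agg = aggregate(area, ("year",)).sort_values("year")
            alive = agg["n_alive"].to_numpy()
            pop = agg["n_population"].to_numpy()
            assert np.array_equal(
                alive, pop - agg["n_deaths_allcause"].to_numpy() + agg["n_births"].to_numpy()
            )
            assert np.array_equal(pop[1:], alive[:-1])

    def test_tally_count_invariants(self, tables, risk_cfg, small_profiles):
        out = run_many(small_profiles, tables, risk_cfg, BASELINE, 12, seed=4)
        assert (out["n_prevalent"] <= out["n_alive"] + out["n_births"]).all()
        assert (out["n_deaths_allcause"] <= out["n_population"]).all()
        assert (out["n_deaths_disease"] <= out["n_deaths_allcause"]).all()


class TestExposureMonotonicity:
    def test_lower_concentration_fewer_deaths_on_average(self, tables, risk_cfg):
        # common random numbers: average over seeds of total deaths should
        # not increase when exposure falls uniformly
        deaths = {}
        for pm in (16.0, 6.0):
            totals = []
            for seed in range(10):
                profile = single_stratum_profile(3000, age=60, pm25=pm, nonanth=2.0)
                out = run_simulation(profile, tables, risk_cfg, BASELINE, 15, seed=seed)
                totals.append(out["n_deaths_allcause"].sum())
            deaths[pm] = np.mean(totals)
        assert deaths[6.0] < deaths[16.0]
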