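"""Annual-cycle stochastic microsimulation engine.

Each small area is simulated independently: every resident is an
individual with an age, sex and health state (H1 healthy, H2 ever
diagnosed, H3 dead).  At initialisation a subset of the population is
seeded into H2 by Bernoulli draws against the baseline prevalence rates.
Each simulated year then proceeds as sequential Bernoulli trials:

1. every H1 individual faces the incidence trial on P(I | H1); those who
   become incident face the diseased-state mortality trial in the same
   year (the first trial's outcome selects the second trial's
   probability -- switchable via ``incident_rule``);
2. surviving non-incident H1 individuals face the other-cause mortality
   trial on P(M~d | H1); H2 individuals face the single trial on P(M|H2);
3. deaths become H3 and are removed from all later years (no
   resurrection); survivors age by one year; newborns are added at the
   year boundary from the general fertility rate applied to females aged
   15-44.

The cohort is held as a struct-of-arrays (NumPy) rather than per-person
objects, and transition probabilities are tabulated once per area-year
over ages 0..110 x sex, which keeps half-century multi-area runs at
desk scale.  Per-area random streams are derived from
``(master_seed, crc32(area_id))``, so scenario and base runs share common
random numbers by default and per-area runs are embarrassingly parallel.
Migration is assumed zero and baseline rates are held at base-year values
throughout.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import MAX_AGE, SEXES, AreaProfile, RateTableSet, rate_to_probability
from .risk import RiskConfig, effective_concentration
from .scenarios import BASELINE, ScenarioSpec, transform_concentration
from .transitions import TransitionArrays, transition_table

logger = logging.getLogger(__name__)

H1, H2, DEAD = 1, 2, 3

#: 5-year reporting bands 0-4 ... 90-94, 95+
N_BANDS = 20
AGE_BAND_LABELS = [f"{5 * i}-{5 * i + 4}" for i in range(N_BANDS - 1)] + ["95+"]

#: probability that a newborn is male (standard human sex ratio at birth)
P_MALE_BIRTH = 0.512

TALLY_COLUMNS = [
    "year",
    "area_id",
    "imd_decile",
    "sex",
    "age_group",
    "age_lo",
    "n_population",
    "n_incident",
    "n_deaths_allcause",
    "n_deaths_disease",
    "n_prevalent",
    "n_alive",
    "n_births",
]


@dataclass
class Cohort:
    """Struct-of-arrays population of one area.

    ``state`` follows the grammar H1* H2* H3: H2 is absorbing until death
    and H3 is terminal.  ``year_of_incidence``/``year_of_death`` are -1
    when unset (0 marks prevalence at initialisation).
    """

    area_id: str
    age: np.ndarray
    sex: np.ndarray  # 0 = female, 1 = male
    state: np.ndarray
    year_of_incidence: np.ndarray
    year_of_death: np.ndarray

    def __len__(self) -> int:
        return self.age.size

    @property
    def alive(self) -> np.ndarray:
        return self.state != DEAD

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive))


@dataclass
class Exposure:
    """Effective concentrations for the three risk channels in one year."""

    incidence: float
    allcause: float
    case_fatality: float


@dataclass
class AnnualTally:
    """Per-year counts stratified by (sex, 5-year age band at year start)."""

    year: int
    n_population: np.ndarray
    n_incident: np.ndarray
    n_deaths_allcause: np.ndarray
    n_deaths_disease: np.ndarray
    n_prevalent: np.ndarray
    n_alive: np.ndarray
    n_births: np.ndarray

    @classmethod
    def empty(cls, year: int) -> "AnnualTally":
        z = lambda: np.zeros((N_BANDS, 2), dtype=np.int64)  # noqa: E731
        return cls(year, z(), z(), z(), z(), z(), z(), z())


def area_seed_sequence(master_seed: int, area_id: str, salt: str = "") -> np.random.SeedSequence:
    """Deterministic per-area seed material; ``salt`` switches streams for
    independent-seed (non-CRN) scenario runs."""
    entropy = [int(master_seed), zlib.crc32(area_id.encode("utf-8"))]
    if salt:
        entropy.append(zlib.crc32(salt.encode("utf-8")))
    return np.random.SeedSequence(entropy)


def initialize_population(
    profile: AreaProfile, tables: RateTableSet, rng: np.random.Generator
) -> Cohort:
    """Materialise one individual per head and seed baseline prevalence.

    Each individual enters H2 with probability equal to the (unadjusted)
    baseline prevalence rate for their age and sex, else H1.
    """
    counts = profile.population_matrix()
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"{profile.area_id}: empty population table")
    ages_grid, sex_grid = np.nonzero(counts)
    reps = counts[ages_grid, sex_grid]
    age = np.repeat(ages_grid, reps).astype(np.int16)
    sex = np.repeat(sex_grid, reps).astype(np.int8)

    p_prev = np.column_stack(
        [rate_to_probability(tables.expanded("prevalence", s), warn=False) for s in SEXES]
    )
    p = p_prev[np.minimum(age, MAX_AGE), sex]
    prevalent = rng.random(total) < p
    state = np.where(prevalent, H2, H1).astype(np.int8)
    year_of_incidence = np.where(prevalent, 0, -1).astype(np.int16)
    return Cohort(
        area_id=profile.area_id,
        age=age,
        sex=sex,
        state=state,
        year_of_incidence=year_of_incidence,
        year_of_death=np.full(total, -1, dtype=np.int16),
    )


def _band_of(age: np.ndarray) -> np.ndarray:
    return np.minimum(age.astype(np.int64) // 5, N_BANDS - 1)


def _counts(key: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.bincount(key[mask], minlength=N_BANDS * 2).reshape(N_BANDS, 2)


def step_year(
    cohort: Cohort,
    profile: AreaProfile,
    tables: RateTableSet,
    config: RiskConfig,
    exposure: Exposure | float,
    year: int,
    rng: np.random.Generator,
    *,
    incident_rule: str = "diseased",
) -> AnnualTally:
    """Advance the cohort by one simulated year (trials + aging).

    ``exposure`` is either a single effective concentration or an
    :class:`Exposure` giving per-channel lag-adjusted values.  Births are
    applied separately (see :func:`apply_births`).
    """
    if isinstance(exposure, (int, float)):
        exposure = Exposure(float(exposure), float(exposure), float(exposure))
    trans = transition_table(
        profile.imd_decile,
        exposure.incidence,
        exposure.allcause,
        exposure.case_fatality,
        tables,
        config,
    )
    return _step(cohort, trans, year, rng, incident_rule=incident_rule)


def _step(
    cohort: Cohort,
    trans: TransitionArrays,
    year: int,
    rng: np.random.Generator,
    *,
    incident_rule: str = "diseased",
) -> AnnualTally:
    if incident_rule not in ("diseased", "healthy"):
        raise ValueError("incident_rule must be 'diseased' or 'healthy'")
    n = len(cohort)
    # one uniform per individual per trial, drawn for the full roster so
    # that common random numbers stay person-aligned across scenario runs
    u_inc = rng.random(n)
    u_mort = rng.random(n)

    alive = cohort.alive
    age_idx = np.minimum(cohort.age, MAX_AGE).astype(np.int64)
    sex = cohort.sex.astype(np.int64)
    p_inc = trans.p_inc_given_h1[age_idx, sex]
    p_m1 = trans.p_mort_given_h1[age_idx, sex]
    p_m2 = trans.p_mort_given_h2[age_idx, sex]
    # disease-attributable share of the H2 mortality probability
    p_excess = np.maximum(p_m2 - p_m1, 0.0)

    is_h1 = alive & (cohort.state == H1)
    is_h2 = alive & (cohort.state == H2)
    incident = is_h1 & (u_inc < p_inc)

    if incident_rule == "diseased":
        p_death_h1 = np.where(incident, p_m2, p_m1)
        diseased_trial = is_h2 | incident
    else:
        p_death_h1 = p_m1
        diseased_trial = is_h2
    dies = (is_h1 & (u_mort < p_death_h1)) | (is_h2 & (u_mort < p_m2))
    dies_disease = diseased_trial & dies & (u_mort < p_excess)

    band = _band_of(age_idx)
    key = band * 2 + sex

    tally = AnnualTally.empty(year)
    tally.n_population[:] = _counts(key, alive)
    tally.n_incident[:] = _counts(key, incident)
    tally.n_deaths_allcause[:] = _counts(key, dies)
    tally.n_deaths_disease[:] = _counts(key, dies_disease)

    cohort.state[incident] = H2
    cohort.year_of_incidence[incident] = year
    cohort.state[dies] = DEAD
    cohort.year_of_death[dies] = year

    survivors = alive & ~dies
    tally.n_alive[:] = _counts(key, survivors)
    tally.n_prevalent[:] = _counts(key, survivors & (cohort.state == H2))
    cohort.age[survivors] = np.minimum(cohort.age[survivors] + 1, MAX_AGE)
    return tally


def apply_births(
    cohort: Cohort,
    profile: AreaProfile,
    year: int,
    rng: np.random.Generator,
    *,
    p_male: float = P_MALE_BIRTH,
) -> np.ndarray:
    """Add newborns from the general fertility rate; returns per-sex counts.

    Each alive female aged 15-44 at the year end independently bears one
    child with probability gfr/1000.  Newborns enter at age 0 in state H1
    and face no trials until the following year.
    """
    if not 0 <= profile.gfr <= 1000:
        raise ValueError("gfr must lie in [0, 1000]")
    eligible = cohort.alive & (cohort.sex == 0) & (cohort.age >= 15) & (cohort.age <= 44)
    n_eligible = int(np.count_nonzero(eligible))
    births = int(np.count_nonzero(rng.random(n_eligible) < profile.gfr / 1000.0))
    counts = np.zeros(2, dtype=np.int64)
    if births == 0:
        return counts
    newborn_sex = (rng.random(births) < p_male).astype(np.int8)
    counts[0] = int(np.count_nonzero(newborn_sex == 0))
    counts[1] = births - counts[0]
    cohort.age = np.concatenate([cohort.age, np.zeros(births, dtype=np.int16)])
    cohort.sex = np.concatenate([cohort.sex, newborn_sex])
    cohort.state = np.concatenate([cohort.state, np.full(births, H1, dtype=np.int8)])
    cohort.year_of_incidence = np.concatenate(
        [cohort.year_of_incidence, np.full(births, -1, dtype=np.int16)]
    )
    cohort.year_of_death = np.concatenate(
        [cohort.year_of_death, np.full(births, -1, dtype=np.int16)]
    )
    return counts


def run_simulation(
    profile: AreaProfile,
    tables: RateTableSet,
    config: RiskConfig,
    scenario: ScenarioSpec = BASELINE,
    horizon_years: int = 50,
    seed: int = 0,
    *,
    p_male: float = P_MALE_BIRTH,
    incident_rule: str = "diseased",
    rng_mode: str = "common",
) -> pd.DataFrame:
    """Simulate one area for ``horizon_years`` and return its tally table.

    Bitwise reproducible given (profile, seed, scenario).  With
    ``rng_mode="common"`` (the default) the random streams depend only on
    (seed, area), so scenario and base runs are driven by common random
    numbers and their deltas are not dominated by Monte-Carlo noise;
    ``rng_mode="independent"`` salts the stream with the scenario name.
    """
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    if rng_mode not in ("common", "independent"):
        raise ValueError("rng_mode must be 'common' or 'independent'")
    salt = scenario.name if rng_mode == "independent" else ""
    ss = area_seed_sequence(seed, profile.area_id, salt)
    rng_init, rng_trials, rng_births = (np.random.default_rng(s) for s in ss.spawn(3))

    cohort = initialize_population(profile, tables, rng_init)
    x_base = profile.pm25_total
    x_scn = transform_concentration(profile, scenario)
    ac_curve = config.allcause_lag_curve()
    cf_curve = config.ihd_lag_curve()

    table_cache: dict[tuple, TransitionArrays] = {}
    clamp_totals: dict[str, int] = {}
    tallies: list[AnnualTally] = []
    for year in range(1, horizon_years + 1):
        t_since = max(year - scenario.applies_at_year, 0)
        if t_since >= 1:
            x_inc = x_scn
            x_ac = effective_concentration(x_base, x_scn, t_since, ac_curve)
            x_cf = effective_concentration(x_base, x_scn, t_since, cf_curve)
        else:
            x_inc = x_ac = x_cf = x_base
        cache_key = (round(x_inc, 9), round(x_ac, 9), round(x_cf, 9))
        trans = table_cache.get(cache_key)
        if trans is None:
            trans = transition_table(
                profile.imd_decile, x_inc, x_ac, x_cf, tables, config
            )
            table_cache[cache_key] = trans
            for k, v in trans.warnings.items():
                clamp_totals[k] = clamp_totals.get(k, 0) + v
        tally = _step(cohort, trans, year, rng_trials, incident_rule=incident_rule)
        newborns = apply_births(cohort, profile, year, rng_births, p_male=p_male)
        tally.n_births[0, :] += newborns
        tally.n_alive[0, :] += newborns
        tallies.append(tally)
    if clamp_totals:
        logger.warning(
            "%s/%s: clamp/floor events in transition tables: %s",
            profile.area_id, scenario.name, clamp_totals,
        )
    return tallies_to_frame(tallies, profile)


def tallies_to_frame(tallies: list[AnnualTally], profile: AreaProfile) -> pd.DataFrame:
    """Flatten per-year tallies into a long (year, sex, age band) table."""
    n_years = len(tallies)
    rows = n_years * N_BANDS * 2
    years = np.repeat([t.year for t in tallies], N_BANDS * 2)
    band_idx = np.tile(np.repeat(np.arange(N_BANDS), 2), n_years)
    sex_idx = np.tile([0, 1], n_years * N_BANDS)
    data = {
        "year": years,
        "area_id": np.full(rows, profile.area_id, dtype=object),
        "imd_decile": np.full(rows, profile.imd_decile, dtype=np.int64),
        "sex": np.array(SEXES, dtype=object)[sex_idx],
        "age_group": np.array(AGE_BAND_LABELS, dtype=object)[band_idx],
        "age_lo": band_idx * 5,
    }
    for name in (
        "n_population",
        "n_incident",
        "n_deaths_allcause",
        "n_deaths_disease",
        "n_prevalent",
        "n_alive",
        "n_births",
    ):
        data[name] = np.concatenate([getattr(t, name).reshape(-1) for t in tallies])
    return pd.DataFrame(data, columns=TALLY_COLUMNS)


def run_many(
    profiles: list[AreaProfile],
    tables: RateTableSet,
    config: RiskConfig,
    scenario: ScenarioSpec = BASELINE,
    horizon_years: int = 50,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run every area independently and concatenate the tallies.

    Areas share no state, so this loop is embarrassingly parallel; the
    per-area seed derivation makes results independent of run order.
    """
    frames = [
        run_simulation(p, tables, config, scenario, horizon_years, seed, **kwargs)
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)
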