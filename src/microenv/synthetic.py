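"""Synthetic small-area profiles and rate tables.

Emulates the statistical *structure* of the data sources the model is
built for -- census-style single-year age/sex pyramids of ~1500 residents
per area, area deprivation deciles, gridded annual-mean PM2.5 mapped to
areas, general fertility rates, and GBD-style 5-year age-band rates for
disease incidence/prevalence/mortality and all-cause mortality -- so
every downstream module is exercisable without any external download.
It makes no attempt to reproduce real marginals for any particular city,
nor spatial autocorrelation of the pollution field.

The default age pyramid ("young-urban") peaks near age 30 with child and
elderly tails, the qualitative shape of a large-city population.  Rate
tables are built from smooth parametric forms (Gompertz all-cause
mortality; logistic age profiles for disease metrics) with seeded
parameter-level jitter, so the constructed inequalities -- disease
mortality below all-cause mortality, male disease rates at or above
female, monotone adult age gradients -- hold for every seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .rates import AreaProfile, RateTableSet, SEXES

PYRAMID_MODES = ("young-urban", "uniform", "aging")

# (weight, kind, params) mixture components per pyramid mode; ages in years
_PYRAMIDS = {
    # large-city shape: bulk of adults centred near 30, child and elderly tails
    "young-urban": [
        (0.18, "uniform", (0, 14)),
        (0.62, "normal", (30.0, 12.0, 15, 74)),
        (0.20, "normal", (68.0, 12.0, 55, 100)),
    ],
    "uniform": [(1.0, "uniform", (0, 90))],
    "aging": [
        (0.12, "uniform", (0, 14)),
        (0.45, "normal", (45.0, 15.0, 15, 74)),
        (0.43, "normal", (72.0, 10.0, 55, 100)),
    ],
}


class SynthConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SynthConfig:
    """Controls for the synthetic-area generator.

    ``pm25_range`` is the interval (ug/m3) for total annual-mean
    concentration; ``nonanthropogenic_floor`` the minimum natural
    background, which can never exceed the total.
    ``decile_pm25_correlation`` (rho in [-1, 1], Gaussian copula) makes
    more-polluted areas more deprived when positive; the default 0 assigns
    deciles uniformly.
    """

    n_areas: int
    mean_pop_per_area: int = 1500
    age_pyramid_mode: str = "young-urban"
    pm25_range: tuple[float, float] = (8.0, 16.0)
    nonanthropogenic_floor: float = 2.0
    gfr_range: tuple[float, float] = (50.0, 70.0)
    decile_pm25_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_areas < 1:
            raise SynthConfigError("n_areas must be >= 1")
        if self.mean_pop_per_area < 1:
            raise SynthConfigError("mean_pop_per_area must be >= 1")
        if self.age_pyramid_mode not in PYRAMID_MODES:
            raise SynthConfigError(f"age_pyramid_mode must be one of {PYRAMID_MODES}")
        lo, hi = self.pm25_range
        if not 0 <= lo < hi:
            raise SynthConfigError("pm25_range must be a non-empty interval with 0 <= lo < hi")
        if not 0 <= self.nonanthropogenic_floor <= lo:
            raise SynthConfigError("nonanthropogenic_floor must lie in [0, min(pm25_range)]")
        g_lo, g_hi = self.gfr_range
        if not 0 <= g_lo < g_hi <= 1000:
            raise SynthConfigError("gfr_range must be a non-empty interval within [0, 1000]")
        if not -1.0 <= self.decile_pm25_correlation <= 1.0:
            raise SynthConfigError("decile_pm25_correlation must lie in [-1, 1]")


def _sample_ages(n: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    components = _PYRAMIDS[mode]
    weights = np.array([w for w, _, _ in components])
    choice = rng.choice(len(components), size=n, p=weights / weights.sum())
    ages = np.empty(n, dtype=float)
    for i, (_, kind, params) in enumerate(components):
        mask = choice == i
        m = int(mask.sum())
        if m == 0:
            continue
        if kind == "uniform":
            lo, hi = params
            ages[mask] = rng.integers(lo, hi + 1, size=m)
        else:
            # truncated normal via inverse-CDF so no mass piles on the bounds
            mean, sd, lo, hi = params
            u_lo, u_hi = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
            u = rng.uniform(u_lo, u_hi, size=m)
            ages[mask] = mean + sd * ndtri(u)
    return np.clip(np.rint(ages), 0, 100).astype(int)


def generate_area_profiles(config: SynthConfig) -> list[AreaProfile]:
    """Draw ``config.n_areas`` synthetic area profiles (deterministic in seed).

    Each area gets a Poisson-sized population around ``mean_pop_per_area``
    with the configured pyramid shape, an IMD decile, a total PM2.5 in
    ``pm25_range`` with a non-anthropogenic component in
    ``[nonanthropogenic_floor, pm25_total]``, and a fertility rate.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pm25_range
    floor = config.nonanthropogenic_floor
    rho = config.decile_pm25_correlation

    profiles = []
    for i in range(config.n_areas):
        area_id = f"A{i:05d}"
        u_pm = rng.uniform()
        pm_total = round(lo + (hi - lo) * u_pm, 3)
        # natural background varies little between nearby areas
        pm_nonanth = round(
            float(np.clip(rng.normal(floor + 1.0, 0.3), floor, pm_total)), 3
        )
        if rho != 0.0:
            z = rho * ndtri(u_pm) + np.sqrt(1 - rho**2) * rng.standard_normal()
            u_dec = 1.0 - ndtr(z)  # high pollution -> low decile (more deprived)
            decile = int(np.clip(np.floor(u_dec * 10) + 1, 1, 10))
        else:
            decile = int(rng.integers(1, 11))
        gfr = round(rng.uniform(*config.gfr_range), 3)

        n = max(int(rng.poisson(config.mean_pop_per_area)), 1)
        ages = _sample_ages(n, config.age_pyramid_mode, rng)
        sexes = rng.integers(0, 2, size=n)  # 0 female, 1 male
        counts = np.zeros((101, 2), dtype=np.int64)
        np.add.at(counts, (ages, sexes), 1)
        age_idx, sex_idx = np.nonzero(counts)
        population = pd.DataFrame(
            {
                "age": age_idx,
                "sex": np.array(SEXES, dtype=object)[sex_idx],
                "count": counts[age_idx, sex_idx],
            }
        )
        profiles.append(
            AreaProfile(
                area_id=area_id,
                imd_decile=decile,
                pm25_total=pm_total,
                pm25_nonanthropogenic=pm_nonanth,
                gfr=gfr,
                population=population,
            )
        )
    return profiles


def generate_rate_tables(seed: int = 0) -> RateTableSet:
    """GBD-style 5-year-band rate tables for both sexes and all four metrics.

    Construction guarantees, for every seed: all-cause mortality increases
    with age (Gompertz); disease mortality is a sub-fraction of all-cause;
    prevalence and incidence are logistic (non-decreasing) in age; male
    disease rates are at or above female rates.  Rates are per 100,000 per
    year, rounded to 4 decimals so CSV round-trips are exact.
    """
    rng = np.random.default_rng(seed)
    band_lo = np.arange(0, 100, 5)
    mid = band_lo + 2.5
    mid[-1] = 97.5  # open 95+ band

    # parameter-level jitter keeps every constructed inequality intact
    gomp_a = 3.9 * rng.lognormal(0.0, 0.05)
    gomp_b = 0.090 * (1.0 + 0.03 * rng.standard_normal())
    jit = lambda s: float(rng.lognormal(0.0, s))  # noqa: E731

    params = {
        # sex: (allcause multiplier, prevalence max, incidence max, CF fraction max)
        "female": (1.0, 8000.0 * jit(0.05), 800.0 * jit(0.05), 0.12 * jit(0.05)),
    }
    f_all, f_prev, f_inc, f_frac = params["female"]
    params["male"] = (
        f_all * 1.2 * jit(0.03),
        f_prev * (1.4 + 0.1 * rng.uniform()),
        f_inc * (1.4 + 0.1 * rng.uniform()),
        min(f_frac * (1.3 + 0.1 * rng.uniform()), 0.25),
    )

    rows = []
    for sex in SEXES:
        mult, prev_max, inc_max, frac_max = params[sex]
        allcause = gomp_a * mult * np.exp(gomp_b * mid)
        frac = frac_max / (1.0 + np.exp(-(mid - 60.0) / 12.0))
        disease_mort = allcause * frac
        prevalence = prev_max / (1.0 + np.exp(-(mid - 70.0) / 9.0))
        incidence = inc_max / (1.0 + np.exp(-(mid - 65.0) / 10.0))
        series = {
            "allcause_mortality": allcause,
            "disease_mortality": disease_mort,
            "prevalence": prevalence,
            "incidence": incidence,
        }
        for metric, values in series.items():
            for k, lo in enumerate(band_lo):
                rows.append(
                    {
                        "age_lo": int(lo),
                        "age_hi": np.inf if lo == 95 else int(lo + 4),
                        "sex": sex,
                        "metric": metric,
                        "rate_per_100k": round(float(values[k]), 4),
                    }
                )
    return RateTableSet(pd.DataFrame(rows))
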