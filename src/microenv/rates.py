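"""Age-sex rate tables and small-area population profiles.

Baseline epidemiology enters the model as rates per 100,000 population per
year, tabulated by sex and 5-year age band (0-4 ... 95+) for four metrics:

* ``incidence`` -- new diagnoses of the modelled disease,
* ``prevalence`` -- persons living with a diagnosis,
* ``disease_mortality`` -- deaths attributed to the disease,
* ``allcause_mortality`` -- deaths from any cause.

A :class:`RateTableSet` validates a table for complete, non-overlapping
coverage of ages 0-100 and expands it to single years of age (piecewise
constant within a band; the open-ended top band covers every age above its
lower edge).  Area inputs -- deprivation decile, annual-mean PM2.5 (total
and non-anthropogenic), general fertility rate and an age x sex head-count
table -- are carried by :class:`AreaProfile`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRICS = ("incidence", "prevalence", "disease_mortality", "allcause_mortality")
SEXES = ("female", "male")

#: coverage is required for every age in [0, COVERAGE_AGE]
COVERAGE_AGE = 100
#: lookups are defined (via the open top band) up to this age
MAX_AGE = 110

RATE_COLUMNS = ["age_lo", "age_hi", "sex", "metric", "rate_per_100k"]
AREA_COLUMNS = ["area_id", "imd_decile", "pm25_total", "pm25_nonanthropogenic", "gfr"]
POPULATION_COLUMNS = ["area_id", "age", "sex", "count"]


class RateTableError(ValueError):
    """Malformed or incomplete rate table."""


class ProfileError(ValueError):
    """Malformed area profile."""


def rate_to_probability(rate, *, warn: bool = True):
    """Convert an annual rate per 100,000 to an annual probability.

    The conversion is the direct ratio ``rate / 100000`` clamped to 1,
    i.e. the rate is treated as a Bernoulli probability without an
    actuarial ``1 - exp(-r)`` transform; at the magnitudes of the baseline
    tables the difference is negligible.  Accepts scalars or arrays.
    """
    arr = np.asarray(rate, dtype=float)
    if np.any(arr < 0):
        raise ValueError("rate must be non-negative")
    p = arr / 100_000.0
    n_clamped = int(np.count_nonzero(p > 1.0))
    if n_clamped and warn:
        logger.warning("rate_to_probability: clamped %d value(s) above 100000 per 100k", n_clamped)
    p = np.minimum(p, 1.0)
    if np.isscalar(rate) or np.ndim(rate) == 0:
        return float(p)
    return p


@dataclass(frozen=True)
class AgeSexRate:
    """One band of a rate table; ``age_hi = inf`` marks the open top band."""

    age_lo: int
    age_hi: float
    sex: str
    metric: str
    rate_per_100k: float

    @property
    def open_ended(self) -> bool:
        return math.isinf(self.age_hi)


class RateTableSet:
    """Validated set of age-sex rates for all four metrics and both sexes.

    Parameters
    ----------
    frame:
        DataFrame with columns ``age_lo, age_hi, sex, metric, rate_per_100k``.
        ``age_hi`` may be missing/NaN for the open-ended top band.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_rate_frame(frame)
        self._expanded: dict[tuple[str, str], np.ndarray] = {}
        for metric in METRICS:
            for sex in SEXES:
                self._expanded[(metric, sex)] = self._expand(metric, sex)

    # -- construction ------------------------------------------------------

    @classmethod
    def read_csv(cls, path) -> "RateTableSet":
        """Read a ``rates.csv`` file (header required, UTF-8)."""
        frame = pd.read_csv(path, dtype={"sex": str, "metric": str})
        missing = [c for c in RATE_COLUMNS if c not in frame.columns]
        if missing:
            raise RateTableError(f"{path}: missing column(s) {missing}")
        return cls(frame)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def to_csv(self, path) -> None:
        out = self._frame.copy()
        # open top band written with an empty age_hi cell
        out["age_hi"] = out["age_hi"].map(lambda v: "" if math.isinf(v) else int(v))
        out.to_csv(path, index=False)

    def bands(self, metric: str, sex: str) -> list[AgeSexRate]:
        sel = self._frame[(self._frame["metric"] == metric) & (self._frame["sex"] == sex)]
        return [
            AgeSexRate(int(r.age_lo), float(r.age_hi), r.sex, r.metric, float(r.rate_per_100k))
            for r in sel.itertuples()
        ]

    # -- lookup ------------------------------------------------------------

    def _expand(self, metric: str, sex: str) -> np.ndarray:
        out = np.empty(MAX_AGE + 1, dtype=float)
        for band in self.bands(metric, sex):
            hi = MAX_AGE if band.open_ended else min(int(band.age_hi), MAX_AGE)
            out[band.age_lo : hi + 1] = band.rate_per_100k
        return out

    def expanded(self, metric: str, sex: str) -> np.ndarray:
        """Single-year-of-age rate vector over ages 0..110 (read-only view)."""
        arr = self._expanded[(metric, sex)]
        arr.setflags(write=False)
        return arr

    def lookup(self, metric: str, sex: str, age) -> float:
        """Rate per 100k for single-year age(s); ages above the top band
        boundary use the open-ended top band."""
        if metric not in METRICS:
            raise RateTableError(f"unknown metric {metric!r}")
        if sex not in SEXES:
            raise RateTableError(f"unknown sex {sex!r}")
        ages = np.asarray(age)
        if np.any(ages < 0):
            raise ValueError("age must be non-negative")
        idx = np.minimum(ages.astype(int), MAX_AGE)
        out = self._expanded[(metric, sex)][idx]
        if np.ndim(age) == 0:
            return float(out)
        return out


def _validate_rate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATE_COLUMNS if c not in frame.columns]
    if missing:
        raise RateTableError(f"missing column(s) {missing}")
    frame = frame.loc[:, RATE_COLUMNS].copy()
    frame["age_hi"] = pd.to_numeric(frame["age_hi"], errors="coerce").fillna(np.inf)
    frame["age_lo"] = pd.to_numeric(frame["age_lo"], errors="raise")
    frame["rate_per_100k"] = pd.to_numeric(frame["rate_per_100k"], errors="raise")

    bad_rows = []
    for i, row in enumerate(frame.itertuples(), start=2):  # header is line 1
        if row.sex not in SEXES:
            bad_rows.append(f"line {i}: unknown sex {row.sex!r}")
        elif row.metric not in METRICS:
            bad_rows.append(f"line {i}: unknown metric {row.metric!r}")
        elif row.rate_per_100k < 0:
            bad_rows.append(f"line {i}: negative rate {row.rate_per_100k}")
        elif row.age_lo < 0 or row.age_lo > row.age_hi:
            bad_rows.append(f"line {i}: invalid band ({row.age_lo}, {row.age_hi})")
    if bad_rows:
        raise RateTableError("invalid rate rows: " + "; ".join(bad_rows))

    for metric in METRICS:
        for sex in SEXES:
            sel = frame[(frame["metric"] == metric) & (frame["sex"] == sex)]
            if sel.empty:
                raise RateTableError(f"no bands for {sex}/{metric}")
            sel = sel.sort_values("age_lo")
            expected_lo = 0
            for row in sel.itertuples():
                if row.age_lo > expected_lo:
                    raise RateTableError(
                        f"coverage gap for {sex}/{metric}/{expected_lo}"
                    )
                if row.age_lo < expected_lo:
                    raise RateTableError(
                        f"overlapping bands for {sex}/{metric}/{int(row.age_lo)}"
                    )
                expected_lo = int(row.age_hi) + 1 if not math.isinf(row.age_hi) else None
                if expected_lo is None:
                    break
            if expected_lo is not None and expected_lo <= COVERAGE_AGE:
                raise RateTableError(f"coverage gap for {sex}/{metric}/{expected_lo}")
    return frame.sort_values(["metric", "sex", "age_lo"]).reset_index(drop=True)


@dataclass
class AreaProfile:
    """One small area: deprivation, exposure, fertility and head counts.

    ``population`` holds one row per (age, sex) with a non-negative count;
    decile 1 is the most deprived tenth of areas.
    """

    area_id: str
    imd_decile: int
    pm25_total: float
    pm25_nonanthropogenic: float
    gfr: float
    population: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if not 1 <= int(self.imd_decile) <= 10:
            raise ProfileError(f"{self.area_id}: imd_decile must be in 1..10")
        if not 0 <= self.pm25_nonanthropogenic <= self.pm25_total:
            raise ProfileError(
                f"{self.area_id}: need 0 <= pm25_nonanthropogenic <= pm25_total"
            )
        if self.gfr < 0:
            raise ProfileError(f"{self.area_id}: gfr must be non-negative")
        pop = self.population
        missing = [c for c in ("age", "sex", "count") if c not in pop.columns]
        if missing:
            raise ProfileError(f"{self.area_id}: population missing {missing}")
        if (pop["count"] < 0).any():
            raise ProfileError(f"{self.area_id}: negative population count")
        if not pop["sex"].isin(SEXES).all():
            raise ProfileError(f"{self.area_id}: unknown sex label in population")

    def population_matrix(self) -> np.ndarray:
        """Counts as an array of shape (COVERAGE_AGE + 1, 2), sex order
        (female, male); ages above 100 are folded into age 100."""
        out = np.zeros((COVERAGE_AGE + 1, 2), dtype=np.int64)
        ages = np.minimum(self.population["age"].to_numpy(int), COVERAGE_AGE)
        sex_idx = (self.population["sex"] == "male").to_numpy(int)
        np.add.at(out, (ages, sex_idx), self.population["count"].to_numpy(np.int64))
        return out

    @property
    def total_population(self) -> int:
        return int(self.population["count"].sum())


def read_area_profiles(areas_path, population_path) -> list[AreaProfile]:
    """Read ``areas.csv`` + ``population.csv`` into a list of profiles."""
    areas = pd.read_csv(areas_path, dtype={"area_id": str})
    missing = [c for c in AREA_COLUMNS if c not in areas.columns]
    if missing:
        raise ProfileError(f"{areas_path}: missing column(s) {missing}")
    pop = pd.read_csv(population_path, dtype={"area_id": str, "sex": str})
    missing = [c for c in POPULATION_COLUMNS if c not in pop.columns]
    if missing:
        raise ProfileError(f"{population_path}: missing column(s) {missing}")
    grouped = dict(tuple(pop.groupby("area_id")))
    profiles = []
    for row in areas.itertuples():
        sub = grouped.get(row.area_id)
        if sub is None or sub.empty:
            raise ProfileError(f"no population rows for area {row.area_id}")
        profiles.append(
            AreaProfile(
                area_id=row.area_id,
                imd_decile=int(row.imd_decile),
                pm25_total=float(row.pm25_total),
                pm25_nonanthropogenic=float(row.pm25_nonanthropogenic),
                gfr=float(row.gfr),
                population=sub[["age", "sex", "count"]].reset_index(drop=True),
            )
        )
    return profiles


def write_area_profiles(profiles, areas_path, population_path) -> None:
    areas = pd.DataFrame(
        [
            {
                "area_id": p.area_id,
                "imd_decile": p.imd_decile,
                "pm25_total": p.pm25_total,
                "pm25_nonanthropogenic": p.pm25_nonanthropogenic,
                "gfr": p.gfr,
            }
            for p in profiles
        ],
        columns=AREA_COLUMNS,
    )
    areas.to_csv(areas_path, index=False)
    pop = pd.concat(
        [p.population.assign(area_id=p.area_id) for p in profiles], ignore_index=True
    )[POPULATION_COLUMNS]
    pop.to_csv(population_path, index=False)
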