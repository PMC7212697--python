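"""Counterfactual exposure scenarios and scenario-vs-base delta metrics.

A scenario rewrites each area's annual-mean PM2.5 at a fixed simulation
year (instantaneously, year 0 by default) and holds it static thereafter:

* ``baseline``              -- concentrations unchanged;
* ``cap``                   -- concentrations capped at ``cap_value``
  (WHO-guideline style, 10 ug/m3 by default; only binds where exceeded);
* ``uniform_reduction``     -- a fixed decrement everywhere (NECD style,
  e.g. 3.6 ug/m3), floored at the non-anthropogenic component;
* ``remove_anthropogenic``  -- only the non-anthropogenic component remains.

Impacts are reported as differences of proportions between a scenario run
and the base run, scaled per 100,000:

    delta_prevalence = (N_diseased/N_population)_scenario
                     - (N_diseased/N_population)_base
    delta_mortality  = (N_deaths/N_population)_scenario
                     - (N_deaths/N_population)_base

computed on counts aggregated to the requested stratification
(ratio of totals, not an average of per-area deltas), with an optional
working-age (15-64) filter and a centred 5-year running mean for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import AreaProfile

SCENARIO_KINDS = ("baseline", "cap", "uniform_reduction", "remove_anthropogenic")

#: tally columns that aggregate by summation
COUNT_COLUMNS = [
    "n_population",
    "n_incident",
    "n_deaths_allcause",
    "n_deaths_disease",
    "n_prevalent",
    "n_alive",
    "n_births",
]

_GROUP_COLUMN = {
    "year": "year",
    "sex": "sex",
    "age_group": "age_group",
    "imd_decile": "imd_decile",
    "area": "area_id",
    "area_id": "area_id",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Definition of one counterfactual exposure scenario."""

    name: str
    kind: str = "baseline"
    cap_value: float = 10.0
    decrement: float = 0.0
    applies_at_year: int = 0

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"kind must be one of {SCENARIO_KINDS}")
        if self.cap_value <= 0:
            raise ValueError("cap_value must be positive")
        if self.decrement < 0:
            raise ValueError("decrement must be non-negative")
        if self.applies_at_year < 0:
            raise ValueError("applies_at_year must be non-negative")


BASELINE = ScenarioSpec(name="base", kind="baseline")


def transform_concentration(profile: AreaProfile, spec: ScenarioSpec) -> float:
    """Scenario concentration for one area (ug/m3).

    Never returns a value below the area's non-anthropogenic component:
    no policy lever can remove natural background.
    """
    x = profile.pm25_total
    floor = profile.pm25_nonanthropogenic
    if spec.kind == "baseline":
        out = x
    elif spec.kind == "cap":
        out = min(x, spec.cap_value)
    elif spec.kind == "uniform_reduction":
        out = x - spec.decrement
    else:  # remove_anthropogenic
        out = floor
    return float(max(out, floor, 0.0))


def aggregate(
    tallies: pd.DataFrame,
    group_by=("year",),
    age_filter: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Sum tally counts to a stratification and attach rates per 100k.

    ``group_by`` is any subset of {year, sex, age_group, imd_decile, area};
    ``age_filter=(lo, hi)`` keeps only age groups fully inside [lo, hi]
    (e.g. ``(15, 64)`` for the working-age population).  Adds
    ``prevalence_per_100k`` and ``mortality_per_100k`` columns.
    """
    cols = []
    for key in group_by:
        if key not in _GROUP_COLUMN:
            raise KeyError(f"unknown group key {key!r}")
        cols.append(_GROUP_COLUMN[key])
    frame = tallies
    if age_filter is not None:
        lo, hi = age_filter
        keep = (frame["age_lo"] >= lo) & (frame["age_lo"] + 4 <= hi)
        frame = frame[keep]
    if not cols:
        out = frame[COUNT_COLUMNS].sum().to_frame().T
    else:
        out = frame.groupby(cols, as_index=False, observed=True)[COUNT_COLUMNS].sum()
    denom = out["n_population"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["prevalence_per_100k"] = np.where(
            denom > 0, out["n_prevalent"] / denom * 1e5, np.nan
        )
        out["mortality_per_100k"] = np.where(
            denom > 0, out["n_deaths_allcause"] / denom * 1e5, np.nan
        )
    return out


def _delta(
    scenario_tallies: pd.DataFrame,
    base_tallies: pd.DataFrame,
    numerator: str,
    out_name: str,
    group_by=("year",),
    age_filter: tuple[int, int] | None = None,
) -> pd.DataFrame:
    cols = [_GROUP_COLUMN[k] for k in group_by]
    scn = aggregate(scenario_tallies, group_by, age_filter)
    base = aggregate(base_tallies, group_by, age_filter)
    merged = scn.merge(base, on=cols, how="inner", suffixes=("_scn", "_base"))
    d_scn = merged["n_population_scn"].to_numpy(float)
    d_base = merged["n_population_base"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(
            (d_scn > 0) & (d_base > 0),
            (merged[f"{numerator}_scn"] / d_scn - merged[f"{numerator}_base"] / d_base)
            * 1e5,
            np.nan,
        )
    out = merged[cols].copy()
    out[out_name] = delta
    return out


def delta_prevalence(
    scenario_tallies, base_tallies, group_by=("year",), age_filter=None
) -> pd.DataFrame:
    """Per-stratum change in prevalent proportion, scenario minus base,
    per 100,000 (negative = scenario benefit)."""
    return _delta(
        scenario_tallies, base_tallies, "n_prevalent", "delta_prevalence_per_100k",
        group_by, age_filter,
    )


def delta_mortality(
    scenario_tallies, base_tallies, group_by=("year",), age_filter=None
) -> pd.DataFrame:
    """Per-stratum change in all-cause death proportion per 100,000."""
    return _delta(
        scenario_tallies, base_tallies, "n_deaths_allcause", "delta_mortality_per_100k",
        group_by, age_filter,
    )


def compare(
    scenario_tallies, base_tallies, group_by=("year",), age_filter=None, window: int = 1
) -> pd.DataFrame:
    """Scenario-vs-base table with rates and both delta columns.

    With ``window > 1`` the rate and delta columns are smoothed with a
    centred running mean within each non-year stratum.
    """
    cols = [_GROUP_COLUMN[k] for k in group_by]
    scn = aggregate(scenario_tallies, group_by, age_filter)
    base = aggregate(base_tallies, group_by, age_filter)
    merged = scn.merge(base, on=cols, how="inner", suffixes=("_scn", "_base"))
    out = merged[cols].copy()
    out["prevalence_per_100k"] = merged["prevalence_per_100k_scn"]
    out["mortality_per_100k"] = merged["mortality_per_100k_scn"]
    out["delta_prevalence_per_100k"] = (
        merged["prevalence_per_100k_scn"] - merged["prevalence_per_100k_base"]
    )
    out["delta_mortality_per_100k"] = (
        merged["mortality_per_100k_scn"] - merged["mortality_per_100k_base"]
    )
    value_cols = [
        "prevalence_per_100k",
        "mortality_per_100k",
        "delta_prevalence_per_100k",
        "delta_mortality_per_100k",
    ]
    if window > 1 and "year" in group_by:
        others = [c for c in cols if c != "year"]
        out = out.sort_values(cols).reset_index(drop=True)
        if others:
            for col in value_cols:
                out[col] = out.groupby(others, observed=True)[col].transform(
                    lambda s: running_mean(s.to_numpy(), window)
                )
        else:
            for col in value_cols:
                out[col] = running_mean(out[col].to_numpy(), window)
    return out


def running_mean(series, window: int = 5) -> np.ndarray:
    """Centred moving average with the window truncated symmetrically at
    the series edges (the first/last points average fewer years)."""
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("series must be non-empty")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        k = min(half, i, values.size - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return out
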