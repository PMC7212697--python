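"""State-conditional transition probabilities for the three-state model.

The model tracks three health states: H1 (free of diagnosed disease),
H2 (ever diagnosed, absorbing until death) and H3 (dead).  Published
statistics give *population-level* annual probabilities -- incidence P(I),
prevalence P(H2), disease mortality P(M_d) and all-cause mortality P(M_a)
-- whereas the simulation needs the three *state-conditional* ones:

* ``P(I | H1)   = P(I) / (1 - P(H2))`` -- incidence among the undiagnosed;
* ``P(M~d | H1) = P(M_a) - P(M_d)``   -- other-cause mortality, assumed
  equal in the diagnosed and undiagnosed;
* ``P(M | H2)   = P(M_d) / P(H2) + P(M~d)`` -- death from the diseased
  state, using the assumption that disease-specific death is only possible
  from the prevalent state.

Relative risks are applied to the population-level probabilities *before*
the other-cause subtraction, so the exposure multiplier on disease
mortality is not double-counted in the all-cause channel.  Deprivation
multiplies both mortality channels but never incidence.  Adjusted
probabilities that leave [0, 1] are clamped and counted rather than raised:
extreme-but-legal configurations must not abort a long simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rates import MAX_AGE, SEXES, RateTableSet, rate_to_probability
from .risk import RiskConfig, deprivation_rr, pollution_rr

logger = logging.getLogger(__name__)


class DegenerateStratumError(ValueError):
    """Rates for a stratum are mutually inconsistent (e.g. P(H2) = 1)."""


@dataclass(frozen=True)
class PopulationProbabilities:
    """Population-level annual probabilities for one (age, sex) stratum."""

    p_incidence: float
    p_prevalence: float
    p_disease_mortality: float
    p_allcause_mortality: float


@dataclass(frozen=True)
class TransitionProbabilities:
    """The three state-conditional annual probabilities for one stratum."""

    p_inc_given_h1: float
    p_mort_given_h1: float
    p_mort_given_h2: float


def _clamp01(p, warnings: dict | None, key: str):
    n_over = int(np.count_nonzero(np.asarray(p) > 1.0))
    if n_over:
        if warnings is not None:
            warnings[key] = warnings.get(key, 0) + n_over
        else:
            logger.warning("%s: clamped %d probability value(s) above 1", key, n_over)
    return np.minimum(p, 1.0)


def incidence_given_healthy(p_incidence, p_prevalence, warnings: dict | None = None):
    """P(I | H1) = P(I) / (1 - P(H2)), clamped to 1."""
    p_i = np.asarray(p_incidence, dtype=float)
    p_h2 = np.asarray(p_prevalence, dtype=float)
    if np.any((p_h2 < 0) | (p_h2 >= 1)):
        raise DegenerateStratumError("p_prevalence must lie in [0, 1)")
    if np.any(p_i < 0):
        raise ValueError("p_incidence must be non-negative")
    out = _clamp01(p_i / (1.0 - p_h2), warnings, "incidence_given_healthy")
    return float(out) if np.ndim(p_incidence) == 0 and np.ndim(p_prevalence) == 0 else out


def nonihd_mortality(p_allcause_adj, p_disease_mortality_adj, warnings: dict | None = None):
    """Other-cause mortality: max(0, P(M_a) - P(M_d)) on *adjusted* inputs.

    The floor at zero can genuinely bind when the case-fatality RR exceeds
    the all-cause RR at high exposure; floored strata are counted.
    """
    p_a = np.asarray(p_allcause_adj, dtype=float)
    p_d = np.asarray(p_disease_mortality_adj, dtype=float)
    diff = p_a - p_d
    n_floor = int(np.count_nonzero(diff < 0))
    if n_floor:
        if warnings is not None:
            warnings["nonihd_floor"] = warnings.get("nonihd_floor", 0) + n_floor
        else:
            logger.warning(
                "nonihd_mortality: floored %d negative difference(s) at 0", n_floor
            )
    out = np.maximum(diff, 0.0)
    scalar = np.ndim(p_allcause_adj) == 0 and np.ndim(p_disease_mortality_adj) == 0
    return float(out) if scalar else out


def mortality_given_diseased(
    p_disease_mortality_adj, p_prevalence, p_nonihd, warnings: dict | None = None
):
    """P(M | H2) = P(M_d) / P(H2) + P(M~d), clamped to 1."""
    p_d = np.asarray(p_disease_mortality_adj, dtype=float)
    p_h2 = np.asarray(p_prevalence, dtype=float)
    p_n = np.asarray(p_nonihd, dtype=float)
    if np.any((p_h2 == 0) & (p_d > 0)):
        raise DegenerateStratumError(
            "nonzero disease mortality with zero prevalence in a stratum"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        excess = np.where(p_h2 > 0, p_d / np.where(p_h2 > 0, p_h2, 1.0), 0.0)
    out = _clamp01(excess + p_n, warnings, "mortality_given_diseased")
    scalar = all(np.ndim(a) == 0 for a in (p_disease_mortality_adj, p_prevalence, p_nonihd))
    return float(out) if scalar else out


@dataclass
class TransitionArrays:
    """Transition probabilities tabulated over ages 0..110 x (female, male).

    Produced once per (area, year); individuals then index into the arrays
    by (age, sex).  ``warnings`` counts clamp/floor events.
    """

    p_inc_given_h1: np.ndarray
    p_mort_given_h1: np.ndarray
    p_mort_given_h2: np.ndarray
    warnings: dict = field(default_factory=dict)


def transition_table(
    decile: int,
    x_incidence: float,
    x_allcause: float,
    x_case_fatality: float,
    tables: RateTableSet,
    config: RiskConfig,
) -> TransitionArrays:
    """Build the full age x sex transition table for one area-year.

    The three concentrations are the (possibly lag-adjusted) effective
    exposures for the incidence, all-cause-mortality and case-fatality
    channels; in a baseline run all three equal the area concentration.
    """
    mu = config.reference_mean
    rr_inc = pollution_rr(config.rr_incidence_per10, x_incidence, mu)
    rr_cf = pollution_rr(config.rr_case_fatality_per10, x_case_fatality, mu)
    rr_ac = pollution_rr(config.rr_allcause_per10, x_allcause, mu)

    n_ages = MAX_AGE + 1
    warnings: dict = {}
    p_inc = np.empty((n_ages, 2))
    p_m1 = np.empty((n_ages, 2))
    p_m2 = np.empty((n_ages, 2))
    for s, sex in enumerate(SEXES):
        depr = deprivation_rr(sex, decile, config)
        p_i = rate_to_probability(tables.expanded("incidence", sex), warn=False)
        p_h2 = rate_to_probability(tables.expanded("prevalence", sex), warn=False)
        p_md = rate_to_probability(tables.expanded("disease_mortality", sex), warn=False)
        p_ma = rate_to_probability(tables.expanded("allcause_mortality", sex), warn=False)

        p_i_adj = _clamp01(p_i * rr_inc, warnings, "incidence_adjust")
        p_md_adj = _clamp01(p_md * rr_cf * depr, warnings, "disease_mortality_adjust")
        p_ma_adj = _clamp01(p_ma * rr_ac * depr, warnings, "allcause_adjust")

        p_non = nonihd_mortality(p_ma_adj, p_md_adj, warnings)
        p_inc[:, s] = incidence_given_healthy(p_i_adj, p_h2, warnings)
        p_m1[:, s] = p_non
        p_m2[:, s] = mortality_given_diseased(p_md_adj, p_h2, p_non, warnings)
    return TransitionArrays(p_inc, p_m1, p_m2, warnings)


def assemble(
    age: int,
    sex: str,
    decile: int,
    concentration: float,
    tables: RateTableSet,
    config: RiskConfig,
    *,
    x_allcause: float | None = None,
    x_case_fatality: float | None = None,
) -> TransitionProbabilities:
    """Transition probabilities for a single (age, sex, area) stratum.

    ``concentration`` drives the incidence channel; the two mortality
    channels default to the same value but may be given separately when a
    cessation lag makes their effective concentrations differ.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if age < 0:
        raise ValueError("age must be non-negative")
    table = transition_table(
        decile,
        concentration,
        concentration if x_allcause is None else x_allcause,
        concentration if x_case_fatality is None else x_case_fatality,
        tables,
        config,
    )
    if table.warnings:
        # counts cover the whole tabulated age range, not just this stratum
        logger.debug("assemble: clamp/floor events %s", table.warnings)
    a = min(int(age), MAX_AGE)
    s = SEXES.index(sex)
    return TransitionProbabilities(
        p_inc_given_h1=float(table.p_inc_given_h1[a, s]),
        p_mort_given_h1=float(table.p_mort_given_h1[a, s]),
        p_mort_given_h2=float(table.p_mort_given_h2[a, s]),
    )
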