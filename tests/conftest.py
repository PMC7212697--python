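import math

import numpy as np
import pandas as pd
import pytest

from microenv import AreaProfile, RateTableSet, RiskConfig, SynthConfig
from microenv import generate_area_profiles, generate_rate_tables

BAND_LOS = list(range(0, 100, 5))


def constant_rate_frame(incidence=0.0, prevalence=0.0, disease_mortality=0.0,
                        allcause_mortality=0.0):
    """Rate table with the same rate in every band -- transition
    probabilities then stay constant as individuals age."""
    rows = []
    values = {
        "incidence": incidence,
        "prevalence": prevalence,
        "disease_mortality": disease_mortality,
        "allcause_mortality": allcause_mortality,
    }
    for sex in ("female", "male"):
        for metric, rate in values.items():
            for lo in BAND_LOS:
                rows.append({
                    "age_lo": lo,
                    "age_hi": math.inf if lo == 95 else lo + 4,
                    "sex": sex,
                    "metric": metric,
                    "rate_per_100k": rate,
                })
    return pd.DataFrame(rows)


def constant_tables(**kwargs) -> RateTableSet:
    return RateTableSet(constant_rate_frame(**kwargs))


def single_stratum_profile(n, age=60, sex="male", area_id="TEST", decile=5,
                           pm25=10.0, nonanth=2.0, gfr=0.0) -> AreaProfile:
    return AreaProfile(
        area_id=area_id,
        imd_decile=decile,
        pm25_total=pm25,
        pm25_nonanthropogenic=nonanth,
        gfr=gfr,
        population=pd.DataFrame({"age": [age], "sex": [sex], "count": [n]}),
    )


@pytest.fixture(scope="session")
def risk_cfg():
    """Reference configuration: mu = 10 ug/m3, published default RRs."""
    return RiskConfig(reference_mean=10.0)


@pytest.fixture(scope="session")
def neutral_cfg():
    """All risk channels switched off (every multiplier is 1 at x = mu)."""
    return RiskConfig(reference_mean=10.0, rr_incidence_per10=1.0,
                      rr_case_fatality_per10=1.0, rr_allcause_per10=1.0,
                      depr_ratio_male=1.0, depr_ratio_female=1.0)


@pytest.fixture(scope="session")
def tables():
    return generate_rate_tables(seed=7)


@pytest.fixture(scope="session")
def small_profiles():
    return generate_area_profiles(SynthConfig(n_areas=5, seed=11))
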