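"""Relative-risk multipliers and cessation-lag curves.

Two risk channels modify the baseline transition probabilities:

* **Deprivation.** Area-level mortality risk scales with the Index of
  Multiple Deprivation decile ``j`` (1 = most deprived) as
  ``ratio ** ((5.5 - j) / 9)``, where ``ratio`` is the most-/least-deprived
  mortality ratio (1.7 for men, 1.5 for women by default).  The exponent is
  centred on the population-average decile 5.5, so the multiplier is > 1 in
  deprived areas, < 1 in affluent ones, and the decile-1 : decile-10 ratio
  equals ``ratio`` exactly.  Deprivation is applied to mortality only, not
  to disease incidence.

* **PM2.5 exposure.** A published relative risk per 10 ug/m3 is rescaled to
  the area concentration ``x`` relative to the population-weighted national
  mean ``mu``: ``RR(x) = RR_per10 ** ((x - mu) / 10)``.

When a scenario lowers concentrations, the mortality benefit accrues
gradually (a *cessation lag*).  The lag is expressed as a cumulative
fraction ``f(t)`` of the asymptotic benefit realised ``t`` years after the
change, and is applied by interpolating the concentration itself,
``x_eff(t) = x_base - f(t) * (x_base - x_scenario)`` -- under the power-law
RR this is exactly log-linear interpolation of the relative risk.
Concentration *increases* take effect immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import SEXES

#: population-average IMD decile about which the deprivation RR is centred
MEAN_DECILE = 5.5
#: span of deciles used to normalise the deprivation exponent
DECILE_SPAN = 9.0

LAG_KINDS = ("epa_smooth", "exponential", "none")

# EPA-recommended tranche structure: 30% of the benefit in year 1, 50%
# spread over years 2-5, 20% over years 6-20; realised as uniform annual
# increments, i.e. piecewise-linear in continuous time.
_EPA_KNOTS_T = np.array([0.0, 1.0, 5.0, 20.0])
_EPA_KNOTS_F = np.array([0.0, 0.30, 0.80, 1.0])


@dataclass
class RiskConfig:
    """Relative-risk and lag parameters.

    Parameters
    ----------
    reference_mean:
        Population-weighted mean PM2.5 concentration ``mu`` (ug/m3) at
        which every exposure RR equals 1.  There is no sensible universal
        default, so it must be supplied.
    rr_incidence_per10, rr_case_fatality_per10, rr_allcause_per10:
        Relative risks per 10 ug/m3 PM2.5 for disease incidence, case
        fatality among the diagnosed, and all-cause mortality.
    depr_ratio_male, depr_ratio_female:
        Mortality ratio between the most and least deprived deciles.
    ihd_lag_tau:
        Time constant (years) of the exponential disease-mortality lag.
    allcause_lag, ihd_lag:
        Lag-curve kinds for the all-cause and disease mortality channels.
    """

    reference_mean: float
    rr_incidence_per10: float = 1.08
    rr_case_fatality_per10: float = 1.21
    rr_allcause_per10: float = 1.06
    depr_ratio_male: float = 1.7
    depr_ratio_female: float = 1.5
    ihd_lag_tau: float = 5.0
    allcause_lag: str = "epa_smooth"
    ihd_lag: str = "exponential"

    def __post_init__(self):
        for name in (
            "rr_incidence_per10",
            "rr_case_fatality_per10",
            "rr_allcause_per10",
            "depr_ratio_male",
            "depr_ratio_female",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reference_mean < 0:
            raise ValueError("reference_mean must be non-negative")
        if self.ihd_lag_tau <= 0:
            raise ValueError("ihd_lag_tau must be positive")
        for name in ("allcause_lag", "ihd_lag"):
            if getattr(self, name) not in LAG_KINDS:
                raise ValueError(f"{name} must be one of {LAG_KINDS}")

    def depr_ratio(self, sex: str) -> float:
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        return self.depr_ratio_male if sex == "male" else self.depr_ratio_female

    def allcause_lag_curve(self) -> "LagCurve":
        return LagCurve(self.allcause_lag, tau=self.ihd_lag_tau)

    def ihd_lag_curve(self) -> "LagCurve":
        return LagCurve(self.ihd_lag, tau=self.ihd_lag_tau)


def deprivation_rr(sex: str, decile: int, config: RiskConfig) -> float:
    """Deprivation mortality multiplier for an area of IMD decile ``decile``."""
    if not 1 <= decile <= 10:
        raise ValueError("decile must be in 1..10")
    ratio = config.depr_ratio(sex)
    return float(ratio ** ((MEAN_DECILE - decile) / DECILE_SPAN))


def pollution_rr(base_rr_per10: float, concentration, reference: float):
    """Exposure relative risk at concentration ``x`` relative to ``mu``.

    ``RR = base_rr_per10 ** ((x - mu) / 10)``; equals 1 at ``x == mu`` and
    is monotone increasing in ``x`` when ``base_rr_per10 > 1``.
    """
    if base_rr_per10 <= 0:
        raise ValueError("base_rr_per10 must be positive")
    x = np.asarray(concentration, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    out = base_rr_per10 ** ((x - reference) / 10.0)
    if np.ndim(concentration) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class LagCurve:
    """Cumulative benefit fraction f(t) after an exposure reduction.

    ``epa_smooth`` follows the 30/50/20 tranche structure; ``exponential``
    is ``1 - exp(-t / tau)``; ``none`` applies the full benefit from the
    first year.  Every curve satisfies f(0) = 0, f non-decreasing,
    f(t) -> 1.
    """

    kind: str
    tau: float = 5.0

    def __post_init__(self):
        if self.kind not in LAG_KINDS:
            raise ValueError(f"kind must be one of {LAG_KINDS}")
        if self.kind == "exponential" and self.tau <= 0:
            raise ValueError("tau must be positive")

    def __call__(self, t):
        return lag_fraction(self, t)


def lag_fraction(curve: LagCurve, t):
    """Evaluate the cumulative lag fraction at ``t`` years since the change."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    if curve.kind == "epa_smooth":
        out = np.interp(arr, _EPA_KNOTS_T, _EPA_KNOTS_F)
    elif curve.kind == "exponential":
        out = 1.0 - np.exp(-arr / curve.tau)
    else:  # none: instantaneous from the first year
        out = np.where(arr >= 1.0, 1.0, 0.0)
    if np.ndim(t) == 0:
        return float(out)
    return out


def effective_concentration(x_base: float, x_scenario: float, t, curve: LagCurve):
    """Lag-adjusted concentration ``t`` years after an intervention.

    Reductions accrue as ``x_base - f(t) * (x_base - x_scenario)``;
    increases (or no change) take effect from the first year without lag.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    if x_scenario >= x_base:
        out = np.where(arr >= 1.0, float(x_scenario), float(x_base))
    else:
        out = x_base - lag_fraction(curve, arr) * (x_base - x_scenario)
    if np.ndim(t) == 0:
        return float(out)
    return out
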