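"""Recovery-assay analysis: survival fractions, critical time, logistic fit.

Plants waterlogged for increasing durations are drained and scored for
survival.  The critical time t_c is the longest duration at which the
majority of plants can still be rescued: survival fractions are projected to
a non-increasing sequence (isotonic regression, weighted by plants treated)
when sampling noise makes them non-monotone, then t_c is the largest grid
duration whose smoothed fraction is at or above the majority threshold.

A parametric summary is available via a binomial logistic fit
survived ~ Binomial(n, 1 / (1 + exp((d - t50) / s))), estimated as a GLM in
(intercept, duration) and mapped back to (t50, s) with delta-method standard
errors.  Symptom percentages reproduce the leaf-scoring table arithmetic
(rounded half-up to one decimal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "SurvivalSchedule",
    "CriticalTime",
    "critical_time",
    "fit_logistic_survival",
    "symptom_percentages",
    "LogisticSurvivalCurve",
]


@dataclass
class SurvivalSchedule:
    """Plants treated / surviving per waterlogging duration."""

    duration_h: np.ndarray
    n_treated: np.ndarray
    n_survived: np.ndarray

    def __post_init__(self) -> None:
        self.duration_h = np.asarray(self.duration_h, dtype=float)
        self.n_treated = np.asarray(self.n_treated, dtype=int)
        self.n_survived = np.asarray(self.n_survived, dtype=int)
        if len(self.duration_h) == 0:
            raise ValueError("schedule is empty")
        if len(set(self.duration_h)) != len(self.duration_h):
            raise ValueError("durations must be unique")
        if np.any(np.diff(self.duration_h) <= 0):
            order = np.argsort(self.duration_h)
            self.duration_h = self.duration_h[order]
            self.n_treated = self.n_treated[order]
            self.n_survived = self.n_survived[order]
        if np.any(self.n_treated <= 0):
            raise ValueError("n_treated must be positive")
        if np.any(self.n_survived < 0) or np.any(self.n_survived > self.n_treated):
            raise ValueError("must satisfy 0 <= n_survived <= n_treated")

    @property
    def fraction(self) -> np.ndarray:
        return self.n_survived / self.n_treated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "duration_h": self.duration_h,
                "n_treated": self.n_treated,
                "n_survived": self.n_survived,
            }
        )


@dataclass
class CriticalTime:
    t_c: float
    majority: float
    smoothed: bool
    fractions: np.ndarray
    warning: bool = False
    t50_h: float | None = None
    slope_h: float | None = None


def isotonic_nonincreasing(fractions, weights=None) -> np.ndarray:
    """Weighted least-squares projection onto non-increasing sequences."""
    fractions = np.asarray(fractions, dtype=float)
    x = np.arange(len(fractions))
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(x, fractions, sample_weight=weights)


def critical_time(schedule: SurvivalSchedule, majority: float = 0.5) -> CriticalTime:
    """Largest duration at which the (smoothed) survival fraction >= majority."""
    if len(schedule.duration_h) < 2 or schedule.duration_h[0] != 0:
        raise ValueError("schedule needs >= 2 durations including 0 h")
    frac = schedule.fraction
    monotone = bool(np.all(np.diff(frac) <= 0))
    smoothed_frac = frac if monotone else isotonic_nonincreasing(
        frac, weights=schedule.n_treated
    )
    above = smoothed_frac >= majority
    if not above.any():
        warnings.warn(
            "no duration retains a majority of survivors; t_c set to 0",
            stacklevel=2,
        )
        return CriticalTime(
            t_c=0.0,
            majority=majority,
            smoothed=not monotone,
            fractions=smoothed_frac,
            warning=True,
        )
    t_c = float(schedule.duration_h[np.flatnonzero(above).max()])
    if t_c == 0.0:
        warnings.warn(
            "majority of plants lost by the first nonzero duration",
            stacklevel=2,
        )
    return CriticalTime(
        t_c=t_c,
        majority=majority,
        smoothed=not monotone,
        fractions=smoothed_frac,
        warning=t_c == 0.0,
    )


def _separation_fit(schedule: SurvivalSchedule):
    """Boundary fit under complete separation: a step at the gap midpoint."""
    frac = schedule.fraction
    alive = np.flatnonzero(frac == 1.0)
    dead = np.flatnonzero(frac == 0.0)
    last_alive = schedule.duration_h[alive.max()] if alive.size else schedule.duration_h[0]
    first_dead = schedule.duration_h[dead.min()] if dead.size else schedule.duration_h[-1]
    t50 = float((last_alive + first_dead) / 2.0)
    return t50, 0.0


def fit_logistic_survival(schedule: SurvivalSchedule):
    """Binomial MLE of the logistic survival-vs-duration curve.

    Returns ``(t50_h, slope_h, se_t50, se_slope, separated)``.  Survival
    probability is p(d) = 1 / (1 + exp((d - t50) / s)); under complete
    separation (fractions all 0 or 1 with a clean split) the boundary fit is
    returned with ``slope_h = 0`` (an infinitely steep step) and NaN SEs.
    """
    if len(schedule.duration_h) < 3:
        raise ValueError("logistic fit needs >= 3 durations")
    frac = schedule.fraction
    if not ((frac > 0).any() and (frac < 1).any()):
        raise ValueError("schedule needs both survivors and deaths somewhere")
    if np.all((frac == 0.0) | (frac == 1.0)):
        t50, slope = _separation_fit(schedule)
        return t50, slope, float("nan"), float("nan"), True

    endog = np.column_stack(
        [schedule.n_survived, schedule.n_treated - schedule.n_survived]
    )
    exog = sm.add_constant(schedule.duration_h)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit()
    b0, b1 = fit.params
    if b1 >= 0 or not np.isfinite(b1):
        # survival not decreasing in duration: no usable midpoint
        t50, slope = _separation_fit(schedule)
        return t50, slope, float("nan"), float("nan"), True
    # logit p = b0 + b1 d  <=>  p = 1/(1+exp((d - t50)/s)),
    # t50 = -b0/b1, s = -1/b1; SEs by the delta method
    t50 = -b0 / b1
    slope = -1.0 / b1
    cov = np.asarray(fit.cov_params())
    grad_t50 = np.array([-1.0 / b1, b0 / b1**2])
    grad_s = np.array([0.0, 1.0 / b1**2])
    se_t50 = float(np.sqrt(grad_t50 @ cov @ grad_t50))
    se_slope = float(np.sqrt(grad_s @ cov @ grad_s))
    return float(t50), float(slope), se_t50, se_slope, False


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def symptom_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage of symptomatic leaves per time, rounded half-up to 1 decimal.

    ``counts`` has columns ``time_h, n_symptomatic, n_total``.
    """
    required = {"time_h", "n_symptomatic", "n_total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"symptom table missing columns: {sorted(missing)}")
    if (counts["n_total"] <= 0).any():
        bad = counts.loc[counts["n_total"] <= 0, "time_h"].tolist()
        raise ValueError(f"zero leaf totals at times {bad}: percentage undefined")
    if (counts["n_symptomatic"] > counts["n_total"]).any():
        raise ValueError("symptomatic count exceeds total")
    out = counts.copy()
    out["percent"] = [
        round_half_up(100.0 * s / t, 1)
        for s, t in zip(out["n_symptomatic"], out["n_total"])
    ]
    return out


class LogisticSurvivalCurve(BaseEstimator):
    """Logistic survival-vs-duration model with majority-rule critical time.

    Attributes (after :meth:`fit`)
    ------------------------------
    t50_h_, slope_h_ : float
        Duration of 50% survival and logistic scale (hours).
    se_t50_h_, se_slope_h_ : float
        Delta-method standard errors (NaN under separation).
    separated_ : bool
        True when the schedule shows complete separation.
    critical_time_ : CriticalTime
        Grid-valued majority-rule critical time.
    """

    def __init__(self, majority: float = 0.5):
        self.majority = majority

    def fit(self, schedule: SurvivalSchedule, y=None):
        self.critical_time_ = critical_time(schedule, majority=self.majority)
        (
            self.t50_h_,
            self.slope_h_,
            self.se_t50_h_,
            self.se_slope_h_,
            self.separated_,
        ) = fit_logistic_survival(schedule)
        return self

    def predict_proba(self, duration_h) -> np.ndarray:
        d = np.asarray(duration_h, dtype=float)
        if self.slope_h_ == 0.0:
            return (d < self.t50_h_).astype(float) + 0.5 * (d == self.t50_h_)
        return 1.0 / (1.0 + np.exp((d - self.t50_h_) / self.slope_h_))
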