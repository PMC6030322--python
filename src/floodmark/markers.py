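"""Sharp-signal detection, marker designation and damage prediction.

The damage-severity markers are genes whose expression breaks abruptly just
after the critical waterlogging duration t_c: an up-trending gene that
collapses, or a slowly declining gene that suddenly drops.  Such a break is
a *sharp signal*: the largest adjacent log2 step of the series, accepted
when its magnitude reaches ``theta`` log2 units and stands out against the
rest of the series (``contrast`` = |step| over the median |other step|).

Marker designation aligns sharp signals to the critical time: a candidate
gene becomes a marker when its sharp signal lands inside the alarm window
(t_c, t_c + window] and its pre-signal behaviour is consistent (elevated or
rising through t_c for up-markers; slowly declining — less than one log2
unit in total — for down-markers).  Candidacy is screened on the series
restricted to t <= t_c, because the post-critical collapse itself breaks
full-series monotonicity for exactly the genes the rule is after.

Prediction on a new panel re-detects sharp signals per marker gene and fires
an alarm when direction and window match the trained rule; at least ``m``
fired alarms declare the plant irrecoverable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .qpcr import ExpressionSeries
from .trend import TrendCall, classify_trend

__all__ = [
    "SharpSignal",
    "Marker",
    "MarkerRule",
    "DamageCall",
    "sharp_signal",
    "select_markers",
    "predict_damage",
    "DamageMarkerModel",
]


@dataclass
class SharpSignal:
    gene_id: str
    t_star: float  # hour of the step's right endpoint
    delta_log2: float  # signed log2 change over the step
    direction: str  # increase | decrease
    contrast: float
    pre_trend: str  # up | down | flat


@dataclass
class Marker:
    gene_id: str
    alarm_direction: str
    window: tuple[float, float]  # alarm interval (t_c, t_c + window]


@dataclass
class MarkerRule:
    t_c: float
    window_h: float
    min_alarms: int
    markers: list[Marker] = field(default_factory=list)
    theta: float = 1.0
    contrast_min: float = 2.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "t_c": self.t_c,
                "window": self.window_h,
                "m": self.min_alarms,
                "theta": self.theta,
                "contrast_min": self.contrast_min,
                "markers": [asdict(m) for m in self.markers],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MarkerRule":
        d = json.loads(text)
        markers = [
            Marker(
                gene_id=m["gene_id"],
                alarm_direction=m["alarm_direction"],
                window=tuple(m["window"]),
            )
            for m in d["markers"]
        ]
        return cls(
            t_c=d["t_c"],
            window_h=d["window"],
            min_alarms=d["m"],
            markers=markers,
            theta=d.get("theta", 1.0),
            contrast_min=d.get("contrast_min", 2.0),
        )


@dataclass
class DamageCall:
    verdict: str  # recoverable | irrecoverable | indeterminate
    alarms_fired: list[str]
    evaluated: list[str]
    not_evaluable: list[str]


def _pre_trend(series: ExpressionSeries, t_star: float) -> str:
    """Monotone direction of the series restricted to times < t_star."""
    keep = series.times_h < t_star
    rel = series.rel[keep]
    if len(rel) < 2:
        return "flat"
    amplitude = abs(np.log2(rel.max() / rel.min()))
    if amplitude < 1.0:
        return "flat"
    return "up" if rel[-1] >= rel[0] else "down"


def sharp_signal(
    series: ExpressionSeries, theta: float = 1.0, contrast_min: float = 2.0
) -> SharpSignal | None:
    """Locate the series' largest adjacent log2 step; return it if sharp.

    A signal is returned iff |delta_log2| >= theta and the step's contrast
    against the median |log2 step| of the rest of the series reaches
    ``contrast_min`` (a uniformly steep geometric series has contrast 1 and
    never alarms).
    """
    if len(series) < 4:
        raise ValueError("sharp-signal detection needs >= 4 time points")
    if np.any(series.rel <= 0):
        raise ValueError("relative expression must be positive")
    log2_steps = np.diff(np.log2(series.rel))
    idx = int(np.argmax(np.abs(log2_steps)))
    delta = float(log2_steps[idx])
    others = np.abs(np.delete(log2_steps, idx))
    med = float(np.median(others))
    contrast = float("inf") if med == 0 else abs(delta) / med
    if abs(delta) < theta or contrast < contrast_min:
        return None
    t_star = float(series.times_h[idx + 1])
    return SharpSignal(
        gene_id=series.gene_id,
        t_star=t_star,
        delta_log2=delta,
        direction="increase" if delta > 0 else "decrease",
        contrast=contrast,
        pre_trend=_pre_trend(series, t_star),
    )


def _is_candidate(
    series: ExpressionSeries,
    t_c: float,
    trend_call: TrendCall | None,
    a_min: float = 1.0,
) -> bool:
    """Marker candidacy: continual (non-saturating) through t_c, or a slow decliner.

    The trend is judged on the pre-critical restriction of the series when it
    has >= 4 points there (falling back to the full-series call otherwise).
    A slow decliner loses less than ``a_min`` log2 units in total up to t_c.
    """
    pre = series.restrict(t_c)
    call = None
    if len(pre) >= 4:
        call = classify_trend(pre, a_min=a_min)
    elif trend_call is not None:
        call = trend_call
    if call is not None and call.continual and not call.saturating:
        return True
    if len(pre) >= 2:
        total = float(np.log2(pre.rel[-1] / pre.rel[0]))
        if -a_min < total <= 0:
            return True
    return False


def select_markers(
    panel: Mapping[str, ExpressionSeries],
    t_c: float,
    window_h: float = 48.0,
    min_alarms: int = 2,
    theta: float = 1.0,
    contrast_min: float = 2.0,
    trend_calls: Mapping[str, TrendCall] | None = None,
) -> MarkerRule:
    """Designate marker genes whose sharp signal falls just past t_c.

    ``trend_calls`` (e.g. from a prior panel screen) are used for candidacy
    when the pre-critical restriction of a series is too short to classify.
    """
    rule = MarkerRule(
        t_c=t_c,
        window_h=window_h,
        min_alarms=min_alarms,
        theta=theta,
        contrast_min=contrast_min,
    )
    if window_h <= 0:
        warnings.warn("empty alarm window: no markers selectable", stacklevel=2)
        return rule
    for gene, series in panel.items():
        call = trend_calls.get(gene) if trend_calls else None
        if not _is_candidate(series, t_c, call):
            continue
        sig = sharp_signal(series, theta=theta, contrast_min=contrast_min)
        if sig is None:
            continue
        if not (t_c < sig.t_star <= t_c + window_h):
            continue
        if sig.pre_trend == "up":
            consistent = True
        else:
            # down-marker: require a slow pre-critical decline
            pre = series.restrict(t_c)
            total = float(np.log2(pre.rel[-1] / pre.rel[0])) if len(pre) >= 2 else 0.0
            consistent = -1.0 < total <= 0.0
        if not consistent:
            continue
        rule.markers.append(
            Marker(
                gene_id=gene,
                alarm_direction=sig.direction,
                window=(t_c, t_c + window_h),
            )
        )
    if not rule.markers:
        warnings.warn("no marker genes selected", stacklevel=2)
    return rule


def predict_damage(
    panel: Mapping[str, ExpressionSeries], rule: MarkerRule
) -> DamageCall:
    """Apply a trained marker rule to a new panel of series.

    Each marker's alarm fires iff a sharp signal with the trained direction
    lands inside the alarm window.  Verdict: irrecoverable when at least
    ``min_alarms`` fire, recoverable when none fire, indeterminate otherwise.
    """
    if not rule.markers:
        raise ValueError("marker rule is empty")
    lo, hi = rule.t_c, rule.t_c + rule.window_h
    fired, evaluated, missing = [], [], []
    for marker in rule.markers:
        series = panel.get(marker.gene_id)
        if series is None:
            missing.append(marker.gene_id)
            continue
        if series.times_h.max() <= lo:
            raise ValueError(
                f"panel for {marker.gene_id!r} does not cover the alarm window "
                f"({lo}, {hi}] h"
            )
        evaluated.append(marker.gene_id)
        sig = sharp_signal(series, theta=rule.theta, contrast_min=rule.contrast_min)
        if sig is None:
            continue
        if sig.direction == marker.alarm_direction and lo < sig.t_star <= hi:
            fired.append(marker.gene_id)
    if not evaluated:
        raise ValueError("no marker gene is present in the panel")
    if len(fired) >= rule.min_alarms:
        verdict = "irrecoverable"
    elif not fired:
        verdict = "recoverable"
    else:
        verdict = "indeterminate"
    return DamageCall(
        verdict=verdict,
        alarms_fired=fired,
        evaluated=evaluated,
        not_evaluable=missing,
    )


class DamageMarkerModel(BaseEstimator):
    """Fit a marker rule on a training panel; predict damage on new panels.

    Parameters mirror :func:`select_markers`.  After :meth:`fit`, ``rule_``
    holds the :class:`MarkerRule` and ``markers_`` the selected genes.
    """

    def __init__(
        self,
        window_h: float = 48.0,
        min_alarms: int = 2,
        theta: float = 1.0,
        contrast_min: float = 2.0,
    ):
        self.window_h = window_h
        self.min_alarms = min_alarms
        self.theta = theta
        self.contrast_min = contrast_min

    def fit(
        self,
        panel: Mapping[str, ExpressionSeries],
        t_c: float,
        trend_calls: Mapping[str, TrendCall] | None = None,
    ):
        self.rule_ = select_markers(
            panel,
            t_c,
            window_h=self.window_h,
            min_alarms=self.min_alarms,
            theta=self.theta,
            contrast_min=self.contrast_min,
            trend_calls=trend_calls,
        )
        self.markers_ = [m.gene_id for m in self.rule_.markers]
        return self

    def predict(self, panel: Mapping[str, ExpressionSeries]) -> DamageCall:
        return predict_damage(panel, self.rule_)
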