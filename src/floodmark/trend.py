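"""Monotone-trend screening of expression time courses.

A gene's course is "continual" when it rises or falls monotonically across
the whole treatment window.  Monotonicity is scored Mann-Kendall style:
S = sum over ordered pairs i < j of sign(rel_j - rel_i), normalized to
tau = S / (T(T-1)/2) in [-1, 1] (ties contribute 0).  A continual call
additionally requires an overall swing of at least ``a_min`` log2 units and
no noise-significant step against the trend, where an adjacent step counts
as noise-significant when |rel_{t+1} - rel_t| > z_adj * sqrt(se_t^2 +
se_{t+1}^2).

Fast-saturating monotone profiles — ones that collapse to a floor within the
first couple of points and are indistinguishable across later treatment
times — are flagged and excluded from marker candidacy: they pass
monotonicity but carry no information about stress duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .qpcr import ExpressionSeries

__all__ = [
    "TrendCall",
    "classify_trend",
    "discriminability",
    "screen_panel",
    "TrendClassifier",
]

CONTINUAL_CLASSES = ("continual_up", "continual_down")


@dataclass
class TrendCall:
    gene_id: str
    trend: str  # continual_up | continual_down | non_continual | flat
    s_stat: int
    tau: float
    amplitude_log2: float
    n_discriminable: int
    saturating: bool

    @property
    def continual(self) -> bool:
        return self.trend in CONTINUAL_CLASSES


def _pairwise_s(rel: np.ndarray) -> int:
    diffs = rel[None, :] - rel[:, None]
    return int(np.sign(diffs[np.triu_indices(len(rel), k=1)]).sum())


def _significant_steps(rel: np.ndarray, se: np.ndarray, z_adj: float) -> np.ndarray:
    steps = np.diff(rel)
    noise = z_adj * np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
    return np.abs(steps) > noise


def discriminability(
    series: ExpressionSeries, z_adj: float = 2.0, k_sat: int = 2
) -> tuple[int, bool]:
    """Count noise-significant adjacent steps; flag fast-saturating profiles.

    ``saturating`` is True when the series is monotone within noise (no
    significant step against its dominant direction) yet every adjacent pair
    from point ``k_sat`` onward is indistinguishable from noise.
    """
    rel, se = series.rel, series.se
    sig = _significant_steps(rel, se, z_adj)
    steps = np.diff(rel)
    n_discriminable = int(sig.sum())
    direction = np.sign(_pairwise_s(rel))
    if direction == 0:
        return n_discriminable, False
    against = sig & (np.sign(steps) == -direction)
    monotone = not against.any()
    tail_flat = not sig[k_sat:].any() if len(sig) > k_sat else True
    saturating = bool(monotone and tail_flat and sig[:k_sat].any())
    return n_discriminable, saturating


def classify_trend(
    series: ExpressionSeries,
    tau_min: float = 0.8,
    a_min: float = 1.0,
    z_adj: float = 2.0,
    k_sat: int = 2,
) -> TrendCall:
    """Classify one time course as continual up/down, flat or non-continual."""
    if len(series) < 4:
        raise ValueError(
            f"trend classification needs >= 4 time points, got {len(series)}"
        )
    rel, se = series.rel, series.se
    n = len(rel)
    s = _pairwise_s(rel)
    tau = s / (n * (n - 1) / 2)
    amplitude = float(np.abs(np.log2(rel.max() / rel.min())))
    n_disc, saturating = discriminability(series, z_adj=z_adj, k_sat=k_sat)

    sig = _significant_steps(rel, se, z_adj)
    steps = np.diff(rel)
    sig_decrease = bool((sig & (steps < 0)).any())
    sig_increase = bool((sig & (steps > 0)).any())

    if amplitude < a_min:
        trend = "flat"
    elif tau >= tau_min and not sig_decrease:
        trend = "continual_up"
    elif tau <= -tau_min and not sig_increase:
        trend = "continual_down"
    else:
        trend = "non_continual"

    return TrendCall(
        gene_id=series.gene_id,
        trend=trend,
        s_stat=s,
        tau=float(tau),
        amplitude_log2=amplitude,
        n_discriminable=n_disc,
        saturating=saturating,
    )


def screen_panel(
    panel: Mapping[str, ExpressionSeries] | Iterable[ExpressionSeries],
    tau_min: float = 0.8,
    a_min: float = 1.0,
    z_adj: float = 2.0,
    k_sat: int = 2,
) -> tuple[list[TrendCall], dict[str, int]]:
    """Screen every series in a panel; saturating genes leave the continual classes.

    Returns the per-gene calls and a tally per final class.
    """
    if isinstance(panel, Mapping):
        series_list = list(panel.values())
    else:
        series_list = list(panel)
    if not series_list:
        raise ValueError("panel is empty")
    calls = []
    for series in series_list:
        call = classify_trend(series, tau_min, a_min, z_adj, k_sat)
        if call.saturating and call.continual:
            call.trend = "non_continual"
        calls.append(call)
    tallies = {
        "continual_up": 0,
        "continual_down": 0,
        "non_continual": 0,
        "flat": 0,
    }
    for call in calls:
        tallies[call.trend] += 1
    return calls, tallies


def calls_to_frame(calls: Iterable[TrendCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "trend": [c.trend for c in calls],
            "tau": [c.tau for c in calls],
            "amplitude_log2": [c.amplitude_log2 for c in calls],
            "n_discriminable": [c.n_discriminable for c in calls],
            "saturating": [c.saturating for c in calls],
        }
    )


class TrendClassifier(BaseEstimator):
    """Panel-level monotone-trend screen.

    ``predict`` maps a panel (dict or list of ExpressionSeries) to a list of
    :class:`TrendCall`; ``tallies_`` holds the per-class counts of the last
    screen.
    """

    def __init__(
        self,
        tau_min: float = 0.8,
        a_min: float = 1.0,
        z_adj: float = 2.0,
        k_sat: int = 2,
    ):
        self.tau_min = tau_min
        self.a_min = a_min
        self.z_adj = z_adj
        self.k_sat = k_sat

    def fit(self, panel=None, y=None):
        return self

    def predict(self, panel) -> list[TrendCall]:
        calls, tallies = screen_panel(
            panel,
            tau_min=self.tau_min,
            a_min=self.a_min,
            z_adj=self.z_adj,
            k_sat=self.k_sat,
        )
        self.tallies_ = tallies
        return calls
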