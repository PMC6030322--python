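"""qPCR quantification: standard curves, 2^-ddCt and time-course assembly.

A Ct panel is a long-format table with columns
``gene_id, condition, time_h, replicate, ct_target, ct_reference``.
Relative expression is computed per replicate as 2^-ddCt, where
dCt = Ct_target - Ct_reference and ddCt subtracts the mean dCt of the
calibrator sample (by default the treated sample at 0 h, so every series
starts at 1 and trends read as change under stress).  Replicates are
aggregated as mean with the standard error of the replicate 2^-ddCt values.

The standard-curve path (Ct regressed on log10 input copies) reports the
amplification efficiency E = 10^(-1/slope) - 1; the ddCt path assumes 100%
efficiency (base 2), as the quantification formula states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "StandardCurve",
    "ExpressionSeries",
    "fit_standard_curve",
    "relative_expression",
    "build_series",
    "DeltaDeltaCt",
]

CT_COLUMNS = [
    "gene_id",
    "condition",
    "time_h",
    "replicate",
    "ct_target",
    "ct_reference",
]


@dataclass
class StandardCurve:
    """Least-squares line of Ct on log10(input copies)."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 == 100% (doubling per cycle)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies(self, ct) -> np.ndarray:
        """Invert the curve: estimated input copies for observed Ct."""
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


@dataclass
class ExpressionSeries:
    """Per-gene relative-expression time course (mean +/- SE per point)."""

    gene_id: str
    times_h: np.ndarray
    rel: np.ndarray
    se: np.ndarray
    n_reps: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.rel = np.asarray(self.rel, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.n_reps is None:
            self.n_reps = np.ones_like(self.times_h, dtype=int)
        self.n_reps = np.asarray(self.n_reps, dtype=int)
        if not (len(self.times_h) == len(self.rel) == len(self.se)):
            raise ValueError("times, rel and se must have equal length")
        if np.any(self.rel <= 0):
            raise ValueError("relative expression must be positive")
        order = np.argsort(self.times_h)
        self.times_h = self.times_h[order]
        self.rel = self.rel[order]
        self.se = self.se[order]
        self.n_reps = self.n_reps[order]

    def __len__(self) -> int:
        return len(self.times_h)

    def restrict(self, max_time_h: float) -> "ExpressionSeries":
        """Sub-series with times <= ``max_time_h``."""
        keep = self.times_h <= max_time_h
        return ExpressionSeries(
            self.gene_id,
            self.times_h[keep],
            self.rel[keep],
            self.se[keep],
            self.n_reps[keep],
        )


def fit_standard_curve(copies, ct) -> StandardCurve:
    """Fit Ct = slope * log10(copies) + intercept over a dilution series."""
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.size < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("input copies must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("dilution series has zero variance in copies")
    res = stats.linregress(x, ct)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def _check_panel(panel: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"Ct panel missing columns: {sorted(missing)}")


def relative_expression(
    panel: pd.DataFrame,
    gene: str,
    calibrator_condition: str = "CT",
    calibrator_time_h: float = 0.0,
) -> pd.DataFrame:
    """Per-sample 2^-ddCt values for one gene.

    Returns a frame with one row per (condition, time_h) carrying the
    replicate-mean relative expression, its SE across replicate 2^-ddCt
    values, and the replicate count.
    """
    _check_panel(panel)
    rows = panel[panel["gene_id"] == gene]
    if rows.empty:
        raise KeyError(f"gene {gene!r} absent from Ct panel")
    if rows[["ct_target", "ct_reference"]].isna().any().any():
        bad = rows[rows[["ct_target", "ct_reference"]].isna().any(axis=1)]
        raise ValueError(
            f"missing target/reference Ct for gene {gene!r} in samples: "
            f"{bad[['condition', 'time_h', 'replicate']].to_dict('records')}"
        )
    rows = rows.copy()
    rows["dct"] = rows["ct_target"] - rows["ct_reference"]
    cal = rows[
        (rows["condition"] == calibrator_condition)
        & (rows["time_h"] == calibrator_time_h)
    ]
    if cal.empty:
        raise ValueError(
            f"calibrator sample ({calibrator_condition}, {calibrator_time_h} h) "
            f"missing for gene {gene!r}"
        )
    cal_dct = cal["dct"].mean()
    rows["rel"] = 2.0 ** -(rows["dct"] - cal_dct)
    out = (
        rows.groupby(["condition", "time_h"])["rel"]
        .agg(rel="mean", se="sem", n="size")
        .reset_index()
    )
    out["se"] = out["se"].fillna(0.0)
    return out


def build_series(
    panel: pd.DataFrame,
    gene: str,
    condition: str = "CT",
    calibrator_condition: str = "CT",
    calibrator_time_h: float = 0.0,
) -> ExpressionSeries:
    """Assemble one condition's time course for ``gene`` as an ExpressionSeries."""
    per_sample = relative_expression(
        panel, gene, calibrator_condition, calibrator_time_h
    )
    sub = per_sample[per_sample["condition"] == condition].sort_values("time_h")
    if len(sub) < 3:
        raise ValueError(
            f"gene {gene!r} covers only {len(sub)} time points in {condition}"
        )
    return ExpressionSeries(
        gene_id=gene,
        times_h=sub["time_h"].to_numpy(),
        rel=sub["rel"].to_numpy(),
        se=sub["se"].to_numpy(),
        n_reps=sub["n"].to_numpy(),
    )


class DeltaDeltaCt(BaseEstimator):
    """2^-ddCt transformer for a long-format Ct panel.

    ``transform`` maps a Ct panel to a dict of gene_id -> ExpressionSeries
    for the chosen condition, calibrated to the configured sample.

    Parameters
    ----------
    condition : str
        Condition whose time course is assembled (default treated, "CT").
    calibrator_condition, calibrator_time_h
        Sample whose mean dCt anchors ddCt = 0 (default CT at 0 h).
    """

    def __init__(
        self,
        condition: str = "CT",
        calibrator_condition: str = "CT",
        calibrator_time_h: float = 0.0,
    ):
        self.condition = condition
        self.calibrator_condition = calibrator_condition
        self.calibrator_time_h = calibrator_time_h

    def fit(self, panel: pd.DataFrame, y=None):
        _check_panel(panel)
        return self

    def transform(self, panel: pd.DataFrame) -> dict[str, ExpressionSeries]:
        _check_panel(panel)
        return {
            gene: build_series(
                panel,
                gene,
                condition=self.condition,
                calibrator_condition=self.calibrator_condition,
                calibrator_time_h=self.calibrator_time_h,
            )
            for gene in pd.unique(panel["gene_id"])
        }

    def fit_transform(self, panel: pd.DataFrame, y=None):
        return self.fit(panel).transform(panel)
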