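"""Synthetic datasets with the statistical structure the analysis assumes.

Every generator is driven by a :class:`~floodmark.config.SimConfig` and is
deterministic given its seed (each generator uses its own substream, so the
call order never matters).

* ``simulate_counts`` — two composite RNA-seq libraries.  Because each
  condition is a single pooled sample, counts are Poisson draws around
  library_size x gene_proportion (the random-sampling model the DE test
  assumes), with a planted fraction of genes whose treated proportion is
  scaled by 2^(+-effect).  An expected-counts mode (counts = rounded
  expectations) supports exact round-trip tests.
* ``simulate_qpcr_panel`` — latent log2 expression curves, piecewise-linear
  on the time grid per trend class, read out as Ct values: target
  Ct(t) = C0 - log2 x(t) + noise against a constant-Ct reference gene,
  three technical replicates, a control condition with x(t) = 1.
* ``simulate_recovery`` — binomial survivor counts around a logistic
  survival-vs-duration curve.
* ``simulate_symptoms`` — binomial symptomatic-leaf counts with a
  nondecreasing symptom probability.
* ``simulate_marker_scenario`` — a fixed qPCR panel reproducing the marker
  shapes (rise-then-collapse at 72 h, rise-then-collapse at 96 h, slow
  decline then sharp drop at 72 h, plus non-marker profiles), in a
  "collapsed" (irrecoverably damaged) or "rescued" variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig, ConfigError, DEFAULT_RECOVERY_GRID
from .degcall import CountTable
from .recovery import SurvivalSchedule

__all__ = [
    "simulate_counts",
    "simulate_qpcr_panel",
    "simulate_recovery",
    "simulate_symptoms",
    "simulate_marker_scenario",
    "simulate_dilution_series",
    "MARKER_SHAPES_COLLAPSED",
    "MARKER_SHAPES_RESCUED",
]

# substream tags so each generator has an independent, reproducible stream
_STREAM_COUNTS = 1
_STREAM_QPCR = 2
_STREAM_RECOVERY = 3
_STREAM_SYMPTOMS = 4
_STREAM_SCENARIO = 5
_STREAM_DILUTION = 6

#: Table-style symptom probabilities on the 7-point morphology grid
#: (fraction of leaves turning yellow and curly under sustained stress)
DEFAULT_SYMPTOM_CURVE = (0.0, 0.077, 0.192, 0.481, 0.577, 0.731, 0.962)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def simulate_counts(
    config: SimConfig, expected: bool = False
) -> tuple[CountTable, pd.DataFrame]:
    """Two-library count table with planted differential expression.

    Returns the table and a truth frame (``gene_id, is_de, log2fc_planted,
    log2fc_realized``; effects are treated-over-control, and the realized
    column accounts for renormalizing the treated proportions to sum 1).
    With ``expected=True`` counts are set to rounded expectations instead of
    Poisson draws.
    """
    config.validate()
    rng = _rng(config, _STREAM_COUNTS)
    n = config.n_genes

    # baseline abundances: log-normal over proportions, normalized per library
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    p_ck = base / base.sum()

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    mean_fc, sd_fc = config.effect_log2fc
    magnitude = np.clip(rng.normal(mean_fc, sd_fc, size=n_de), 0.25, None)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    planted = np.zeros(n)
    planted[de_idx] = sign * magnitude

    p_ct = p_ck * 2.0**planted
    norm = p_ct.sum()
    p_ct = p_ct / norm
    # renormalizing to proportions shifts every realized effect by -log2(norm)
    realized = planted - np.log2(norm)

    mu_ck = config.lib_size_ck * p_ck
    mu_ct = config.lib_size_ct * p_ct
    if expected:
        k_ck = np.round(mu_ck).astype(np.int64)
        k_ct = np.round(mu_ct).astype(np.int64)
    else:
        k_ck = rng.poisson(mu_ck)
        k_ct = rng.poisson(mu_ct)

    lengths = np.round(10 ** rng.uniform(np.log10(200), np.log10(5000), size=n))
    gene_ids = np.array([f"G{i:06d}" for i in range(n)])

    table = CountTable(
        frame=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "length_bp": lengths.astype(np.int64),
                "count_ck": k_ck,
                "count_ct": k_ct,
            }
        ),
        n_ck=int(k_ck.sum()),
        n_ct=int(k_ct.sum()),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": planted != 0.0,
            "log2fc_planted": planted,
            "log2fc_realized": realized,
        }
    )
    return table, truth


def _latent_log2_curve(
    trend_class: str, times: np.ndarray, amplitude: float
) -> np.ndarray:
    """Noise-free log2 relative-expression curve, piecewise-linear on the grid."""
    n = len(times)
    if trend_class == "continual_up":
        return np.linspace(0.0, amplitude, n)
    if trend_class == "continual_down":
        return np.linspace(0.0, -amplitude, n)
    if trend_class == "saturating_down":
        # hits the floor by the third point, indistinguishable afterwards
        curve = np.full(n, -amplitude)
        curve[0] = 0.0
        curve[1] = -0.75 * amplitude
        return curve
    if trend_class == "transient":
        peak = n // 2
        rise = np.linspace(0.0, amplitude, peak + 1)
        fall = np.linspace(amplitude, 0.0, n - peak)
        return np.concatenate([rise, fall[1:]])
    if trend_class == "flat":
        return np.zeros(n)
    raise ConfigError(f"unknown trend class {trend_class!r}")


def _panel_from_latents(
    latents: dict[str, np.ndarray],
    times: np.ndarray,
    rng: np.random.Generator,
    ct_noise_sd: float,
    n_replicates: int,
    c0_target: float = 24.0,
    c0_reference: float = 16.0,
) -> pd.DataFrame:
    """Long-format Ct panel from per-gene latent log2 curves (CK has x(t)=1)."""
    rows = []
    for gene, log2x in latents.items():
        for condition in ("CK", "CT"):
            curve = log2x if condition == "CT" else np.zeros_like(log2x)
            for t, lx in zip(times, curve):
                for rep in range(1, n_replicates + 1):
                    eps_t = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
                    eps_r = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
                    rows.append(
                        (
                            gene,
                            condition,
                            float(t),
                            rep,
                            c0_target - lx + eps_t,
                            c0_reference + eps_r,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "condition",
            "time_h",
            "replicate",
            "ct_target",
            "ct_reference",
        ],
    )


def simulate_qpcr_panel(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct panel for a gene panel with planted trend classes.

    Returns the long-format Ct table and a truth frame
    (``gene_id, trend_class``).
    """
    config.validate()
    if config.panel_size == 0:
        raise ConfigError("trend_mix is empty")
    rng = _rng(config, _STREAM_QPCR)
    times = np.asarray(config.time_grid_h, dtype=float)

    latents: dict[str, np.ndarray] = {}
    truth_rows = []
    for trend_class in sorted(config.trend_mix):
        count = int(config.trend_mix[trend_class])
        for i in range(count):
            gene = f"{trend_class.upper()}_{i + 1:02d}"
            latents[gene] = _latent_log2_curve(
                trend_class, times, config.amplitude_log2
            )
            truth_rows.append((gene, trend_class))

    panel = _panel_from_latents(
        latents, times, rng, config.ct_noise_sd, config.n_replicates
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "trend_class"])
    return panel, truth


def survival_probability(duration_h, t50_h: float, slope_h: float) -> np.ndarray:
    """Logistic survival curve p(d) = 1 / (1 + exp((d - t50) / s))."""
    d = np.asarray(duration_h, dtype=float)
    return 1.0 / (1.0 + np.exp((d - t50_h) / slope_h))


def simulate_recovery(
    config: SimConfig, durations_h=DEFAULT_RECOVERY_GRID
) -> SurvivalSchedule:
    """Binomial survivor counts on the recovery-assay duration grid."""
    config.validate()
    rng = _rng(config, _STREAM_RECOVERY)
    d = np.asarray(durations_h, dtype=float)
    p = survival_probability(d, config.t50_h, config.slope_h)
    survived = rng.binomial(config.plants_per_duration, p)
    return SurvivalSchedule(
        duration_h=d,
        n_treated=np.full(len(d), config.plants_per_duration),
        n_survived=survived,
    )


def simulate_symptoms(
    config: SimConfig,
    times_h=DEFAULT_RECOVERY_GRID,
    q=DEFAULT_SYMPTOM_CURVE,
) -> pd.DataFrame:
    """Binomial symptomatic-leaf counts with nondecreasing probability."""
    config.validate()
    q = np.asarray(q, dtype=float)
    if np.any(np.diff(q) < 0):
        raise ConfigError("symptom probabilities must be nondecreasing")
    rng = _rng(config, _STREAM_SYMPTOMS)
    symptomatic = rng.binomial(config.leaves_per_timepoint, q)
    return pd.DataFrame(
        {
            "time_h": np.asarray(times_h, dtype=float),
            "n_symptomatic": symptomatic,
            "n_total": np.full(len(q), config.leaves_per_timepoint),
        }
    )


# Latent log2 curves on the 8-point qPCR grid for the marker verification
# scenario.  Three marker shapes (rise-to-48h-then-collapse-at-72h,
# rise-to-72h-then-collapse-at-96h, slow-decline-then-sharp-drop-at-72h) plus
# non-marker profiles: a gene staying high, plateau genes level from 24-72 h,
# and fast decliners that bottom out before the critical time.
MARKER_SHAPES_COLLAPSED = {
    "PFK_LIKE": (0.0, 0.7, 1.3, 2.0, -1.0, -1.2, -1.4, -1.5),
    "CAT_LIKE": (0.0, 0.6, 1.2, 1.9, 2.5, -0.8, -1.0, -1.2),
    "GLTX_LIKE": (0.0, -0.15, -0.35, -0.6, -3.0, -3.2, -3.4, -3.6),
    "UP_HIGH": (0.0, 0.8, 1.6, 2.2, 2.6, 2.8, 2.9, 3.0),
    "UP_PLATEAU_1": (0.0, 0.9, 1.8, 1.9, 2.0, 2.1, 2.2, 2.3),
    "UP_PLATEAU_2": (0.0, 0.8, 1.7, 1.8, 1.9, 2.0, 2.1, 2.2),
    "UP_PLATEAU_3": (0.0, 0.9, 1.7, 1.9, 2.0, 2.1, 2.2, 2.3),
    "DOWN_FAST_1": (0.0, -2.2, -3.0, -3.1, -3.2, -3.3, -3.4, -3.5),
    "DOWN_FAST_2": (0.0, -1.8, -2.8, -3.0, -3.1, -3.2, -3.3, -3.4),
}

MARKER_SHAPES_RESCUED = {
    **MARKER_SHAPES_COLLAPSED,
    "PFK_LIKE": (0.0, 0.7, 1.3, 2.0, 2.2, 2.3, 2.4, 2.5),
    "CAT_LIKE": (0.0, 0.6, 1.2, 1.9, 2.5, 2.7, 2.8, 2.9),
    "GLTX_LIKE": (0.0, -0.15, -0.35, -0.6, -0.8, -0.95, -1.05, -1.15),
}

MARKER_GENES = ("PFK_LIKE", "CAT_LIKE", "GLTX_LIKE")


def simulate_marker_scenario(
    config: SimConfig, collapsed: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct panel for the marker verification assay.

    ``collapsed=True`` plants the post-critical sharp signals of an
    irrecoverably damaged plant; ``collapsed=False`` is the rescued variant
    (the marker genes continue their pre-critical trends).  Requires the
    default 8-point time grid.  Returns the Ct panel and a truth frame
    (``gene_id, is_marker``).
    """
    config.validate()
    shapes = MARKER_SHAPES_COLLAPSED if collapsed else MARKER_SHAPES_RESCUED
    times = np.asarray(config.time_grid_h, dtype=float)
    if len(times) != 8:
        raise ConfigError("marker scenario requires the 8-point qPCR grid")
    rng = _rng(config, _STREAM_SCENARIO)
    latents = {g: np.asarray(c, dtype=float) for g, c in shapes.items()}
    panel = _panel_from_latents(
        latents, times, rng, config.ct_noise_sd, config.n_replicates
    )
    truth = pd.DataFrame(
        {
            "gene_id": list(shapes),
            "is_marker": [g in MARKER_GENES and collapsed for g in shapes],
        }
    )
    return panel, truth


def simulate_dilution_series(
    seed: int,
    slope: float = -3.32193,
    intercept: float = 35.0,
    log10_copies=(2, 3, 4, 5, 6),
    ct_noise_sd: float = 0.1,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Standard-curve dilution series: Ct = slope*log10(copies) + intercept + noise."""
    rng = np.random.default_rng([int(seed), _STREAM_DILUTION])
    rows = []
    for lc in log10_copies:
        for _ in range(n_replicates):
            eps = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
            rows.append((10.0**lc, slope * lc + intercept + eps))
    return pd.DataFrame(rows, columns=["copies", "ct"])
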