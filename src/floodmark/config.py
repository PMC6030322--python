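"""Simulation configuration.

A single :class:`SimConfig` drives every synthetic-data generator in
:mod:`floodmark.simulate`.  Defaults describe the study design the package
targets: two composite RNA-seq libraries of roughly 2x10^7 and 3x10^7 mapped
reads (control vs waterlogged), an 8-point qPCR sampling grid
(0, 12, 24, 48, 72, 96, 120, 144 h) with three technical replicates, a
7-duration recovery assay (0..144 h, step 24) with 10 plants per duration,
and per-timepoint leaf symptom counts out of 52 leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


DEFAULT_QPCR_GRID = (0.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0)
DEFAULT_RECOVERY_GRID = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0)

#: trend classes a simulated qPCR gene may follow
TREND_CLASSES = (
    "continual_up",
    "continual_down",
    "saturating_down",
    "transient",
    "flat",
)

#: 30-gene screening panel: 6 continually rising and 3 continually falling
#: candidates among 15 up- and 15 down-regulated genes, the rest transient,
#: fast-saturating or flat.
DEFAULT_TREND_MIX = {
    "continual_up": 6,
    "continual_down": 3,
    "saturating_down": 6,
    "transient": 12,
    "flat": 3,
}


class ConfigError(ValueError):
    """Raised when a SimConfig violates one of its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Parameters
    ----------
    seed
        Single integer controlling every source of randomness.
    n_genes
        Number of genes in the simulated count table.
    lib_size_ck, lib_size_ct
        Expected mapped-read totals of the control (CK) and waterlogged (CT)
        libraries.
    de_fraction
        Fraction of genes planted as differentially expressed.
    effect_log2fc
        ``(mean, sd)`` of the magnitude distribution of planted |log2FC|.
    time_grid_h
        qPCR sampling grid in hours; strictly increasing, starting at 0.
    trend_mix
        Genes per latent trend class for the qPCR panel.
    ct_noise_sd
        Gaussian noise on every Ct measurement, in cycles.
    amplitude_log2
        Maximum |log2 relative expression| of the latent qPCR curves.
    t50_h, slope_h
        Logistic survival parameters: survival probability after ``d`` hours
        of waterlogging is ``1 / (1 + exp((d - t50_h) / slope_h))``.
    plants_per_duration
        Plants shifted to recovery at each waterlogging duration.
    leaves_per_timepoint
        Leaves scored for symptoms at each timepoint.
    n_replicates
        Technical qPCR replicates per well.
    """

    seed: int = 0
    n_genes: int = 20_000
    lib_size_ck: int = 20_000_000
    lib_size_ct: int = 30_000_000
    de_fraction: float = 0.1
    effect_log2fc: tuple[float, float] = (2.0, 0.5)
    time_grid_h: tuple[float, ...] = DEFAULT_QPCR_GRID
    trend_mix: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TREND_MIX)
    )
    ct_noise_sd: float = 0.15
    amplitude_log2: float = 3.0
    t50_h: float = 60.0
    slope_h: float = 10.0
    plants_per_duration: int = 10
    leaves_per_timepoint: int = 52
    n_replicates: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.lib_size_ck <= 0 or self.lib_size_ct <= 0:
            raise ConfigError("library sizes must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd must be nonnegative")
        grid = tuple(self.time_grid_h)
        if len(grid) < 2 or grid[0] != 0:
            raise ConfigError("time_grid_h must start at 0 and have >= 2 points")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("time_grid_h must be strictly increasing")
        if self.plants_per_duration <= 0:
            raise ConfigError("plants_per_duration must be positive")
        if self.leaves_per_timepoint <= 0:
            raise ConfigError("leaves_per_timepoint must be positive")
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")
        if self.slope_h <= 0:
            raise ConfigError("slope_h must be positive")
        if self.amplitude_log2 <= 0:
            raise ConfigError("amplitude_log2 must be positive")
        unknown = set(self.trend_mix) - set(TREND_CLASSES)
        if unknown:
            raise ConfigError(f"unknown trend classes: {sorted(unknown)}")
        if any(v < 0 for v in self.trend_mix.values()):
            raise ConfigError("trend_mix counts must be nonnegative")

    @property
    def panel_size(self) -> int:
        return int(sum(self.trend_mix.values()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["time_grid_h"] = list(self.time_grid_h)
        d["effect_log2fc"] = list(self.effect_log2fc)
        d["trend_mix"] = dict(self.trend_mix)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "time_grid_h" in d:
            d["time_grid_h"] = tuple(float(t) for t in d["time_grid_h"])
        if "effect_log2fc" in d:
            d["effect_log2fc"] = tuple(float(x) for x in d["effect_log2fc"])
        return cls(**d)
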