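"""Plain-text readers and writers for the pipeline's tables.

Dialects:

* count table — TSV with columns ``gene_id  length_bp  count_ck  count_ct``
  preceded by comment lines ``# n_ck=<int>`` and ``# n_ct=<int>`` (and
  optionally ``# seed=<int>``); UTF-8, '.' decimal.
* Ct panel — CSV ``gene_id,condition,time_h,replicate,ct_target,ct_reference``.
* standard curve — CSV ``copies,ct``.
* expression series — TSV ``gene_id,time_h,rel,se,n``.
* trend calls — TSV ``gene_id,trend,tau,amplitude_log2,n_discriminable,saturating``.
* survival schedule — CSV ``duration_h,n_treated,n_survived``.
* symptom counts — CSV ``time_h,n_symptomatic,n_total``.
* marker rule — JSON (see :class:`floodmark.markers.MarkerRule`).
* config — flat ``key=value`` lines (lists comma-separated,
  ``trend_mix`` entries as ``trend_mix.<class>=<count>``).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .degcall import CountTable
from .markers import MarkerRule
from .qpcr import ExpressionSeries
from .recovery import SurvivalSchedule

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_ct_panel",
    "write_ct_panel",
    "read_series_table",
    "write_series_table",
    "series_to_frame",
    "frame_to_panel",
    "read_schedule",
    "write_schedule",
    "read_symptoms",
    "write_symptoms",
    "read_rule",
    "write_rule",
    "read_config",
]

_HEADER_RE = re.compile(r"^#\s*(\w+)\s*=\s*(\S+)")


def read_count_table(path) -> CountTable:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _HEADER_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
    if "n_ck" not in meta or "n_ct" not in meta:
        raise ValueError(f"{path}: missing '# n_ck=' / '# n_ct=' header lines")
    frame = pd.read_csv(path, sep="\t", comment="#")
    return CountTable(frame=frame, n_ck=int(meta["n_ck"]), n_ct=int(meta["n_ct"]))


def write_count_table(table: CountTable, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_ck={table.n_ck}\n# n_ct={table.n_ct}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        table.frame.to_csv(fh, sep="\t", index=False)


def read_ct_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ct_panel(panel: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        panel.to_csv(fh, index=False)


def series_to_frame(panel: dict[str, ExpressionSeries]) -> pd.DataFrame:
    rows = []
    for gene, s in panel.items():
        for t, rel, se, n in zip(s.times_h, s.rel, s.se, s.n_reps):
            rows.append((gene, t, rel, se, n))
    return pd.DataFrame(rows, columns=["gene_id", "time_h", "rel", "se", "n"])


def frame_to_panel(frame: pd.DataFrame) -> dict[str, ExpressionSeries]:
    panel = {}
    for gene, sub in frame.groupby("gene_id", sort=False):
        panel[str(gene)] = ExpressionSeries(
            gene_id=str(gene),
            times_h=sub["time_h"].to_numpy(),
            rel=sub["rel"].to_numpy(),
            se=sub["se"].to_numpy(),
            n_reps=sub["n"].to_numpy(),
        )
    return panel


def write_series_table(panel: dict[str, ExpressionSeries], path) -> None:
    series_to_frame(panel).to_csv(path, sep="\t", index=False)


def read_series_table(path) -> dict[str, ExpressionSeries]:
    return frame_to_panel(pd.read_csv(path, sep="\t", comment="#"))


def read_schedule(path) -> SurvivalSchedule:
    frame = pd.read_csv(path, comment="#")
    return SurvivalSchedule(
        duration_h=frame["duration_h"].to_numpy(),
        n_treated=frame["n_treated"].to_numpy(),
        n_survived=frame["n_survived"].to_numpy(),
    )


def write_schedule(schedule: SurvivalSchedule, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        schedule.to_frame().to_csv(fh, index=False)


def read_symptoms(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_symptoms(counts: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        counts.to_csv(fh, index=False)


def read_rule(path) -> MarkerRule:
    return MarkerRule.from_json(Path(path).read_text(encoding="utf-8"))


def write_rule(rule: MarkerRule, path) -> None:
    Path(path).write_text(rule.to_json() + "\n", encoding="utf-8")


def _parse_value(text: str):
    text = text.strip()
    if "," in text:
        return tuple(_parse_value(t) for t in text.split(","))
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def read_config(path) -> SimConfig:
    """Parse a flat key=value config file into a SimConfig."""
    fields: dict = {}
    trend_mix: dict[str, int] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line is not key=value: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("trend_mix."):
            trend_mix[key.removeprefix("trend_mix.")] = int(value)
        else:
            fields[key] = _parse_value(value)
    if trend_mix:
        fields["trend_mix"] = trend_mix
    return SimConfig.from_dict(fields)
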