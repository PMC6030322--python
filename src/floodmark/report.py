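"""Summary tables: DEG tallies and database-annotation percentages.

Percentages are count/denominator rounded half-up, two decimals for DEG and
annotation summaries, matching the arithmetic of the published report-style
tables.  Annotation counts are inputs here — the BLAST searches that produce
them are outside this package's scope; only the tabulation is reproduced.
"""

from __future__ import annotations

import math

import pandas as pd

from .recovery import round_half_up

__all__ = ["deg_summary", "annotation_summary", "percent"]


def percent(count: int, total: int, decimals: int = 2) -> float:
    """100 * count / total, rounded half-up."""
    if total <= 0:
        raise ValueError("denominator must be positive")
    if count < 0 or count > total:
        raise ValueError("count must satisfy 0 <= count <= total")
    return round_half_up(100.0 * count / total, decimals)


def deg_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Tally DEG statuses and presence classes with percentages among DEGs.

    Returns rows ``(category, count, denominator, percent)``; the up/down
    percentages use the DEG total as denominator and are NaN when there are
    no DEGs.
    """
    status = records["status"].value_counts()
    presence = records["presence"].value_counts()
    n_up = int(status.get("up", 0))
    n_down = int(status.get("down", 0))
    n_deg = n_up + n_down
    rows = [
        ("up", n_up, n_deg, percent(n_up, n_deg) if n_deg else math.nan),
        ("down", n_down, n_deg, percent(n_down, n_deg) if n_deg else math.nan),
        ("no_change", int(status.get("no_change", 0)), len(records), None),
        ("ck_only", int(presence.get("ck_only", 0)), len(records), None),
        ("ct_only", int(presence.get("ct_only", 0)), len(records), None),
        ("both", int(presence.get("both", 0)), len(records), None),
        ("absent", int(presence.get("absent", 0)), len(records), None),
    ]
    out = pd.DataFrame(rows, columns=["category", "count", "denominator", "percent"])
    return out


def annotation_summary(
    annotated: dict[str, int], total_unigenes: int
) -> pd.DataFrame:
    """Percentage of unigenes annotated per database (and combined rows).

    ``annotated`` maps a row label (a database name, or combined labels such
    as "at least one database") to its unigene count; every count must be at
    most ``total_unigenes``.
    """
    if total_unigenes <= 0:
        raise ValueError("total_unigenes must be positive")
    rows = []
    for label, count in annotated.items():
        if count > total_unigenes:
            raise ValueError(
                f"annotated count for {label!r} exceeds total unigenes"
            )
        rows.append((label, int(count), total_unigenes, percent(count, total_unigenes)))
    return pd.DataFrame(rows, columns=["category", "count", "denominator", "percent"])
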