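"""Replicate-free two-library differential expression.

The study design has one composite sample per condition (control CK and
waterlogged CT), so per-gene dispersion cannot be estimated.  Calling is
instead based on the random-sampling model: each gene's read count in a
library is Binomial(library size, gene proportion), and under the null the
two libraries share the proportion.  The test statistic standardizes the
MA-plot ordinate M = log2 k_ck - log2 k_ct against its conditional mean and
variance given the abscissa A = (log2 k_ck + log2 k_ct)/2.

For counts C_i ~ Binomial(n_i, p) the delta method gives log2 C_i
approximately normal with mean log2(n_i p) and variance
(1 - p) / (n_i p ln^2 2).  Conditioning M on A = a and plugging in the
moment estimate p_hat = 2^a / sqrt(n1 n2) yields

    E[M | A=a]   = log2(n1 / n2)
    Var[M | A=a] = 4 (1 - p_hat) / (ln^2 2 * (n1 + n2) * p_hat)

The normal approximation is validated against an exact conditional binomial
test (``exact_cond_test``): given T = k1 + k2, k1 ~ Binomial(T, n1/(n1+n2)),
with the two-sided minimum-likelihood p-value.

Genes seen in only one library cannot enter the log-ratio path; they are
reported through presence classes (ck_only / ct_only) with the exact test
supplying their p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountTable",
    "compute_rpkm",
    "classify_presence",
    "mars_test",
    "exact_cond_test",
    "bh_adjust",
    "call_degs",
    "MarsDEGCaller",
]

LN2_SQ = math.log(2.0) ** 2

#: columns of the per-gene result table, in output order
DEG_COLUMNS = [
    "gene_id",
    "rpkm_ck",
    "rpkm_ct",
    "log2fc",
    "M",
    "A",
    "z",
    "p",
    "q",
    "status",
    "presence",
]


@dataclass
class CountTable:
    """Two-library gene count table.

    ``frame`` has columns ``gene_id, length_bp, count_ck, count_ct``;
    ``n_ck`` / ``n_ct`` are the mapped-read library totals.
    """

    frame: pd.DataFrame
    n_ck: int
    n_ct: int

    def __post_init__(self) -> None:
        required = {"gene_id", "length_bp", "count_ck", "count_ct"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if self.n_ck <= 0 or self.n_ct <= 0:
            raise ValueError("library totals must be positive")
        f = self.frame
        if f["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        if (f["length_bp"] < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        if (f["count_ck"] < 0).any() or (f["count_ct"] < 0).any():
            raise ValueError("counts must be nonnegative")
        if (f["count_ck"] > self.n_ck).any() or (f["count_ct"] > self.n_ct).any():
            raise ValueError("a gene count exceeds its library total")

    def __len__(self) -> int:
        return len(self.frame)


def compute_rpkm(k, n, length_bp):
    """Reads per kilobase per million mapped reads: 1e9 * k / (n * L)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(n < 1) or np.any(length_bp < 1):
        raise ValueError("library total and gene length must be >= 1")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    out = 1e9 * k / (n * length_bp)
    return float(out) if out.ndim == 0 else out


def classify_presence(k_ck, k_ct, min_count: int = 1):
    """Presence class: both / ck_only / ct_only / absent at ``min_count``."""
    k_ck = np.asarray(k_ck)
    k_ct = np.asarray(k_ct)
    if np.any(k_ck < 0) or np.any(k_ct < 0):
        raise ValueError("counts must be nonnegative")
    in_ck = k_ck >= min_count
    in_ct = k_ct >= min_count
    out = np.where(
        in_ck & in_ct,
        "both",
        np.where(in_ck, "ck_only", np.where(in_ct, "ct_only", "absent")),
    )
    return str(out) if out.ndim == 0 else out


def mars_test(k1, n1, k2, n2):
    """MA-plot random-sampling z-test for two library counts.

    Returns ``(M, A, z, p)`` with M = log2 k1 - log2 k2,
    A = (log2 k1 + log2 k2) / 2, z the standardized M given A under the
    common-proportion binomial model, and p the two-sided normal tail.
    Requires k1, k2 >= 1; zero-count genes go through
    :func:`classify_presence` and :func:`exact_cond_test` instead.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    scalar = k1.ndim == 0 and k2.ndim == 0
    if np.any(k1 < 1) or np.any(k2 < 1):
        raise ValueError(
            "mars_test requires counts >= 1 in both libraries; "
            "use exact_cond_test / classify_presence for zero counts"
        )
    M = np.log2(k1) - np.log2(k2)
    A = (np.log2(k1) + np.log2(k2)) / 2.0
    p_hat = np.minimum(2.0**A / np.sqrt(n1 * n2), 1.0 - 1e-12)
    var = 4.0 * (1.0 - p_hat) / (LN2_SQ * (n1 + n2) * p_hat)
    z = (M - np.log2(n1 / n2)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if scalar:
        return float(M), float(A), float(z), float(p)
    return M, A, z, p


def exact_cond_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Exact conditional two-sided binomial test.

    Conditional on T = k1 + k2, k1 ~ Binomial(T, n1/(n1+n2)); the two-sided
    p-value sums the probabilities of every outcome no more likely than the
    observed one (minimum-likelihood method), capped at 1.  T = 0 gives
    p = 1 by convention.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be nonnegative")
    total = k1 + k2
    if total == 0:
        return 1.0
    prob = n1 / (n1 + n2)
    pmf = stats.binom.pmf(np.arange(total + 1), total, prob)
    observed = pmf[k1]
    # tolerance guards against ties broken by floating-point noise
    p = float(pmf[pmf <= observed * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    records: pd.DataFrame,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.001,
) -> pd.DataFrame:
    """Fill the ``status`` column: up / down / no_change.

    A gene is up iff log2fc >= +fc_threshold and q < q_threshold, down iff
    log2fc <= -fc_threshold and q < q_threshold; anything else (including
    genes with undefined log2fc) is no_change.
    """
    records = records.copy()
    fc = records["log2fc"].to_numpy(dtype=float)
    q = records["q"].to_numpy(dtype=float)
    sig = q < q_threshold
    status = np.full(len(records), "no_change", dtype=object)
    with np.errstate(invalid="ignore"):
        status[sig & (fc >= fc_threshold)] = "up"
        status[sig & (fc <= -fc_threshold)] = "down"
    records["status"] = status
    return records


class MarsDEGCaller(BaseEstimator):
    """Differential-expression caller for a two-library count table.

    Parameters
    ----------
    fc_threshold : float
        Minimum |log2 fold change| (treated over control) to call a DEG.
    q_threshold : float
        FDR (BH-adjusted p) cutoff.
    min_count : int
        Count at or above which a gene counts as expressed in a library.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pandas.DataFrame
        One row per gene with RPKM, log2fc, M, A, z, p, q, status, presence.
    n_up_, n_down_, n_no_change_ : int
        Status tallies.
    """

    def __init__(
        self,
        fc_threshold: float = 1.0,
        q_threshold: float = 0.001,
        min_count: int = 1,
    ):
        self.fc_threshold = fc_threshold
        self.q_threshold = q_threshold
        self.min_count = min_count

    def fit(self, table: CountTable, y=None):
        f = table.frame
        n1, n2 = float(table.n_ct), float(table.n_ck)
        k_ck = f["count_ck"].to_numpy(dtype=float)
        k_ct = f["count_ct"].to_numpy(dtype=float)

        rpkm_ck = compute_rpkm(k_ck, table.n_ck, f["length_bp"])
        rpkm_ct = compute_rpkm(k_ct, table.n_ct, f["length_bp"])
        presence = classify_presence(k_ck, k_ct, self.min_count)

        m = np.full(len(f), np.nan)
        a = np.full(len(f), np.nan)
        z = np.full(len(f), np.nan)
        p = np.ones(len(f))
        log2fc = np.full(len(f), np.nan)

        # treated-over-control sign convention: upregulated genes (higher in
        # CT) must come out positive
        both = (k_ck >= 1) & (k_ct >= 1)
        if both.any():
            m_b, a_b, z_b, p_b = mars_test(k_ct[both], n1, k_ck[both], n2)
            m[both] = m_b
            a[both] = a_b
            z[both] = z_b
            p[both] = p_b
            log2fc[both] = np.log2((k_ct[both] / n1) / (k_ck[both] / n2))

        single = ~both & ((k_ck >= 1) | (k_ct >= 1))
        for i in np.flatnonzero(single):
            p[i] = exact_cond_test(
                int(k_ct[i]), int(n1), int(k_ck[i]), int(n2)
            )

        q = bh_adjust(p)
        results = pd.DataFrame(
            {
                "gene_id": f["gene_id"].to_numpy(),
                "rpkm_ck": rpkm_ck,
                "rpkm_ct": rpkm_ct,
                "log2fc": log2fc,
                "M": m,
                "A": a,
                "z": z,
                "p": p,
                "q": q,
                "presence": presence,
            }
        )
        results = call_degs(results, self.fc_threshold, self.q_threshold)
        self.results_ = results[DEG_COLUMNS]
        counts = results["status"].value_counts()
        self.n_up_ = int(counts.get("up", 0))
        self.n_down_ = int(counts.get("down", 0))
        self.n_no_change_ = int(counts.get("no_change", 0))
        return self

    def fit_transform(self, table: CountTable, y=None) -> pd.DataFrame:
        return self.fit(table).results_
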