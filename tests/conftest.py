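import numpy as np
import pandas as pd
import pytest

from floodmark import SimConfig
from floodmark.qpcr import ExpressionSeries
from floodmark.recovery import SurvivalSchedule


@pytest.fixture
def small_count_config():
    """Desk-scale count simulation: 5000 genes, a few million reads."""
    return dict(
        n_genes=5000,
        lib_size_ck=2_000_000,
        lib_size_ct=3_000_000,
    )


@pytest.fixture
def qpcr_config():
    return SimConfig(seed=7)


@pytest.fixture
def noise_free_qpcr_config():
    return SimConfig(seed=7, ct_noise_sd=0.0)


def make_series(rel, times=None, se=None, gene_id="G"):
    rel = np.asarray(rel, dtype=float)
    if times is None:
        times = np.arange(len(rel), dtype=float) * 24.0
    if se is None:
        se = np.zeros_like(rel)
    return ExpressionSeries(gene_id=gene_id, times_h=times, rel=rel, se=se)


@pytest.fixture
def paper_pattern_schedule():
    """Survival fractions 1.0, .9, .6, .3, .2, .1, 0 on 0..144 h step 24."""
    return SurvivalSchedule(
        duration_h=np.arange(0, 145, 24, dtype=float),
        n_treated=np.full(7, 10),
        n_survived=np.array([10, 9, 6, 3, 2, 1, 0]),
    )


@pytest.fixture
def table1_ct_counts():
    """Leaf symptom counts of the treated plants (out of 52 leaves)."""
    return pd.DataFrame(
        {
            "time_h": [0.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0],
            "n_symptomatic": [0, 4, 10, 25, 30, 38, 50],
            "n_total": [52] * 7,
        }
    )
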