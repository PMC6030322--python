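"""Tests for the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from floodmark import MarsDEGCaller, SimConfig
from floodmark.config import ConfigError
from floodmark.simulate import (
    DEFAULT_SYMPTOM_CURVE,
    simulate_counts,
    simulate_marker_scenario,
    simulate_qpcr_panel,
    simulate_recovery,
    simulate_symptoms,
    survival_probability,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=0),
            dict(lib_size_ck=0),
            dict(de_fraction=1.5),
            dict(ct_noise_sd=-0.1),
            dict(time_grid_h=(12.0, 24.0)),  # must start at 0
            dict(time_grid_h=(0.0, 24.0, 24.0)),  # strictly increasing
            dict(plants_per_duration=0),
            dict(trend_mix={"bogus_class": 3}),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)

    def test_round_trip_through_dict(self):
        cfg = SimConfig(seed=3, n_genes=100)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestSimulateCounts:
    def test_seed_determinism(self, small_count_config):
        cfg = SimConfig(seed=42, **small_count_config)
        t1, truth1 = simulate_counts(cfg)
        t2, truth2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)
        pd.testing.assert_frame_equal(truth1, truth2)
        assert (t1.n_ck, t1.n_ct) == (t2.n_ck, t2.n_ct)

    def test_different_seeds_differ(self, small_count_config):
        t1, _ = simulate_counts(SimConfig(seed=1, **small_count_config))
        t2, _ = simulate_counts(SimConfig(seed=2, **small_count_config))
        assert not t1.frame.equals(t2.frame)

    def test_truth_matches_de_fraction(self, small_count_config):
        cfg = SimConfig(seed=5, de_fraction=0.1, **small_count_config)
        _, truth = simulate_counts(cfg)
        assert truth.is_de.sum() == 500

    def test_null_panel_produces_no_deg_calls(self, small_count_config):
        # de_fraction 0: fraction called DE at q < 0.001 stays at chance level
        rates = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, de_fraction=0.0, **small_count_config)
            table, _ = simulate_counts(cfg)
            results = MarsDEGCaller().fit(table).results_
            rates.append(results.status.isin(["up", "down"]).mean())
        assert np.mean(rates) <= 0.002

    def test_planted_strong_effects_recovered(self, small_count_config):
        # |log2FC| = 2 at expected counts >= 200: >= 95% power
        recovered = total = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed, de_fraction=0.1, effect_log2fc=(2.0, 0.0),
                **small_count_config,
            )
            table, truth = simulate_counts(cfg)
            results = MarsDEGCaller().fit(table).results_
            called = results.status.isin(["up", "down"]).to_numpy()
            big = (
                truth.is_de.to_numpy()
                & (table.frame.count_ck >= 200).to_numpy()
                & (table.frame.count_ct >= 200).to_numpy()
            )
            recovered += (called & big).sum()
            total += big.sum()
        assert recovered / total >= 0.95


class TestSimulateQpcr:
    def test_seed_determinism(self):
        p1, _ = simulate_qpcr_panel(SimConfig(seed=8))
        p2, _ = simulate_qpcr_panel(SimConfig(seed=8))
        pd.testing.assert_frame_equal(p1, p2)

    def test_panel_shape(self, qpcr_config):
        panel, truth = simulate_qpcr_panel(qpcr_config)
        expected_rows = qpcr_config.panel_size * 8 * 2 * 3  # genes*times*cond*reps
        assert len(panel) == expected_rows
        assert len(truth) == qpcr_config.panel_size

    def test_empty_trend_mix_rejected(self):
        cfg = SimConfig(seed=0, trend_mix={})
        with pytest.raises(ConfigError, match="empty"):
            simulate_qpcr_panel(cfg)


class TestSimulateRecovery:
    def test_logistic_midpoint(self):
        assert survival_probability(60.0, 60.0, 10.0) == pytest.approx(0.5)

    def test_steep_limit_is_step_function(self):
        p = survival_probability([48.0, 72.0], 60.0, 1e-9)
        np.testing.assert_allclose(p, [1.0, 0.0], atol=1e-12)

    def test_seed_determinism(self):
        s1 = simulate_recovery(SimConfig(seed=9))
        s2 = simulate_recovery(SimConfig(seed=9))
        np.testing.assert_array_equal(s1.n_survived, s2.n_survived)

    def test_fractions_within_binomial_envelopes(self):
        # Monte-Carlo check: pooled survivors per duration stay inside a
        # 99% binomial envelope around the planted logistic curve
        n_seeds, n_plants = 100, 10
        d = np.arange(0, 145, 24, dtype=float)
        p = survival_probability(d, 60.0, 10.0)
        totals = np.zeros(7)
        for seed in range(n_seeds):
            totals += simulate_recovery(SimConfig(seed=seed)).n_survived
        from scipy import stats

        n = n_seeds * n_plants
        lo = stats.binom.ppf(0.005, n, p)
        hi = stats.binom.ppf(0.995, n, p)
        assert np.all(totals >= lo) and np.all(totals <= hi)


class TestSimulateSymptoms:
    def test_no_symptoms_at_time_zero(self):
        table = simulate_symptoms(SimConfig(seed=10))
        assert table.n_symptomatic.iloc[0] == 0

    def test_expected_counts_nondecreasing(self):
        # q is nondecreasing, so averaged counts over seeds are too
        acc = np.zeros(len(DEFAULT_SYMPTOM_CURVE))
        for seed in range(50):
            acc += simulate_symptoms(SimConfig(seed=seed)).n_symptomatic
        assert np.all(np.diff(acc) >= 0)

    def test_seed_determinism(self):
        a = simulate_symptoms(SimConfig(seed=11))
        b = simulate_symptoms(SimConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestMarkerScenario:
    def test_marker_truth_labels(self):
        _, truth = simulate_marker_scenario(SimConfig(seed=12))
        assert truth.is_marker.sum() == 3
        _, truth_rescued = simulate_marker_scenario(
            SimConfig(seed=12), collapsed=False
        )
        assert truth_rescued.is_marker.sum() == 0

    def test_requires_eight_point_grid(self):
        cfg = SimConfig(seed=0, time_grid_h=(0.0, 24.0, 48.0, 72.0))
        with pytest.raises(ConfigError, match="8-point"):
            simulate_marker_scenario(cfg)
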