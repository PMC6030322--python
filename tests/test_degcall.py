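"""Unit and property tests for the replicate-free DE caller."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from floodmark import (
    CountTable,
    MarsDEGCaller,
    SimConfig,
    bh_adjust,
    call_degs,
    classify_presence,
    compute_rpkm,
    exact_cond_test,
    mars_test,
)
from floodmark.simulate import simulate_counts


class TestRPKM:
    def test_direct_formula(self):
        assert compute_rpkm(100, 10**7, 1000) == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        assert compute_rpkm(0, 12345, 777) == 0.0

    def test_scale_invariance_in_depth(self):
        assert compute_rpkm(100, 10**6, 500) == pytest.approx(
            compute_rpkm(200, 2 * 10**6, 500)
        )

    def test_rejects_zero_length_or_depth(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 10, 0)
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 100)


class TestPresence:
    @pytest.mark.parametrize(
        "k_ck, k_ct, expected",
        [(0, 25, "ct_only"), (25, 0, "ck_only"), (10, 10, "both"), (0, 0, "absent")],
    )
    def test_classes(self, k_ck, k_ct, expected):
        assert classify_presence(k_ck, k_ct, min_count=1) == expected

    def test_min_count_threshold(self):
        assert classify_presence(4, 5, min_count=5) == "ct_only"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_presence(-1, 3)


class TestMarsTest:
    def test_equal_proportions_null(self):
        m, a, z, p = mars_test(50, 1e6, 100, 2e6)
        assert m == pytest.approx(-1.0)
        assert abs(z) < 1e-9
        assert p > 0.9

    def test_fourfold_change_is_significant(self):
        # exact conditional oracle gives p ~ 2e-22 for this pair
        _, _, z, p = mars_test(200, 1e6, 50, 1e6)
        assert p < 1e-6
        assert z > 0

    def test_swap_symmetry(self):
        m1, _, z1, p1 = mars_test(73, 1.1e6, 188, 2.3e6)
        m2, _, z2, p2 = mars_test(188, 2.3e6, 73, 1.1e6)
        assert m2 == pytest.approx(-m1, abs=1e-12)
        assert z2 == pytest.approx(-z1, abs=1e-9)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError, match="exact_cond_test"):
            mars_test(0, 1e6, 10, 1e6)


def brute_force_exact(k1, n1, k2, n2):
    """Independent enumeration of the conditional two-sided p-value."""
    total = k1 + k2
    if total == 0:
        return 1.0
    prob = n1 / (n1 + n2)
    probs = [stats.binom.pmf(j, total, prob) for j in range(total + 1)]
    observed = probs[k1]
    return min(sum(p for p in probs if p <= observed + 1e-15), 1.0)


class TestExactConditional:
    def test_all_in_one_library_small(self):
        # enumeration over T=3 outcomes at equal depths: 2 * 0.5^3
        assert exact_cond_test(3, 10**5, 0, 10**5) == pytest.approx(0.25)

    def test_all_in_one_library_ten(self):
        assert exact_cond_test(10, 10**5, 0, 10**5) == pytest.approx(
            2 * 0.5**10, rel=1e-9
        )

    def test_modal_outcome_p_is_one(self):
        assert exact_cond_test(17, 10**5, 17, 10**5) == pytest.approx(1.0)

    def test_zero_total_convention(self):
        assert exact_cond_test(0, 100, 0, 100) == 1.0

    @pytest.mark.parametrize("k1,k2", [(5, 2), (12, 3), (8, 8), (1, 9)])
    def test_matches_independent_enumeration(self, k1, k2):
        assert exact_cond_test(k1, 3 * 10**5, k2, 10**5) == pytest.approx(
            brute_force_exact(k1, 3 * 10**5, k2, 10**5), rel=1e-9
        )


class TestOracleEquivalence:
    def test_spearman_on_small_count_grid(self):
        ks = np.arange(1, 51)
        p_mars = np.empty((50, 50))
        p_exact = np.empty((50, 50))
        for i, k1 in enumerate(ks):
            for j, k2 in enumerate(ks):
                p_mars[i, j] = mars_test(k1, 1e5, k2, 1e5)[3]
                p_exact[i, j] = exact_cond_test(int(k1), 10**5, int(k2), 10**5)
        rho = stats.spearmanr(p_mars.ravel(), p_exact.ravel()).statistic
        assert rho >= 0.99

    @pytest.mark.parametrize(
        "k1,k2", [(150, 100), (300, 100), (120, 80), (500, 250), (200, 150)]
    )
    def test_log_p_agreement_at_moderate_counts(self, k1, k2):
        p_m = mars_test(k1, 1e6, k2, 1e6)[3]
        p_e = exact_cond_test(k1, 10**6, k2, 10**6)
        assert abs(np.log(p_m) - np.log(p_e)) <= 0.1 * abs(np.log(p_e))


def bh_brute_force(p):
    """Step-up BH computed directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestBHAdjust:
    def test_four_value_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_all_orderings_of_four(self):
        from itertools import permutations

        rng = np.random.default_rng(5)
        for _ in range(4):
            base = rng.uniform(0, 1, size=4)
            for perm in permutations(range(4)):
                p = base[list(perm)]
                np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p))


class TestCallDegs:
    @pytest.mark.parametrize(
        "log2fc,q,expected",
        [
            (1.2, 1e-4, "up"),
            (0.9, 1e-9, "no_change"),  # fails the fold-change criterion
            (-3.0, 0.01, "no_change"),  # fails the FDR criterion
            (-1.0, 1e-5, "down"),
            (np.nan, 1e-9, "no_change"),
        ],
    )
    def test_thresholds(self, log2fc, q, expected):
        rec = pd.DataFrame({"log2fc": [log2fc], "q": [q]})
        assert call_degs(rec)["status"].iloc[0] == expected


class TestCallerOnSimulatedData:
    def test_sign_convention_treated_over_control(self, small_count_config):
        cfg = SimConfig(seed=3, de_fraction=0.1, effect_log2fc=(2.0, 0.0),
                        **small_count_config)
        table, truth = simulate_counts(cfg, expected=True)
        results = MarsDEGCaller().fit(table).results_
        merged = results.merge(truth, on="gene_id")
        planted_up = merged[merged.log2fc_planted > 0]
        # genes planted higher in the treated library must carry positive log2fc
        assert (planted_up.log2fc > 0).mean() > 0.99

    def test_expected_counts_recover_planted_effect(self, small_count_config):
        cfg = SimConfig(seed=4, de_fraction=0.05, effect_log2fc=(2.0, 0.0),
                        **small_count_config)
        table, truth = simulate_counts(cfg, expected=True)
        results = MarsDEGCaller().fit(table).results_
        merged = results.merge(truth, on="gene_id")
        big = merged[(table.frame.count_ck >= 200).to_numpy()
                     & (table.frame.count_ct >= 200).to_numpy()
                     & merged.is_de.to_numpy()]
        # rounding expectations leaves only sub-count quantization error
        assert np.allclose(big.log2fc, big.log2fc_realized, atol=0.05)

    def test_single_library_genes_use_exact_path(self):
        frame = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "length_bp": [1000, 1000, 1000],
                "count_ck": [0, 50, 40],
                "count_ct": [30, 0, 60],
            }
        )
        table = CountTable(frame=frame, n_ck=10**5, n_ct=10**5)
        results = MarsDEGCaller().fit(table).results_.set_index("gene_id")
        assert results.loc["a", "presence"] == "ct_only"
        assert results.loc["b", "presence"] == "ck_only"
        assert np.isnan(results.loc["a", "z"])
        assert results.loc["a", "p"] == pytest.approx(
            brute_force_exact(30, 10**5, 0, 10**5), rel=1e-9
        )

    def test_count_table_validation(self):
        frame = pd.DataFrame(
            {"gene_id": ["a", "a"], "length_bp": [1, 1],
             "count_ck": [1, 1], "count_ct": [1, 1]}
        )
        with pytest.raises(ValueError, match="unique"):
            CountTable(frame=frame, n_ck=10, n_ct=10)
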