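"""Spearman scoring, block-length estimation, bootstrap null, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interbrain.inference import (
    block_shuffle,
    bootstrap_null,
    bootstrap_pvalue,
    evaluate_dyad,
    fdr_adjust,
    find_block_lag,
    spearman,
)
from interbrain.models import ModelGrid, fit_all_channels
from conftest import ar_noise_spec, bandpassed, make_config
from interbrain.simulate import generate_dyad


class TestSpearman:
    def test_identical_series_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, x) == pytest.approx(1.0)

    def test_reversed_series_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_textbook_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 summing to 2
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(-10**6, 10**6), min_size=5, max_size=30, unique=True),
           st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, values, seed):
        a = np.asarray(values, dtype=float) / 1000.0
        b = np.random.default_rng(seed).permutation(a)
        base = spearman(a, b)
        assert spearman(3.0 * a + 7.0, b) == pytest.approx(base, abs=1e-12)
        assert spearman(a, b**3 + 5.0 * b) == pytest.approx(base, abs=1e-12)


class TestFindBlockLag:
    def test_white_noise_decorrelates_immediately(self):
        x = np.random.default_rng(0).standard_normal((3500, 3))
        est = find_block_lag(x)
        assert est.lag == 1

    def test_ar1_lag_matches_analytic_decay(self):
        # 0.9^k <= 0.05 first at k = 29
        rng = np.random.default_rng(1)
        n = 20000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + eps[i]
        est = find_block_lag(x, max_lag=100)
        assert abs(est.lag - 29) <= 4

    def test_median_aggregation_across_channels(self):
        est = find_block_lag.__wrapped__ if hasattr(find_block_lag, "__wrapped__") else None
        # aggregate two channels with very different decorrelation times
        rng = np.random.default_rng(2)
        n = 30000
        fast = rng.standard_normal(n)            # lag ~ 1
        slow = np.convolve(rng.standard_normal(n), np.ones(40) / 40, mode="same")
        x = np.column_stack([fast, slow])
        est = find_block_lag(x, max_lag=100)
        lo, hi = sorted(est.per_channel_lags)
        expected = int(np.ceil(np.median([lo, hi])))
        assert est.lag == expected
        assert lo < est.lag < hi

    def test_no_crossing_raises(self):
        trend = np.linspace(0, 1, 2000)  # ACF never near zero
        with pytest.raises(ValueError, match="max_lag"):
            find_block_lag(trend, max_lag=50)

    def test_segment_shorter_than_twice_max_lag_rejected(self):
        with pytest.raises(ValueError, match="twice max_lag"):
            find_block_lag(np.random.default_rng(0).standard_normal(100), max_lag=60)


class TestBlockShuffle:
    def test_block_count_rule(self):
        x = np.random.default_rng(0).standard_normal((7000, 2))
        out = block_shuffle(x, lag=35, seed=1)
        assert out.shape == (7000, 2)          # 7000/35 = 200 exact blocks
        x2 = np.random.default_rng(0).standard_normal((7010, 2))
        assert block_shuffle(x2, lag=35, seed=1).shape == (7000, 2)  # remainder dropped

    def test_single_block_is_identity(self):
        x = np.random.default_rng(1).standard_normal((50, 3))
        np.testing.assert_array_equal(block_shuffle(x, lag=50, seed=9), x)

    def test_multiset_of_samples_preserved(self):
        x = np.random.default_rng(2).standard_normal((101, 2))
        out = block_shuffle(x, lag=10, seed=3)
        np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(x[:100, 0]))

    def test_same_permutation_across_channels(self):
        x = np.random.default_rng(3).standard_normal((90, 1))
        both = np.column_stack([x, x + 1000.0])
        out = block_shuffle(both, lag=9, seed=4)
        np.testing.assert_allclose(out[:, 1] - out[:, 0], 1000.0)

    def test_lag_bounds_validated(self):
        x = np.zeros((10, 1))
        with pytest.raises(ValueError):
            block_shuffle(x, lag=0)
        with pytest.raises(ValueError):
            block_shuffle(x, lag=11)


class TestBootstrapPvalue:
    def test_exceedance_ratio(self):
        null = np.concatenate([np.full(988, -0.5), np.full(12, 0.9)])
        assert bootstrap_pvalue(0.5, null) == pytest.approx(0.012)

    def test_observed_above_all(self):
        null = np.linspace(-0.5, 0.5, 1000)
        assert bootstrap_pvalue(0.9, null) == 0.0
        assert bootstrap_pvalue(0.9, null, corrected=True) == pytest.approx(1 / 1001)

    def test_observed_below_all(self):
        null = np.linspace(-0.5, 0.5, 1000)
        assert bootstrap_pvalue(-0.9, null) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bootstrap_pvalue(0.1, np.array([]))


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = np.inf
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adj[i] = min(running_min, 1.0)
    return adj


class TestFDR:
    def test_textbook_vector(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_uniform_vector_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.5] * 6), [0.5] * 6)

    def test_single_p_passthrough(self):
        np.testing.assert_allclose(fdr_adjust([0.123]), [0.123])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(fdr_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_q_at_least_p_and_monotone(self, pvals):
        p = np.asarray(pvals)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_nan_propagates_without_joining_family(self):
        q = fdr_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_oracle([0.01, 0.04]))


class TestBootstrapNull:
    @pytest.fixture(scope="class")
    def ar_dyad(self):
        dyad, _ = generate_dyad(
            make_config(seed=41, duration_s=300.0, signal_amp=0.0,
                        noise=ar_noise_spec()))
        return dyad

    def test_seeded_determinism(self, ar_dyad):
        n1 = bootstrap_null(ar_dyad, "OLS", response_channel=5, B=100, seed=7, max_lag=80)
        n2 = bootstrap_null(ar_dyad, "OLS", response_channel=5, B=100, seed=7, max_lag=80)
        np.testing.assert_array_equal(n1.coefficients, n2.coefficients)
        assert n1.B == 100

    def test_null_distribution_centered_near_zero(self, ar_dyad):
        null = bootstrap_null(ar_dyad, "OLS", response_channel=3, B=200, seed=1, max_lag=80)
        se = null.coefficients.std() / np.sqrt(null.B)
        assert abs(null.coefficients.mean()) < max(3 * se, 0.02)

    def test_small_B_rejected(self, ar_dyad):
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_null(ar_dyad, "OLS", response_channel=1, B=50)

    def test_block_null_wider_than_iid_null_on_autocorrelated_data(self, ar_dyad):
        # the mechanism behind block bootstrapping: sample-wise shuffling
        # destroys serial dependence and understates the null spread
        block = bootstrap_null(ar_dyad, "OLS", response_channel=2, B=150, seed=3, max_lag=80)
        iid = bootstrap_null(ar_dyad, "OLS", response_channel=2, B=150, seed=3, lag=1)
        assert block.coefficients.std() > 1.5 * iid.coefficients.std()


class TestEvaluateDyad:
    def test_table_geometry_and_flags(self, null_dyad):
        dyad = bandpassed(null_dyad)
        res = evaluate_dyad(dyad, B=120, families=("OLS",), seed=5, max_lag=80)
        t = res.table
        assert len(t) == 18
        assert set(t.columns) >= {"dyad", "channel", "region", "family", "rho",
                                  "p", "q", "sig_uncorrected", "sig_fdr"}
        assert t["rho"].between(-1, 1).all()
        assert t["p"].between(0, 1).all()
        # corrected significance never exceeds uncorrected
        assert not (t["sig_fdr"] & ~t["sig_uncorrected"]).any()
        assert (t["region"] == np.where(t["channel"] <= 8, "PFC", "TPJ")).all()

    def test_detection_concentrates_on_coupled_channels(self, coupled_dyad):
        dyad, truth = coupled_dyad
        dyad = bandpassed(dyad)
        res = evaluate_dyad(dyad, B=150, families=("OLS",), seed=6, max_lag=250)
        coupled = {s for _, s in truth.coupled_channel_pairs}
        sub = res.table[res.table["channel"].isin(coupled)]
        other = res.table[~res.table["channel"].isin(coupled)]
        assert (sub["p"] <= 0.01).all()
        # physiological noise shares narrow bands across subjects, so a few
        # uncoupled channels can reach low p; they must stay the minority
        assert (other["p"] <= 0.01).sum() <= 4
        assert sub["rho"].min() > other["rho"].median()

    def test_empty_model_grid_warns_and_returns_empty(self, null_dyad):
        dyad = bandpassed(null_dyad)
        grid = ModelGrid(models={}, skipped=[], boundary=625, families=("OLS",))
        with pytest.warns(UserWarning, match="empty"):
            res = evaluate_dyad(dyad, models=grid, B=120, families=("OLS",), max_lag=80)
        assert res.table.empty

    def test_excluded_channel_reported_na(self, null_dyad):
        dyad = bandpassed(null_dyad)
        grid = fit_all_channels(dyad, families=("OLS",), exclude_channels=(4,))
        res = evaluate_dyad(dyad, models=grid, B=120, families=("OLS",), seed=2, max_lag=80)
        row = res.table[res.table["channel"] == 4].iloc[0]
        assert np.isnan(row["rho"]) and np.isnan(row["p"])
        assert row["note"] == "qc-excluded"
        assert not row["sig_uncorrected"]
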