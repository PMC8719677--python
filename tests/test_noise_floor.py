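"""Envelope fitting, noise levels, growth-rate trend, rank-sum comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noiseprop import noise_floor
from noiseprop.noise_floor import NoiseFloorFit, minimal_variance


def _fit(a, b, cond="c1", q=0.05, n_bins=20, n=1000):
    return NoiseFloorFit(condition_id=cond, a_c=a, b_c=b, quantile=q,
                         n_bins=n_bins, n_points=n)


def synthetic_summaries(
    rng, P=1500, a=0.02, b=0.8, baseline_mean=0.005, n_events=5000, cond="c1"
):
    """Summaries drawn from the estimator's sampling model, no EM involved."""
    m = rng.uniform(3, 8, P)
    v_min = a + b * np.exp(-m)
    v_true = v_min + rng.exponential(baseline_mean, P)
    v_hat = v_true + v_true * np.sqrt(2 / n_events) * rng.standard_normal(P)
    return pd.DataFrame(
        {"promoter_id": [f"p{i}" for i in range(P)], "condition_id": cond,
         "mean": m, "variance": v_hat, "n_used": n_events}
    )


class TestMinimalVariance:
    def test_flat_floor_when_b_zero(self):
        fit = _fit(0.03, 0.0)
        m = np.linspace(0, 10, 7)
        np.testing.assert_allclose(minimal_variance(m, fit), 0.03)

    def test_arithmetic(self):
        assert minimal_variance(0.0, _fit(0.01, 1.0)) == pytest.approx(1.01)

    def test_high_mean_asymptote_is_a_c(self):
        fit = _fit(0.02, 1.0)
        assert abs(minimal_variance(20.0, fit) - 0.02) < 1e-6

    def test_strictly_decreasing_in_mean(self):
        fit = _fit(0.02, 0.5)
        v = minimal_variance(np.linspace(0, 15, 100), fit)
        assert (np.diff(v) < 0).all()

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(1e-4, 1.0),
        b=st.floats(1e-6, 10.0),
        m=st.floats(0.0, 12.0),
        dm=st.floats(1e-3, 5.0),
    )
    def test_envelope_order_and_bounds_property(self, a, b, m, dm):
        """For any valid (a_c, b_c): v_min is above a_c, decreasing, and
        approaches a_c at high mean."""
        fit = _fit(a, b)
        v1, v2 = minimal_variance(m, fit), minimal_variance(m + dm, fit)
        assert v1 > a and v2 > a
        assert v2 < v1
        assert minimal_variance(m + 60.0, fit) == pytest.approx(a, rel=1e-9)


class TestFitNoiseFloor:
    def test_noiseless_points_recovered_exactly(self):
        m = np.linspace(3, 8, 300)
        s = pd.DataFrame(
            {"promoter_id": [f"p{i}" for i in range(300)], "condition_id": "c1",
             "mean": m, "variance": 0.02 + 0.8 * np.exp(-m)}
        )
        fit = noise_floor.fit_noise_floor(s)
        assert fit.a_c == pytest.approx(0.02, rel=1e-3)
        assert fit.b_c == pytest.approx(0.8, rel=1e-3)

    def test_recovery_under_sampling_model(self):
        rng = np.random.default_rng(0)
        s = synthetic_summaries(rng)
        fit = noise_floor.fit_noise_floor(s)
        assert fit.a_c == pytest.approx(0.02, rel=0.10)
        assert fit.b_c == pytest.approx(0.8, rel=0.20)

    def test_binned_method_also_recovers(self):
        rng = np.random.default_rng(1)
        s = synthetic_summaries(rng)
        fit = noise_floor.fit_noise_floor(s, method="binned")
        assert fit.a_c == pytest.approx(0.02, rel=0.10)
        assert fit.b_c == pytest.approx(0.8, rel=0.20)

    def test_median_envelope_sits_above_low_quantile_envelope(self):
        rng = np.random.default_rng(2)
        s = synthetic_summaries(rng, baseline_mean=0.01)
        lo = noise_floor.fit_noise_floor(s, q=0.05)
        mid = noise_floor.fit_noise_floor(s, q=0.5)
        assert mid.a_c > lo.a_c

    def test_envelope_leaves_about_q_points_below(self):
        rng = np.random.default_rng(3)
        s = synthetic_summaries(rng)
        fit = noise_floor.fit_noise_floor(s, q=0.05)
        below = (s["variance"] < minimal_variance(s["mean"].to_numpy(), fit)).mean()
        sd = np.sqrt(0.05 * 0.95 / len(s))
        assert abs(below - 0.05) < 2 * sd + 0.01

    def test_small_bins_merged_with_warning(self):
        rng = np.random.default_rng(4)
        s = synthetic_summaries(rng, P=60)
        with pytest.warns(UserWarning, match="merging"):
            fit = noise_floor.fit_noise_floor(s, method="binned", n_bins=20)
        assert fit.n_bins <= 12

    def test_too_few_promoters_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            noise_floor.fit_noise_floor(synthetic_summaries(rng, P=30))


class TestNoiseLevel:
    def test_on_the_envelope_gives_zero(self):
        fit = _fit(0.05, 0.0)
        s = pd.DataFrame({"mean": [5.0], "variance": [0.05]})
        assert noise_floor.noise_level(s, fit).iloc[0] == pytest.approx(0.0)

    def test_arithmetic(self):
        fit = _fit(0.05, 0.0)
        s = pd.DataFrame({"mean": [5.0], "variance": [0.3]})
        assert noise_floor.noise_level(s, fit).iloc[0] == pytest.approx(0.25)

    def test_mean_independence_after_floor_subtraction(self):
        # constitutive promoters: residual correlation with mean stays small
        corrs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            s = synthetic_summaries(rng)
            fit = noise_floor.fit_noise_floor(s)
            N = noise_floor.noise_level(s, fit)
            corrs.append(np.corrcoef(N, s["mean"])[0, 1])
        assert abs(np.median(corrs)) < 0.05

    def test_negative_values_retained_not_clipped(self):
        fit = _fit(0.05, 0.0)
        s = pd.DataFrame({"mean": [5.0, 6.0], "variance": [0.04, 0.06]})
        levels = noise_floor.noise_level(s, fit)
        assert levels.iloc[0] == pytest.approx(-0.01)


class TestFloorVsGrowthRate:
    def _fits(self, a_values):
        return [_fit(a, 0.5, cond=f"c{i}") for i, a in enumerate(a_values)]

    def test_exact_linear_metadata_recovered(self):
        rates = np.linspace(1.6, 0.1, 8)
        a = 0.16 - 0.08 * rates
        res = noise_floor.floor_vs_growth_rate(self._fits(a), rates)
        assert res["slope"] == pytest.approx(-0.08, abs=1e-6)
        assert res["intercept"] == pytest.approx(0.16, abs=1e-6)
        assert res["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_two_points_warn_trivial_r2(self):
        with pytest.warns(UserWarning, match="two points"):
            res = noise_floor.floor_vs_growth_rate(
                self._fits([0.05, 0.1]), [1.0, 0.2]
            )
        assert res["r2"] == pytest.approx(1.0)

    def test_constant_rates_rejected(self):
        with pytest.raises(ValueError):
            noise_floor.floor_vs_growth_rate(self._fits([0.05, 0.1, 0.2]), [1, 1, 1])

    def test_slope_estimate_within_sampling_theory(self):
        rng = np.random.default_rng(6)
        rates = np.linspace(1.6, 0.1, 8)
        hits = 0
        for _ in range(100):
            a = 0.16 - 0.08 * rates + rng.normal(0, 0.004, 8)
            res = noise_floor.floor_vs_growth_rate(self._fits(a), rates)
            hits += abs(res["slope"] + 0.08) < 2 * res["slope_se"]
        assert hits >= 90


class TestNoiseDistributionTests:
    def test_identical_samples_not_significant(self):
        x = np.linspace(0, 1, 50)
        res = noise_floor.noise_distribution_tests(x, x)
        assert res["p_value"] > 0.99
        assert res["median_a"] == res["median_b"]

    def test_location_shift_detected_with_high_power(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.exponential(0.02, 1500)
            res = noise_floor.noise_distribution_tests(x, x + 0.05)
            assert res["p_value"] < 1e-10

    def test_median_of_symmetric_noise_is_center(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.1, 0.01, 4000)
        res = noise_floor.noise_distribution_tests(x, x)
        assert res["median_a"] == pytest.approx(0.1, abs=0.001)

    def test_undersized_groups_rejected(self):
        with pytest.raises(ValueError):
            noise_floor.noise_distribution_tests(np.ones(5), np.ones(50))
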