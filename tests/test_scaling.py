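import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stomanet.network import mst_total_length
from stomanet.scaling import (
    BetaEstimate,
    UndefinedStatisticError,
    aggregate_beta,
    beta_hat,
    expected_mst_length,
    fit_predicted_vs_observed,
    origin_slope,
    pearson_with_ci,
)
from stomanet.simulate import simulate_csr

from conftest import UNIT


class TestScalingLaw:
    @pytest.mark.parametrize(
        "beta,n,area,expected",
        [(0.64, 100, 1.0, 6.4), (0.63, 4, 1.0, 1.26), (0.7, 0, 1.0, 0.0)],
    )
    def test_expected_length(self, beta, n, area, expected):
        assert expected_mst_length(beta, n, area) == pytest.approx(expected)

    def test_expected_length_rejects_bad_domain(self):
        with pytest.raises(ValueError):
            expected_mst_length(0.64, 10, 0.0)
        with pytest.raises(ValueError):
            expected_mst_length(-0.1, 10, 1.0)

    def test_beta_hat_inverse_example(self):
        assert beta_hat(6.4, 100, 1.0) == pytest.approx(0.64)

    def test_beta_hat_undefined_below_two_points(self):
        with pytest.raises(UndefinedStatisticError):
            beta_hat(0.0, 1, 1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        beta=st.floats(0.01, 10.0),
        n=st.integers(2, 100_000),
        area=st.floats(1e-4, 1e4),
    )
    def test_round_trip_identity(self, beta, n, area):
        assert beta_hat(expected_mst_length(beta, n, area), n, area) == pytest.approx(
            beta, rel=1e-12
        )

    def test_beta_hat_scale_invariant_on_real_patterns(self, rng):
        p = simulate_csr(80, UNIT, rng)
        length = mst_total_length(p.points)
        b = beta_hat(length, p.n, p.window.area())
        for s in (0.5, 2.0, 30.0):
            q = p.scaled(s)
            b_s = beta_hat(mst_total_length(q.points), q.n, q.window.area())
            assert b_s == pytest.approx(b, rel=1e-9)

    def test_beta_hat_rigid_motion_invariant(self, rng):
        p = simulate_csr(80, UNIT, rng)
        b = beta_hat(mst_total_length(p.points), p.n, 1.0)
        q = p.translated(5.0, -2.0)
        assert beta_hat(mst_total_length(q.points), q.n, 1.0) == pytest.approx(b, rel=1e-9)


class TestAggregateBeta:
    def test_mean_of_two(self):
        est = [BetaEstimate(0.7, 10, 1.0, 0.7 * np.sqrt(10)), BetaEstimate(0.8, 10, 1.0, 0.8 * np.sqrt(10))]
        sb = aggregate_beta(est)
        assert sb.mean_beta == pytest.approx(0.75)
        assert sb.ci_low <= sb.mean_beta <= sb.ci_high

    def test_degenerate_spread_collapses_ci(self):
        sb = aggregate_beta([0.64] * 5)
        assert (sb.ci_low, sb.mean_beta, sb.ci_high) == (0.64, 0.64, 0.64)

    def test_t_interval_matches_scipy(self, rng):
        values = rng.normal(0.7, 0.05, size=30)
        sb = aggregate_beta(values)
        lo, hi = stats.t.interval(
            0.95, df=29, loc=values.mean(), scale=stats.sem(values)
        )
        assert sb.ci_low == pytest.approx(lo) and sb.ci_high == pytest.approx(hi)

    def test_bootstrap_ci_brackets_mean_and_is_seeded(self, rng):
        values = rng.normal(0.7, 0.05, size=40)
        a = aggregate_beta(values, method="bootstrap", seed=11)
        b = aggregate_beta(values, method="bootstrap", seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low < a.mean_beta < a.ci_high

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            aggregate_beta([0.7])

    def test_csr_study_mean_within_its_own_t_interval(self, rng):
        """Samples drawn under CSR at one n: the t-CI covers the empirical CSR
        reference value computed from an independent batch."""
        n = 120
        batch = [
            beta_hat(mst_total_length(simulate_csr(n, UNIT, r).points), n, 1.0)
            for r in rng.spawn(60)
        ]
        reference = np.mean(
            [
                beta_hat(mst_total_length(simulate_csr(n, UNIT, r).points), n, 1.0)
                for r in rng.spawn(60)
            ]
        )
        sb = aggregate_beta(batch)
        assert sb.ci_low <= reference <= sb.ci_high


class TestFitStatistics:
    def _samples(self, rng, n_samples=40, beta=0.7, noise_sd=0.0):
        ns = rng.integers(5, 800, size=n_samples)
        areas = np.ones(n_samples)
        lengths = beta * np.sqrt(ns * areas)
        if noise_sd:
            lengths = lengths * (1 + rng.normal(0, noise_sd, size=n_samples))
        return list(zip(lengths, ns, areas))

    def test_perfect_fit_r2_one(self, rng):
        fit = fit_predicted_vs_observed(self._samples(rng), beta_ref=0.7)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_constant_offset_degrades_r2(self, rng):
        samples = [(L + 0.5, n, a) for L, n, a in self._samples(rng)]
        fit = fit_predicted_vs_observed(samples, beta_ref=0.7)
        assert fit.r_squared < 1.0

    def test_ten_percent_noise_keeps_r2_high(self, rng):
        samples = self._samples(rng, n_samples=120, noise_sd=0.10)
        fit = fit_predicted_vs_observed(samples, beta_ref=0.7)
        assert fit.r_squared >= 0.9

    def test_zero_variance_observed_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            fit_predicted_vs_observed([(2.0, 4, 1.0)] * 5, beta_ref=0.7)

    def test_origin_slope_recovers_beta(self, rng):
        slope = origin_slope(*zip(*[(L, n, a) for L, n, a in self._samples(rng, beta=0.66)]))
        assert slope == pytest.approx(0.66, rel=1e-9)


class TestPearsonWithCI:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, lo, hi = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _, _ = pearson_with_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_ci_matches_fisher_z_oracle(self, rng):
        """Closed-form Fisher z interval computed directly."""
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r, lo, hi = pearson_with_ci(x, y)
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(50 - 3)
        assert lo == pytest.approx(np.tanh(z - half), abs=1e-9)
        assert hi == pytest.approx(np.tanh(z + half), abs=1e-9)

    def test_independent_draws_ci_covers_zero(self, rng):
        covered = 0
        reps = 40
        for r_ in rng.spawn(reps):
            x = r_.normal(size=1000)
            y = r_.normal(size=1000)
            r, lo, hi = pearson_with_ci(x, y)
            assert abs(r) < 0.15
            covered += lo <= 0.0 <= hi
        assert covered / reps >= 0.9

    def test_zero_variance_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_with_ci([1.0] * 6, list(range(6)))
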