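"""The LMS distribution: centile and z-score transforms, likelihood, fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from growthref import (
    ConvergenceError,
    DomainError,
    FitOptions,
    LMSTriple,
    MeasurementSample,
    PercentileSpec,
    ValidationError,
    centile,
    fit_group,
    loglikelihood,
    round_half_away,
    zscore,
)

BOYS_H12 = LMSTriple(3.020, 149.72, 0.069)


def lms_quantile_raw(lam, mu, sigma, p):
    """Direct evaluation of the general-L formula (independent oracle)."""
    z = stats.norm.ppf(p)
    return mu * (1.0 + lam * sigma * z) ** (1.0 / lam)


class TestCentile:
    @pytest.mark.parametrize(
        "params, p, expected",
        [
            (BOYS_H12, 0.90, 161.93),
            (BOYS_H12, 0.03, 126.98),
            (LMSTriple(0.531, 37.38, 0.246), 0.03, 21.98),
            (LMSTriple(0.0, 100.0, 0.1), 0.975, 121.65),
        ],
    )
    def test_published_and_lognormal_values(self, params, p, expected):
        assert round_half_away(centile(params, p), 2) == pytest.approx(expected)

    def test_lognormal_limit_agrees_with_small_lambda_formula(self):
        # the L != 0 expression at L = 1e-8 is the oracle for the log form
        for p in (0.03, 0.25, 0.75, 0.975):
            exact = centile(LMSTriple(0.0, 100.0, 0.1), p)
            near = lms_quantile_raw(1e-8, 100.0, 0.1, p)
            assert abs(exact - near) < 1e-6

    def test_median_is_mu_exactly(self):
        for params in (BOYS_H12, LMSTriple(-1.879, 17.48, 0.125), LMSTriple(0, 5, 0.3)):
            assert centile(params, 0.5) == params.mu

    def test_continuity_at_zero_lambda(self):
        mu, sigma = 37.0, 0.2
        for p in np.linspace(0.01, 0.99, 25):
            a = centile(LMSTriple(1e-6, mu, sigma), p)
            b = centile(LMSTriple(0.0, mu, sigma), p)
            assert abs(a - b) < 1e-6 * mu

    def test_strictly_increasing_in_p(self):
        ps = np.linspace(0.01, 0.99, 50)
        for params in (BOYS_H12, LMSTriple(-1.879, 17.48, 0.125)):
            values = [centile(params, p) for p in ps]
            assert all(b > a for a, b in zip(values, values[1:]))

    def test_support_violation_names_percentile(self):
        with pytest.raises(DomainError, match="P97.5"):
            centile(LMSTriple(-2.0, 20.0, 0.5), PercentileSpec.from_p(0.975))

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValidationError):
            LMSTriple(float("nan"), 100.0, 0.1)
        with pytest.raises(ValidationError):
            LMSTriple(1.0, -5.0, 0.1)


class TestPercentileSpec:
    def test_z_is_full_precision_quantile(self):
        spec = PercentileSpec.from_p(0.90)
        assert spec.z == pytest.approx(1.2815515655446004, abs=1e-12)
        assert PercentileSpec.from_p(0.5).z == 0.0

    def test_two_digit_z_rejected(self):
        with pytest.raises(ValidationError):
            PercentileSpec(p=0.90, z=1.28, label="P90")

    def test_label_round_trip(self):
        assert PercentileSpec.from_label("P97.5").p == pytest.approx(0.975)
        assert PercentileSpec.from_p(0.03).label == "P3"


class TestZscore:
    def test_median_maps_to_zero(self):
        assert zscore(BOYS_H12.mu, BOYS_H12) == 0.0

    def test_inverse_of_published_p3_cell(self):
        # root of centile(p) = 126.98 is p = 0.03 up to printed rounding
        assert zscore(126.98, BOYS_H12) == pytest.approx(-1.881, abs=0.002)

    def test_log_form_identity(self):
        params = LMSTriple(0.0, 80.0, 0.2)
        assert zscore(params.mu * math.exp(params.sigma), params) == pytest.approx(1.0)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(DomainError):
            zscore(0.0, BOYS_H12)

    @settings(derandomize=True, max_examples=60)
    @given(
        lam=st.floats(-3, 3),
        sigma=st.floats(0.01, 0.4),
        p=st.floats(0.01, 0.99),
    )
    def test_round_trip_recovers_normal_quantile(self, lam, sigma, p):
        params = LMSTriple(lam, 50.0, sigma)
        spec = PercentileSpec.from_p(p)
        if not params.supports(spec.z):
            return
        assert abs(zscore(centile(params, spec), params) - spec.z) < 1e-9

    @settings(derandomize=True, max_examples=60)
    @given(
        lam=st.floats(-3, 3),
        sigma=st.floats(0.01, 0.4),
        y1=st.floats(10.0, 200.0),
        y2=st.floats(10.0, 200.0),
    )
    def test_strictly_increasing_in_y(self, lam, sigma, y1, y2):
        if y1 == y2:
            return
        lo, hi = sorted((y1, y2))
        params = LMSTriple(lam, 50.0, sigma)
        assert zscore(lo, params) < zscore(hi, params)


class TestLoglikelihood:
    def test_closed_form_single_observation(self):
        # y = M with L = 1: -ln M - ln S - 0.5 ln 2 pi
        value = loglikelihood([100.0], LMSTriple(1.0, 100.0, 0.1))
        assert value == pytest.approx(-3.2215, abs=5e-5)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(30, 60, size=40)
        params = LMSTriple(0.5, 45.0, 0.15)
        assert loglikelihood(y, params) == pytest.approx(
            loglikelihood(y[::-1].copy(), params)
        )

    def test_symmetric_sample_prefers_central_mu(self):
        m, d = 40.0, 0.1
        y = [m * (1 - d), m * (1 + d)]
        at_center = loglikelihood(y, LMSTriple(1.0, m, 0.1))
        assert at_center > loglikelihood(y, LMSTriple(1.0, m * (1 - d), 0.1))
        assert at_center > loglikelihood(y, LMSTriple(1.0, m * (1 + d), 0.1))


class TestFitGroup:
    def test_lognormal_data_has_near_zero_power(self):
        rng = np.random.default_rng(11)
        y = np.exp(rng.normal(math.log(40.0), 0.15, size=2000))
        fit = fit_group(MeasurementSample(y))
        assert abs(fit.lam) <= 0.3
        assert fit.mu == pytest.approx(40.0, rel=0.02)

    def test_beats_brute_force_grid(self):
        rng = np.random.default_rng(321)
        z = rng.standard_normal(50)
        true = LMSTriple(0.5, 40.0, 0.2)
        y = true.mu * (1 + true.lam * true.sigma * z) ** (1 / true.lam)
        sample = MeasurementSample(y)
        fit = fit_group(sample)

        # independent brute-force oracle: best point on a 50^3 grid
        def oracle_loglik(lam, mu, sigma):
            if abs(lam) < 1e-7:
                zz = np.log(y / mu) / sigma
            else:
                zz = ((y / mu) ** lam - 1) / (lam * sigma)
            return np.sum(
                (lam - 1) * np.log(y)
                - lam * np.log(mu)
                - np.log(sigma)
                - 0.5 * np.log(2 * np.pi)
                - 0.5 * zz**2
            )

        cv = float(np.std(y) / np.mean(y))
        q40, q60 = np.quantile(y, [0.40, 0.60])
        best = -np.inf
        for lam in np.linspace(-3, 3, 50):
            for mu in np.linspace(q40, q60, 50):
                for sigma in np.linspace(cv / 2, cv * 2, 50):
                    best = max(best, oracle_loglik(lam, mu, sigma))
        assert loglikelihood(sample, fit) >= best - 1e-6

    def test_deterministic_given_sample(self):
        rng = np.random.default_rng(9)
        y = rng.uniform(140, 180, size=200)
        a = fit_group(MeasurementSample(y))
        b = fit_group(MeasurementSample(y.copy()))
        assert (a.lam, a.mu, a.sigma) == (b.lam, b.mu, b.sigma)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            fit_group(MeasurementSample(np.full(50, 42.0)))

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValidationError, match="minimum"):
            fit_group(MeasurementSample(np.linspace(10, 20, 10)))

    def test_convergence_error_carries_last_iterate(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(30, 70, size=100)
        with pytest.raises(ConvergenceError) as err:
            fit_group(MeasurementSample(y), FitOptions(max_iterations=3))
        assert err.value.last_iterate is not None
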