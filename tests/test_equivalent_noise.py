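"""Equivalent-noise algebra, uncertainty propagation and calibration."""
import math

import numpy as np
import pytest
from scipy import optimize, stats

from vplearn.equivalent_noise import (
    K_GAUSSIAN,
    ENInputs,
    EquivalentNoiseModel,
    estimate_en_parameters,
    predicted_sigma_obs,
    threshold_to_sigma,
)
from vplearn.staircase import ThresholdEstimate

PI4 = math.pi / 4


class TestForwardModel:
    @pytest.mark.parametrize(
        "sigma_int, sigma_ext, eta, expected",
        [(0.0, 0.3, 1.0, 0.3), (0.3, 0.4, 1.0, 0.5), (0.3, 0.4, 4.0, 0.25)],
    )
    def test_quadrature_and_pooling(self, sigma_int, sigma_ext, eta, expected):
        assert predicted_sigma_obs(sigma_int, sigma_ext, eta) == pytest.approx(expected)

    def test_nonpositive_eta_raises(self):
        with pytest.raises(ValueError):
            predicted_sigma_obs(0.1, 0.1, 0.0)


class TestTwoPointEstimate:
    def test_identity_point(self):
        est = estimate_en_parameters(
            ENInputs(sigma_obs0=0.12, delta_sigma_obs0=0.0,
                     sigma_extH=PI4, delta_sigma_extH=0.0, sigma_obsH=PI4)
        )
        assert est.eta == pytest.approx(1.0)
        assert est.sigma_int == pytest.approx(0.12)

    def test_factor_of_two(self):
        est = estimate_en_parameters(
            ENInputs(sigma_obs0=0.1, delta_sigma_obs0=0.0,
                     sigma_extH=math.pi / 2, delta_sigma_extH=0.0, sigma_obsH=PI4)
        )
        assert est.eta == pytest.approx(4.0)
        assert est.sigma_int == pytest.approx(0.2)

    def test_delta_eta_closed_form(self):
        est = estimate_en_parameters(
            ENInputs(sigma_obs0=0.1, delta_sigma_obs0=0.01,
                     sigma_extH=math.pi / 2, delta_sigma_extH=0.05, sigma_obsH=PI4)
        )
        assert est.delta_eta == pytest.approx(0.2546, abs=1e-4)

    def test_propagation_against_monte_carlo_oracle(self):
        """First-order deltas agree with a Monte-Carlo propagation oracle
        (resample the inputs from Gaussians, take the SD of the outputs)
        within 5% for small relative input errors."""
        inputs = ENInputs(sigma_obs0=0.1, delta_sigma_obs0=0.004,
                          sigma_extH=math.pi / 2, delta_sigma_extH=0.03,
                          sigma_obsH=PI4)
        est = estimate_en_parameters(inputs)
        rng = np.random.default_rng(99)
        n = 200_000
        s0 = rng.normal(inputs.sigma_obs0, inputs.delta_sigma_obs0, n)
        sh = rng.normal(inputs.sigma_extH, inputs.delta_sigma_extH, n)
        eta_mc = sh**2 / inputs.sigma_obsH**2
        sint_mc = s0 * np.sqrt(eta_mc)
        assert est.delta_eta == pytest.approx(eta_mc.std(), rel=0.05)
        assert est.delta_sigma_int == pytest.approx(sint_mc.std(), rel=0.05)

    def test_zero_high_noise_raises(self):
        with pytest.raises(ValueError):
            estimate_en_parameters(
                ENInputs(sigma_obs0=0.1, delta_sigma_obs0=0.0,
                         sigma_extH=0.0, delta_sigma_extH=0.0)
            )

    def test_regime_diagnostic(self):
        marginal = estimate_en_parameters(
            ENInputs(sigma_obs0=0.9, delta_sigma_obs0=0.0,
                     sigma_extH=1.0, delta_sigma_extH=0.0, sigma_obsH=PI4)
        )
        assert not marginal.high_noise_regime_ok
        safe = estimate_en_parameters(
            ENInputs(sigma_obs0=0.05, delta_sigma_obs0=0.0,
                     sigma_extH=1.5, delta_sigma_extH=0.0, sigma_obsH=PI4)
        )
        assert safe.high_noise_regime_ok


class TestInvariants:
    def test_round_trip_zero_noise(self):
        inputs = ENInputs(sigma_obs0=0.13, delta_sigma_obs0=0.0,
                          sigma_extH=1.2, delta_sigma_extH=0.0)
        est = estimate_en_parameters(inputs)
        assert predicted_sigma_obs(est.sigma_int, 0.0, est.eta) == pytest.approx(
            inputs.sigma_obs0, abs=1e-12
        )

    def test_high_noise_consistency_bound(self):
        inputs = ENInputs(sigma_obs0=0.13, delta_sigma_obs0=0.0,
                          sigma_extH=1.2, delta_sigma_extH=0.0)
        est = estimate_en_parameters(inputs)
        predicted = predicted_sigma_obs(est.sigma_int, inputs.sigma_extH, est.eta)
        assert predicted >= inputs.sigma_obsH
        # equality in the limit sigma_extH >> sigma_int
        wide = estimate_en_parameters(
            ENInputs(sigma_obs0=1e-4, delta_sigma_obs0=0.0,
                     sigma_extH=3.0, delta_sigma_extH=0.0)
        )
        assert predicted_sigma_obs(wide.sigma_int, 3.0, wide.eta) == pytest.approx(
            PI4, rel=1e-6
        )

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_scale_equivariance(self, c):
        base = ENInputs(sigma_obs0=0.1, delta_sigma_obs0=0.01,
                        sigma_extH=1.2, delta_sigma_extH=0.05, sigma_obsH=PI4)
        scaled = ENInputs(sigma_obs0=c * 0.1, delta_sigma_obs0=c * 0.01,
                          sigma_extH=c * 1.2, delta_sigma_extH=c * 0.05,
                          sigma_obsH=c * PI4)
        a, b = estimate_en_parameters(base), estimate_en_parameters(scaled)
        assert b.eta == pytest.approx(a.eta)
        assert b.sigma_int == pytest.approx(c * a.sigma_int)


class TestCalibration:
    def test_identity_with_k_one(self):
        assert threshold_to_sigma(0.3, 0.02, calibration_k=1.0) == (0.3, 0.02)

    def test_zero_threshold(self):
        sigma, delta = threshold_to_sigma(0.0, 0.0)
        assert sigma == 0.0 and delta == 0.0

    def test_default_k_against_numeric_cdf_oracle(self):
        """k solves Phi(k) = sqrt(1/2); verify against a root-find on the
        Gaussian CDF rather than the quantile function."""
        k_oracle = optimize.brentq(lambda x: stats.norm.cdf(x) - math.sqrt(0.5), 0, 2)
        assert K_GAUSSIAN == pytest.approx(k_oracle, abs=1e-9)
        sigma, _ = threshold_to_sigma(k_oracle, 0.0)
        assert sigma == pytest.approx(1.0, abs=1e-3)

    def test_degree_conversion(self):
        sigma, _ = threshold_to_sigma(45.0, 0.0, calibration_k=1.0, degrees=True)
        assert sigma == pytest.approx(PI4)

    def test_nonpositive_k_raises(self):
        with pytest.raises(ValueError):
            threshold_to_sigma(0.3, 0.0, calibration_k=0.0)

    def test_sigma_int_invariant_to_k_eta_scales_with_k_squared(self):
        """Algebraic identities of the calibration: the sigma_int estimate
        cancels k; the eta estimate scales as k^2."""
        zero = ThresholdEstimate(threshold=0.06, spread=0.01, n_reversals_used=14)
        high = ThresholdEstimate(threshold=1.8, spread=0.2, n_reversals_used=14)
        res_default = EquivalentNoiseModel.from_thresholds(zero, high).fit()
        res_literal = EquivalentNoiseModel.from_thresholds(
            zero, high, calibration_k=1.0
        ).fit()
        assert res_default.sigma_int == pytest.approx(res_literal.sigma_int, rel=1e-12)
        # eta scales as k^2 (literal k = 1 vs default k < 1)
        assert res_default.eta / res_literal.eta == pytest.approx(
            K_GAUSSIAN**2, rel=1e-12
        )

    def test_results_series_schema(self):
        zero = ThresholdEstimate(threshold=0.06, spread=0.01, n_reversals_used=14)
        high = ThresholdEstimate(threshold=1.8, spread=0.2, n_reversals_used=14)
        series = EquivalentNoiseModel.from_thresholds(zero, high).fit().to_series()
        assert list(series.index) == [
            "sigma_obs0", "delta_sigma_obs0", "sigma_extH", "delta_sigma_extH",
            "sigma_obsH", "eta", "delta_eta", "sigma_int", "delta_sigma_int",
            "regime_ok",
        ]
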