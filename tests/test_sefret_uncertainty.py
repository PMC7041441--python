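"""Analytic precision bounds, decomposition, bias and the photon budget."""

import math

import numpy as np
import pytest

from fretbudget import (
    Background,
    SamplePopulation,
    channel_means,
    delta_sigma,
    expected_bias,
    fisher_crlb,
    photon_budget,
    predicted_sigma,
    sigma_decomposition,
    sigma_sweep,
    unmix,
)
from fretbudget.sefret_core import FretSystem, ParameterDomainError, SYSTEM_CONFOCAL
from fretbudget.sefret_uncertainty import _gradient, power_series_grid


class TestDeltaSigma:
    def test_frozen_reference_values(self, half_pop, confocal_sys):
        # hand-verified by independent finite-difference error propagation
        assert delta_sigma(half_pop, which="dfret").sigma_tilde == pytest.approx(
            0.530330, rel=1e-5
        )
        assert delta_sigma(half_pop, which="afret").sigma_tilde == pytest.approx(
            1.5, rel=1e-9
        )
        assert delta_sigma(half_pop, confocal_sys, which="dfret").sigma_tilde == pytest.approx(
            3.569839, rel=1e-5
        )
        assert delta_sigma(half_pop, confocal_sys, which="afret").sigma_tilde == pytest.approx(
            9.457470, rel=1e-5
        )

    def test_dfret_infinitely_precise_at_zero_transfer(self):
        pop = SamplePopulation(100, 100, 0, efficiency=0.0)
        assert delta_sigma(pop, which="dfret").sigma_tilde == 0.0

    @pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
    def test_exposure_invariance(self, half_pop, confocal_sys, lam):
        base = delta_sigma(half_pop, confocal_sys, exposure=1.0, which="dfret")
        scaled = delta_sigma(half_pop, confocal_sys, exposure=lam, which="dfret")
        assert scaled.sigma_tilde == pytest.approx(base.sigma_tilde, rel=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, confocal_sys):
        pop = SamplePopulation.from_fractions(0.37, 0.6, 0.8)
        mu = channel_means(pop, confocal_sys).as_array()
        for which, attr in (("dfret", "dfret"), ("afret", "afret")):
            grad = _gradient(mu, confocal_sys, which)
            for i in range(3):
                h = 1e-6 * mu[i]
                up, dn = mu.copy(), mu.copy()
                up[i] += h
                dn[i] -= h
                fd = (
                    getattr(unmix(tuple(up), confocal_sys), attr)
                    - getattr(unmix(tuple(dn), confocal_sys), attr)
                ) / (2 * h)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-12)

    def test_afret_undefined_without_acceptor_signal(self):
        pop = SamplePopulation(100, 0, 0, efficiency=0.5)
        mu = channel_means(pop)
        assert mu.i_aa > 0  # population always has acceptors; craft a zero directly
        with pytest.raises(ParameterDomainError):
            _gradient(np.array([100.0, 50.0, 0.0]), FretSystem(), "afret")


class TestFisherOracle:
    def test_fisher_equals_delta_at_200_random_interior_points(self):
        rng = np.random.default_rng(42)
        systems = [
            FretSystem(),
            SYSTEM_CONFOCAL,
            FretSystem(der=1.07, aer=0.29, eta=0.015, epsilon=42.0),
        ]
        for _ in range(200):
            e = rng.uniform(0.05, 0.95)
            f_d = rng.uniform(0.1, 1.0)
            f_a = rng.uniform(0.1, 1.0)
            sys = systems[rng.integers(len(systems))]
            # without background the plug-in estimator is the exact MLE of the
            # 3-parameter Poisson channel model, so the two routes coincide
            which = "dfret" if rng.random() < 0.5 else "afret"
            pop = SamplePopulation.from_fractions(e, f_d, f_a)
            a = delta_sigma(pop, sys, which=which).sigma_tilde
            b = fisher_crlb(pop, sys, which=which).sigma_tilde
            assert b == pytest.approx(a, rel=1e-6)

    def test_fisher_matrix_positive_definite_at_interior_point(self):
        from fretbudget.sefret_uncertainty import _fisher_means_and_jacobian

        pop = SamplePopulation.from_fractions(0.5, 1.0, 1.0)
        theta = np.array([0.5, 100.0, 1.0])
        mu, jac = _fisher_means_and_jacobian(theta, FretSystem(), np.zeros(3), "dfret")
        j = (jac / mu[:, None]).T @ jac
        assert np.allclose(j, j.T)
        assert np.all(np.linalg.eigvalsh(j) > 0)


class TestDecomposition:
    def test_ideal_system_is_pure_efficiency_term(self, half_pop):
        res = delta_sigma(half_pop, which="afret")
        assert res.components == pytest.approx((res.sigma_tilde, 0.0, 0.0))

    def test_crosstalk_without_background_has_zero_background_term(self, half_pop, confocal_sys):
        sig_e, sig_sbt, sig_b = sigma_decomposition(half_pop, confocal_sys, which="dfret")
        assert sig_b == 0.0 and sig_sbt > 0.0

    @pytest.mark.parametrize("which", ["dfret", "afret"])
    @pytest.mark.parametrize("beta", [0.0, 0.2, 0.5])
    def test_sum_of_squares_identity(self, confocal_sys, which, beta):
        bg = Background(beta=beta) if beta else Background()
        for e in power_series_grid(9, 0.9)[1:]:
            pop = SamplePopulation.from_fractions(float(e), 0.7, 0.9)
            res = delta_sigma(pop, confocal_sys, 1.0, bg, which)
            total_sq = res.sigma_e**2 + res.sigma_sbt**2 + res.sigma_b**2
            assert total_sq == pytest.approx(res.sigma_tilde**2, rel=1e-9)


class TestBias:
    def test_unbiased_without_background(self, half_pop, confocal_sys):
        for which in ("dfret", "afret"):
            assert expected_bias(half_pop, confocal_sys, which=which) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_bias_magnitude_grows_with_background(self):
        for e in (0.2, 0.4, 0.6):
            pop = SamplePopulation.from_fractions(e, 1.0, 1.0)
            biases = [
                abs(expected_bias(pop, bg=Background(beta=b), which="dfret"))
                for b in (0.0, 0.2, 0.4, 0.6)
            ]
            assert all(b2 >= b1 for b1, b2 in zip(biases, biases[1:]))


class TestPhotonBudget:
    def test_worked_examples(self):
        assert photon_budget(3, 0.05) == 3600
        assert photon_budget(0.5, 0.05) == 100
        assert photon_budget(10, 0.05) == 40000
        assert photon_budget(1.0, 1.0) == 1

    def test_predicted_sigma_examples(self):
        assert predicted_sigma(0.3, 1000) == pytest.approx(0.00949, abs=5e-5)
        assert predicted_sigma(0.7, 1) == 0.7

    @pytest.mark.parametrize("n", [10, 100, 10_000])
    def test_round_trip(self, n):
        assert photon_budget(2.7, predicted_sigma(2.7, n)) == n

    def test_domain_errors(self):
        with pytest.raises(ParameterDomainError):
            photon_budget(0.0, 0.05)
        with pytest.raises(ParameterDomainError):
            photon_budget(1.0, -1.0)
        with pytest.raises(ParameterDomainError):
            predicted_sigma(1.0, 0.5)


class TestSweep:
    def test_dfret_precise_at_both_efficiency_extremes(self):
        df = sigma_sweep(np.array([0.0, 0.5, 0.99]), 1.0, 1.0, which="dfret")
        s = df["sigma_tilde"].to_numpy()
        assert s[0] == 0.0
        assert s[2] < 0.25 * s[1]  # collapsing again toward the E -> 1 boundary

    def test_dfret_snr_never_worse_than_afret_without_crosstalk(self):
        # the estimands differ (f_D E vs f_A E), so the meaningful pointwise
        # comparison is the signal-to-noise ratio estimand/sigma
        grid = power_series_grid(16, 0.95)[1:]
        for f_d in (0.1, 0.5, 1.0):
            for f_a in (0.1, 0.5, 1.0):
                d = sigma_sweep(grid, f_d, f_a, which="dfret")["sigma_tilde"].to_numpy()
                a = sigma_sweep(grid, f_d, f_a, which="afret")["sigma_tilde"].to_numpy()
                snr_d = f_d * grid / d
                snr_a = f_a * grid / a
                assert (snr_d >= snr_a * (1 - 1e-12)).all()
                if f_d == f_a:  # identical estimands: sigma itself comparable
                    assert (d <= a * (1 + 1e-12)).all()

    def test_crosstalk_degrades_precision_pointwise(self, confocal_sys):
        grid = power_series_grid(16, 0.95)[1:]
        ideal = sigma_sweep(grid, 0.5, 1.0, which="dfret")["sigma_tilde"]
        xt = sigma_sweep(grid, 0.5, 1.0, sys=confocal_sys, which="dfret")["sigma_tilde"]
        assert (xt.to_numpy() >= ideal.to_numpy()).all()

    def test_full_sweep_is_finite_and_deterministic(self):
        a = sigma_sweep(128, 0.5, 0.8, which="afret")
        b = sigma_sweep(128, 0.5, 0.8, which="afret")
        assert len(a) == 128
        assert np.isfinite(a["sigma_tilde"]).all()
        assert (a["sigma_tilde"] == b["sigma_tilde"]).all()
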