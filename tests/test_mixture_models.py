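"""Mixture pmfs against quadrature oracles, spectrum likelihood, fitting, LRT."""

import numpy as np
import pytest
from scipy import integrate, stats

from recurrency.mixture_models import (
    GammaLaw,
    fit_model,
    gamma_poisson_pmf,
    likelihood_ratio_test,
    model_comparison_table,
    n_params_for,
    spectrum_log_likelihood,
    two_process_pmf,
)
from recurrency.synthetic_data import simulate_spectra


def quad_gamma_expectation(f, shape: float) -> float:
    """E[f(alpha)] under the mean-1 gamma via the u = alpha**shape substitution.

    Substituting alpha = u**(1/k) removes the alpha**(k-1) endpoint
    singularity exactly, leaving a smooth integrand for adaptive quadrature
    even at small shapes.
    """
    from scipy.special import gammaln

    k = shape
    log_const = (k - 1) * np.log(k) - gammaln(k)

    def g(u):
        a = u ** (1.0 / k)
        return f(a) * np.exp(log_const - k * a)

    val, err = integrate.quad(g, 0, np.inf, limit=400, epsabs=1e-13, epsrel=1e-12)
    return val


def gamma_poisson_quad(x: int, mu: float, shape: float) -> float:
    return quad_gamma_expectation(lambda a: stats.poisson.pmf(x, mu * a), shape)


def two_process_quad(x: int, mu: float, shape: float, eps: float) -> float:
    return quad_gamma_expectation(
        lambda a: stats.poisson.pmf(x, mu * (eps + (1 - eps) * a)), shape
    )


class TestGammaLaw:
    def test_mean_is_one_by_quadrature(self):
        for shape in (0.05, 0.5, 3.0):
            mean = quad_gamma_expectation(lambda a: a, shape)
            assert mean == pytest.approx(1.0, abs=1e-6)

    def test_variance_is_inverse_shape(self):
        law = GammaLaw(0.25)
        assert law.variance == 4.0

    def test_positive_shape_required(self):
        with pytest.raises(ValueError):
            GammaLaw(0.0)


class TestGammaPoissonPmf:
    def test_zero_class_closed_form(self):
        mu, k = 0.3, 0.2
        assert gamma_poisson_pmf(0, mu, k) == pytest.approx((k / (k + mu)) ** k)

    def test_large_shape_degenerates_to_poisson(self):
        xs = np.arange(8)
        nb = gamma_poisson_pmf(xs, 0.5, 1e8)
        assert np.abs(nb - stats.poisson.pmf(xs, 0.5)).max() < 1e-6

    def test_matches_quadrature(self):
        mu, k = 0.3, 0.2
        for x in range(11):
            assert gamma_poisson_pmf(x, mu, k) == pytest.approx(
                gamma_poisson_quad(x, mu, k), abs=1e-8
            )

    def test_normalisation_over_parameter_grid(self):
        # heavy NB tails at tiny shape carry mass beyond any truncation, so
        # normalisation is checked as truncated sum + exact tail mass = 1
        xs = np.arange(201)
        for mu in (1e-4, 1e-2, 0.1):
            for k in (1e-5, 1e-3, 0.5, 50.0):
                total = gamma_poisson_pmf(xs, mu, k).sum() + stats.nbinom.sf(200, k, k / (k + mu))
                assert total == pytest.approx(1.0, abs=1e-9)
                if k >= 0.01:  # tails are light enough for the truncated sum alone
                    assert gamma_poisson_pmf(xs, mu, k).sum() == pytest.approx(1.0, abs=1e-6)

    def test_log_space_stability_extreme_shape(self):
        p = gamma_poisson_pmf(np.arange(51), 0.01, 1e-6)
        assert np.all(np.isfinite(p)) and np.all(p >= 0)


class TestTwoProcessPmf:
    def test_eps_one_is_poisson(self):
        mu = 0.002
        assert two_process_pmf(1, mu, 0.3, 1.0) == pytest.approx(mu * np.exp(-mu))

    def test_eps_zero_is_gamma_poisson(self):
        xs = np.arange(6)
        assert np.allclose(
            two_process_pmf(xs, 0.3, 0.2, 0.0), gamma_poisson_pmf(xs, 0.3, 0.2), atol=1e-12
        )

    def test_zero_class_is_product_of_component_zero_classes(self):
        mu, k, eps = 0.4, 0.15, 0.7
        expected = np.exp(-mu * eps) * (k / (k + mu * (1 - eps))) ** k
        assert two_process_pmf(0, mu, k, eps) == pytest.approx(expected, rel=1e-12)

    def test_study_scale_variable_process_zero_class_exceeds_99_percent(self):
        # shape ~ 4e-4 concentrates the variable process on a tiny site fraction
        p0 = gamma_poisson_pmf(0, 0.001183 * (1 - 0.96), 4e-4)
        assert p0 > 0.99

    def test_matches_quadrature(self):
        mu, k, eps = 0.3, 0.2, 0.6
        for x in range(9):
            assert two_process_pmf(x, mu, k, eps) == pytest.approx(
                two_process_quad(x, mu, k, eps), abs=1e-8
            )

    def test_normalisation(self):
        # as above: account for the variable component's exact tail mass
        xs = np.arange(201)
        mu, k = 0.1, 1e-4
        for eps in (0.0, 0.3, 0.96, 1.0):
            truncated = two_process_pmf(xs, mu, k, eps).sum()
            m_var = mu * (1 - eps)
            tail_bound = stats.nbinom.sf(150, k, k / (k + m_var)) if m_var else 0.0
            assert 0 <= 1.0 - truncated <= tail_bound + 1e-9


class TestSpectrumLogLikelihood:
    def test_single_cell_unit_values(self):
        assert spectrum_log_likelihood(np.array([1.0]), np.array([1.0])) == pytest.approx(-1.0)

    def test_all_zero_observed(self):
        exp = np.array([2.0, 1.5, 0.5])
        assert spectrum_log_likelihood(np.zeros(3), exp) == pytest.approx(-exp.sum())

    def test_three_cell_hand_example(self):
        obs = np.array([3.0, 1.0, 0.0])
        exp = np.array([2.5, 1.2, 0.3])
        hand = sum(stats.poisson.logpmf(int(o), e) for o, e in zip(obs, exp))
        assert spectrum_log_likelihood(obs, exp) == pytest.approx(hand)

    def test_structural_zero_with_observation_is_impossible(self):
        assert spectrum_log_likelihood(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == -np.inf


class TestFitting:
    @pytest.mark.parametrize("model_id, expected_n", [("1a", 2), ("1b", 64), ("2a", 3), ("2b", 96)])
    def test_parameter_counts(self, model_id, expected_n):
        assert n_params_for(model_id, 32) == expected_n

    def test_poisson_data_null_recovery(self):
        # pure Poisson data: model 2a collapses to Poisson, no likelihood gain
        spectra = simulate_spectra(100_000, 5e-3, 0.5, 1.0, n_contexts=4, seed=11)
        fit2a = fit_model(spectra, "2a", n_starts=3, seed=0)
        cells = [spectra[c] for c in sorted(spectra)]
        pois_ll = 0.0
        for s in cells:
            mu_hat = s.m / s.l
            pois_ll += spectrum_log_likelihood(s, s.l * stats.poisson.pmf(np.arange(s.counts.size), mu_hat))
        assert fit2a.log_likelihood - pois_ll < 3.0
        # the fit collapses to Poisson via eps -> 1 or a huge shape
        assert fit2a.median_eps > 0.99 or fit2a.median_shape > 100

    def test_nesting_monotonicity_of_fitted_likelihoods(self):
        spectra = simulate_spectra(200_000, 2e-3, 5e-4, 0.95, n_contexts=4, seed=3)
        fits = {m: fit_model(spectra, m, n_starts=3, seed=0) for m in ("1a", "1b", "2a", "2b")}
        tol = 1e-3
        assert fits["1b"].log_likelihood >= fits["1a"].log_likelihood - tol
        assert fits["2a"].log_likelihood >= fits["1a"].log_likelihood - tol
        assert fits["2b"].log_likelihood >= fits["2a"].log_likelihood - tol
        assert fits["2b"].log_likelihood >= fits["1b"].log_likelihood - tol

    def test_shared_models_replicate_one_estimate(self):
        spectra = simulate_spectra(50_000, 2e-3, 1e-3, 0.9, n_contexts=3, seed=4)
        fit = fit_model(spectra, "2a", n_starts=2, seed=0)
        assert len(set(fit.mu.values())) == 1
        assert len(set(fit.eps.values())) == 1


class TestLikelihoodRatio:
    def test_identical_fits_give_zero_statistic(self):
        spectra = simulate_spectra(20_000, 2e-3, 1e-3, 0.9, n_contexts=2, seed=5)
        f1 = fit_model(spectra, "1a", n_starts=2, seed=0)
        f2 = fit_model(spectra, "2a", n_starts=2, seed=0)
        f2.log_likelihood = f1.log_likelihood  # same likelihood by construction
        res = likelihood_ratio_test(f1, f2)
        assert res.statistic == 0 and res.p_value == 1

    def test_df_is_parameter_difference(self):
        spectra = simulate_spectra(20_000, 2e-3, 1e-3, 0.9, n_contexts=32, seed=6)
        f2a = fit_model(spectra, "2a", n_starts=1, seed=0, maxiter=200)
        f2b = fit_model(spectra, "2b", n_starts=1, seed=0, maxiter=200)
        res = likelihood_ratio_test(f2a, f2b)
        assert res.df == 96 - 3 == 93

    def test_non_nested_pair_rejected(self):
        spectra = simulate_spectra(20_000, 2e-3, 1e-3, 0.9, n_contexts=2, seed=7)
        f1b = fit_model(spectra, "1b", n_starts=1, seed=0, maxiter=200)
        f2a = fit_model(spectra, "2a", n_starts=1, seed=0, maxiter=200)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(f1b, f2a)


class TestModelComparison:
    def test_two_process_data_prefers_two_process_family(self):
        spectra = simulate_spectra(500_000, 1.5e-3, 3e-4, 0.95, n_contexts=8, seed=8)
        table, fits = model_comparison_table(
            spectra, models=("1a", "2a"), n_starts=3, seed=0
        )
        assert table.loc[table["preferred"], "model"].item() == "2a"
        assert set(table.columns) >= {"model", "N", "log_likelihood", "median_shape", "median_eps"}

    def test_reported_parameter_counts(self):
        spectra = simulate_spectra(20_000, 2e-3, 1e-3, 0.9, n_contexts=4, seed=9)
        table, _ = model_comparison_table(spectra, n_starts=1, seed=0)
        assert dict(zip(table["model"], table["N"])) == {"1a": 2, "1b": 8, "2a": 3, "2b": 12}
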