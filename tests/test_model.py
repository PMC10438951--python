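"""CAR Poisson model: sampler correctness, diagnostics, results API."""

import numpy as np
import pytest
import statsmodels.api as sm

from dpsmr import (
    CARPoissonModel,
    ExpectedCounts,
    GeneratingParameters,
    MCMCConfig,
    OutcomeData,
    fit_car_poisson,
    simulate_outcomes,
)
from dpsmr.model import CARPoissonResults


@pytest.fixture(scope="module")
def simulated(small_dataset, generating_params):
    g, _, cov, exp = small_dataset
    out, eff = simulate_outcomes(exp, cov, generating_params, g, rng=np.random.default_rng(21))
    return g, cov, exp, out


@pytest.fixture(scope="module")
def quick_fit(simulated):
    g, cov, exp, out = simulated
    return fit_car_poisson(out, exp, cov, g, MCMCConfig.quick(seed=31))


def _dummy_results(beta_draws):
    """Results object with injected draws, for testing summaries in isolation."""
    S = beta_draws.shape[0]
    return CARPoissonResults(
        model=None,
        config=None,
        beta_draws=beta_draws,
        theta_draws=np.zeros((S, 1)),
        phi_draws=np.zeros((S, 1)),
        tau2_draws=np.ones(S),
        sigma2_draws=np.ones(S),
        rho_draws=np.full(S, 0.5),
        fitted_lambda=np.array([[1.0]]),
        acceptance={},
    )


class TestGLMLimit:
    def test_matches_irls_poisson_when_random_effects_disabled(self, simulated):
        """With theta and phi pinned at zero the posterior collapses to a
        fixed-effects Poisson GLM; posterior means must match the
        independent IRLS solution within 2 posterior standard deviations."""
        g, cov, exp, out = simulated
        cfg = MCMCConfig(
            n_iterations=6000, n_burnin=3000, thinning=3, seed=17,
            sample_theta=False, sample_phi=False,
        )
        res = fit_car_poisson(out, exp, cov, g, cfg)

        mask = out.mask & (exp.values > 0)
        X = np.column_stack(
            [
                np.ones(mask.sum()),
                cov.group_indicator(2)[mask],
                np.repeat(cov.prop_pov[:, None], 2, axis=1)[mask],
            ]
        )
        glm = sm.GLM(
            out.y[mask], X, family=sm.families.Poisson(), offset=np.log(exp.values[mask])
        ).fit()
        sd = res.beta_draws.std(axis=0, ddof=1)
        assert (np.abs(res.beta_mean - glm.params) < 2 * sd).all()

    def test_offset_identity_recovers_null_intercept(self, small_dataset):
        """If observed counts equal the expected counts exactly, the
        intercept posterior concentrates at zero."""
        g, _, cov, exp = small_dataset
        y = np.round(exp.values).astype(np.int64)
        y = np.maximum(y, 1)
        identity_exp = ExpectedCounts(y.astype(float))
        out = OutcomeData(y, mask=identity_exp.values > 0)
        cfg = MCMCConfig(
            n_iterations=4000, n_burnin=2000, thinning=2, seed=5,
            sample_theta=False, sample_phi=False,
        )
        res = fit_car_poisson(out, identity_exp, cov, g, cfg)
        assert abs(res.beta_mean[0]) < 0.05


class TestChainBehaviour:
    def test_bit_identical_given_seed(self, simulated):
        g, cov, exp, out = simulated
        cfg = MCMCConfig.quick(seed=77)
        a = fit_car_poisson(out, exp, cov, g, cfg)
        b = fit_car_poisson(out, exp, cov, g, cfg)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)
        np.testing.assert_array_equal(a.theta_draws, b.theta_draws)
        np.testing.assert_array_equal(a.rho_draws, b.rho_draws)

    def test_acceptance_rates_in_healthy_window(self, quick_fit):
        for block in ("beta", "theta", "phi"):
            assert 0.15 <= quick_fit.acceptance[block] <= 0.6

    def test_summary_table_complete(self, quick_fit):
        s = quick_fit.summary()
        assert {"beta0", "beta1", "beta2", "tau2", "sigma2", "rho"} <= set(s.index)
        assert (s["2.5%"] <= s["97.5%"]).all()


class TestReferenceProblemMixing:
    def test_beta1_effective_sample_size(self, small_dataset, generating_params):
        """Default-settings chain on the reference lattice keeps enough
        independent information in the group-effect coefficient."""
        import dpsmr

        g = dpsmr.build_lattice_adjacency(15, 15)
        pop = dpsmr.generate_population(g, "diffuse", seed=1)
        cov = dpsmr.generate_covariates(g, pop, seed=2)
        from dpsmr.standardize import DEFAULT_REFERENCE_RATES, AgeRateTable

        exp = dpsmr.expected_counts(
            pop, AgeRateTable(np.asarray(DEFAULT_REFERENCE_RATES), pop.age_bands)
        )
        out, _ = simulate_outcomes(exp, cov, generating_params, g, rng=np.random.default_rng(3))
        res = fit_car_poisson(out, exp, cov, g, MCMCConfig(seed=8))
        assert res.ess("beta1") >= 200


class TestResultsAPI:
    def test_rate_ratio_degenerate_chain(self):
        res = _dummy_results(np.zeros((200, 3)))
        rr = res.rate_ratios()
        assert rr.loc["beta1", "rate_ratio"] == pytest.approx(1.0)
        assert rr.loc["beta1", "ci_low"] == pytest.approx(1.0)
        assert rr.loc["beta1", "ci_high"] == pytest.approx(1.0)

    def test_rate_ratio_constant_log2(self):
        draws = np.zeros((200, 3))
        draws[:, 1] = np.log(2.0)
        res = _dummy_results(draws)
        assert res.rate_ratios().loc["beta1", "rate_ratio"] == pytest.approx(2.0)

    def test_rate_ratio_normal_draws_closed_form(self):
        rng = np.random.default_rng(0)
        draws = np.zeros((10_000, 3))
        draws[:, 1] = rng.normal(0.4, 0.05, size=10_000)
        res = _dummy_results(draws)
        rr = res.rate_ratios()
        assert rr.loc["beta1", "rate_ratio"] == pytest.approx(np.exp(0.4), rel=0.01)
        assert rr.loc["beta1", "ci_low"] == pytest.approx(np.exp(0.4 - 1.96 * 0.05), rel=0.01)
        assert rr.loc["beta1", "ci_high"] == pytest.approx(np.exp(0.4 + 1.96 * 0.05), rel=0.01)

    def test_rate_ratio_requires_enough_draws(self):
        res = _dummy_results(np.zeros((50, 3)))
        with pytest.raises(ValueError, match="100"):
            res.rate_ratios()

    def test_predict_smr_direct_division(self, quick_fit):
        smrs = quick_fit.predict_smr()
        ok = ~np.isnan(smrs)
        np.testing.assert_allclose(
            smrs[ok], quick_fit.fitted_lambda[ok] / quick_fit.model.expected.values[ok]
        )
        assert (smrs[ok] > 0).all()

    def test_predict_smr_injected_values(self):
        res = _dummy_results(np.zeros((200, 3)))
        res.fitted_lambda = np.array([[5.0, 3.0]])
        out = res.predict_smr(ExpectedCounts(np.array([[5.0, 12.0]])))
        np.testing.assert_allclose(out, [[1.0, 0.25]])


class TestValidation:
    def test_zero_expected_on_modeled_stratum_rejected(self, small_dataset):
        g, _, cov, exp = small_dataset
        y = np.ones(exp.values.shape, dtype=np.int64)
        bad_exp = ExpectedCounts(np.zeros_like(exp.values))
        out = OutcomeData(y)  # mask defaults to all-modeled
        with pytest.raises(ValueError):
            CARPoissonModel(out, bad_exp, cov, g)

    def test_misaligned_shapes_rejected(self, small_dataset):
        g, _, cov, exp = small_dataset
        out = OutcomeData(np.ones((3, 2), dtype=np.int64))
        with pytest.raises(ValueError, match="misaligned"):
            CARPoissonModel(out, exp, cov, g)

    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError, match="n_burnin"):
            MCMCConfig(n_iterations=100, n_burnin=100)
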