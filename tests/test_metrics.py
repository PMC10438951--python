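"""Evaluation metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest

from dpsmr import (
    ExpectedCounts,
    GeneratingParameters,
    coefficient_bias,
    denominator_summaries,
    interval_coverage,
    percent_difference,
    smr_errors,
)


def _exp(values):
    return ExpectedCounts(np.asarray(values, dtype=float))


class TestPercentDifference:
    def test_identity_is_zero(self):
        e = _exp([[10.0, 5.0]])
        out = percent_difference(e, e)
        np.testing.assert_allclose(out["percent_diff"], 0.0)

    def test_direct_formula(self):
        out = percent_difference(_exp([[9.0]]), _exp([[10.0]]))
        assert out["percent_diff"].iloc[0] == pytest.approx(-10.0)

    def test_zero_baseline_excluded_and_counted(self):
        out = percent_difference(_exp([[9.0, 1.0]]), _exp([[0.0, 2.0]]))
        assert out["excluded"].iloc[0]
        assert np.isnan(out["percent_diff"].iloc[0])
        assert not out["excluded"].iloc[1]


class TestDenominatorSummaries:
    def test_identity_has_no_underestimation(self):
        e = _exp([[10.0, 5.0], [3.0, 2.0]])
        s = denominator_summaries(e, e)
        assert (s["pct_underestimated"] == 0.0).all()

    def test_underestimation_fraction(self):
        base = _exp([[10.0], [10.0]])
        test = _exp([[9.0], [11.0]])
        s = denominator_summaries(test, base)
        assert s.loc[0, "pct_underestimated"] == pytest.approx(50.0)

    def test_zero_and_small_count_fractions(self):
        base = _exp([[1.0], [1.0], [1.0]])
        test = _exp([[0.0], [3.0], [7.0]])
        s = denominator_summaries(test, base)
        assert s.loc[0, "pct_zero"] == pytest.approx(100 / 3)
        assert s.loc[0, "pct_below_5"] == pytest.approx(200 / 3)


class TestCoefficientBias:
    def test_direct_formula(self):
        truth = GeneratingParameters(beta0=0, beta1=0.4, beta2=0.01)
        df = coefficient_bias([np.array([0.0, 0.41, 0.01])], truth)
        row = df[df["coefficient"] == "beta1"].iloc[0]
        assert row["raw_bias"] == pytest.approx(0.01)
        assert row["percent_bias"] == pytest.approx(2.5)

    def test_exact_estimate_has_zero_bias(self):
        truth = GeneratingParameters()
        df = coefficient_bias([truth.beta], truth)
        assert (df["raw_bias"] == 0).all()

    def test_percent_bias_suppressed_for_zero_truth(self):
        truth = GeneratingParameters(beta0=0.0)
        df = coefficient_bias([np.array([0.2, 0.4, 0.01])], truth)
        row = df[df["coefficient"] == "beta0"].iloc[0]
        assert np.isnan(row["percent_bias"])
        assert row["raw_bias"] == pytest.approx(0.2)


class TestIntervalCoverage:
    def test_direct_count(self):
        truth = GeneratingParameters(beta1=0.4)
        fits = [
            {"beta0": (-1, 1), "beta1": iv, "beta2": (-1, 1)}
            for iv in [(0.3, 0.5), (0.45, 0.6), (0.1, 0.39)]
        ]
        cov = interval_coverage(fits, truth)
        assert cov.loc["beta1", "coverage_pct"] == pytest.approx(100 / 3)

    def test_full_coverage(self):
        truth = GeneratingParameters()
        fits = [{n: (-10, 10) for n in ("beta0", "beta1", "beta2")}] * 5
        cov = interval_coverage(fits, truth)
        assert (cov["coverage_pct"] == 100.0).all()

    def test_endpoint_counts_as_covered(self):
        truth = GeneratingParameters(beta1=0.4)
        fits = [{"beta0": (0, 0), "beta1": (0.4, 0.5), "beta2": (0.01, 0.01)}]
        cov = interval_coverage(fits, truth)
        assert cov.loc["beta1", "coverage_pct"] == pytest.approx(100.0)


class TestSmrErrors:
    def test_two_simulation_example(self):
        # truth SMR 1.0 in both simulations; estimates 1.1 and 0.9
        P = _exp([[2.0]])
        lam = np.array([[[2.0]], [[2.0]]])
        est = np.array([[[1.1]], [[0.9]]])
        out = smr_errors(est, lam, P)
        assert out["bias"].iloc[0] == pytest.approx(0.0)
        assert out["mape"].iloc[0] == pytest.approx(0.10)

    def test_exact_estimates_have_zero_error(self):
        P = _exp([[4.0, 2.0]])
        lam = np.array([[[4.0, 3.0]]])
        est = lam / P.values[None]
        out = smr_errors(est, lam, P)
        assert (out["bias"] == 0).all()
        assert (out["mape"] == 0).all()

    def test_single_simulation(self):
        P = _exp([[1.0]])
        lam = np.array([[[2.0]]])
        est = np.array([[[2.5]]])
        out = smr_errors(est, lam, P)
        assert out["bias"].iloc[0] == pytest.approx(0.5)
        assert out["mape"].iloc[0] == pytest.approx(0.25)

    def test_upward_fraction(self):
        P = _exp([[1.0, 1.0]])
        lam = np.ones((1, 1, 2))
        est = np.array([[[1.5, 0.5]]])
        out = smr_errors(est, lam, P)
        gs = out.attrs["group_summary"]
        assert gs.loc[0, "pct_biased_upward"] == pytest.approx(100.0)
        assert gs.loc[1, "pct_biased_upward"] == pytest.approx(0.0)


class TestBruteForceOracles:
    """All metric operations agree with naive loop implementations to 1e-12."""

    def test_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n_i, n_j, K = rng.integers(2, 6), 2, int(rng.integers(1, 6))
            base = rng.uniform(0.5, 10, size=(n_i, n_j))
            test = np.abs(base + rng.normal(0, 2, size=base.shape))
            lam = rng.uniform(0.5, 8, size=(K, n_i, n_j))
            est = np.abs(lam / base[None] + rng.normal(0, 0.3, size=lam.shape))

            # percent difference
            got = percent_difference(_exp(test), _exp(base))
            for idx, (i, j) in enumerate((i, j) for i in range(n_i) for j in range(n_j)):
                want = 100.0 * (test[i, j] - base[i, j]) / base[i, j]
                assert got["percent_diff"].iloc[idx] == pytest.approx(want, abs=1e-12)

            # SMR bias / MAPE
            out = smr_errors(est, lam, _exp(base))
            for idx, (i, j) in enumerate((i, j) for i in range(n_i) for j in range(n_j)):
                truth_ij = [lam[k, i, j] / base[i, j] for k in range(K)]
                bias = sum(est[k, i, j] - truth_ij[k] for k in range(K)) / K
                mape = sum(
                    abs(est[k, i, j] - truth_ij[k]) / truth_ij[k] for k in range(K)
                ) / K
                assert out["bias"].iloc[idx] == pytest.approx(bias, abs=1e-12)
                assert out["mape"].iloc[idx] == pytest.approx(mape, abs=1e-12)

            # coverage
            truth = GeneratingParameters()
            fits = []
            for _ in range(K):
                lo = rng.normal(size=3)
                hi = lo + np.abs(rng.normal(size=3))
                fits.append({n: (lo[c], hi[c]) for c, n in enumerate(("beta0", "beta1", "beta2"))})
            got_cov = interval_coverage(fits, truth)
            for c, name in enumerate(("beta0", "beta1", "beta2")):
                want = 100.0 * sum(
                    1 for f in fits if f[name][0] <= truth.beta[c] <= f[name][1]
                ) / K
                assert got_cov.loc[name, "coverage_pct"] == pytest.approx(want, abs=1e-12)
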