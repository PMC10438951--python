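"""Simulation-study orchestration: arms, seeding, report assembly."""

import numpy as np
import pandas as pd
import pytest

from dpsmr import MCMCConfig, PrivacyConfig, StudyConfig, run_simulation_study
from dpsmr.study import PROVENANCE_FLAGS

TINY_MCMC = MCMCConfig(n_iterations=600, n_burnin=300, thinning=3)


@pytest.fixture(scope="module")
def tiny_report():
    cfg = StudyConfig(
        n_simulations=3,
        arms=(
            ("truth", PrivacyConfig(epsilon=float("inf"), seed=0)),
            ("eps1", PrivacyConfig(epsilon=1.0, seed=0)),
        ),
        n_rows=4,
        n_cols=4,
        regime="diffuse",
        mcmc=TINY_MCMC,
        master_seed=3,
    )
    return run_simulation_study(cfg)


class TestConfigValidation:
    def test_truth_arm_mandatory(self):
        with pytest.raises(ValueError, match="truth arm"):
            StudyConfig(arms=(("eps1", PrivacyConfig(epsilon=1.0)),))

    def test_bad_zero_policy_rejected(self):
        with pytest.raises(ValueError, match="zero_policy"):
            StudyConfig(zero_policy="ignore")

    def test_default_simulation_count_is_reference_design(self):
        assert StudyConfig().n_simulations == 100


class TestStructure:
    def test_per_simulation_records(self, tiny_report):
        for arm in ("truth", "eps1"):
            bias = tiny_report.coefficient_bias[arm]
            # 3 simulations x 3 coefficients
            assert len(bias) == 9
            assert bias["simulation"].nunique() == 3
            err = tiny_report.smr_errors[arm]
            # one Bias/MAPE row per stratum
            assert len(err) == 16 * 2

    def test_coverage_bounded(self, tiny_report):
        for arm in ("truth", "eps1"):
            cov = tiny_report.coverage[arm]["coverage_pct"]
            assert ((0 <= cov) & (cov <= 100)).all()

    def test_mape_nonnegative(self, tiny_report):
        err = tiny_report.smr_errors["truth"]
        assert (err.loc[err["modeled"], "mape"] >= 0).all()

    def test_provenance_block_complete(self, tiny_report):
        assert set(PROVENANCE_FLAGS) <= set(tiny_report.provenance)

    def test_json_and_csv_outputs(self, tiny_report, tmp_path):
        tiny_report.to_json(tmp_path / "report.json")
        tiny_report.write_csvs(tmp_path / "tables")
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "tables" / "coefficient_bias.csv").exists()
        combined = pd.read_csv(tmp_path / "tables" / "coefficient_bias.csv")
        assert set(combined["arm"]) == {"truth", "eps1"}


class TestSeedingInvariance:
    def test_duplicate_noiseless_arm_matches_truth_arm(self):
        """An extra arm with the identity mechanism and shared seeds must
        reproduce the truth arm's results exactly."""
        cfg = StudyConfig(
            n_simulations=2,
            arms=(
                ("truth", PrivacyConfig(epsilon=float("inf"), seed=0)),
                ("also-truth", PrivacyConfig(epsilon=float("inf"), seed=0)),
            ),
            n_rows=3,
            n_cols=3,
            regime="diffuse",
            mcmc=TINY_MCMC,
            master_seed=5,
        )
        report = run_simulation_study(cfg)
        pd.testing.assert_frame_equal(
            report.coefficient_bias["truth"], report.coefficient_bias["also-truth"]
        )
        pd.testing.assert_frame_equal(
            report.smr_errors["truth"], report.smr_errors["also-truth"]
        )

    def test_reproducible_from_master_seed(self):
        cfg = StudyConfig(
            n_simulations=1,
            arms=(("truth", PrivacyConfig(epsilon=float("inf"))),),
            n_rows=3,
            n_cols=3,
            regime="diffuse",
            mcmc=TINY_MCMC,
            master_seed=9,
        )
        a = run_simulation_study(cfg)
        b = run_simulation_study(cfg)
        pd.testing.assert_frame_equal(
            a.coefficient_bias["truth"], b.coefficient_bias["truth"]
        )

    def test_checkpoints_written(self, tmp_path):
        cfg = StudyConfig(
            n_simulations=2,
            arms=(("truth", PrivacyConfig(epsilon=float("inf"))),),
            n_rows=3,
            n_cols=3,
            regime="diffuse",
            mcmc=TINY_MCMC,
            master_seed=1,
        )
        run_simulation_study(cfg, checkpoint_dir=tmp_path / "ck")
        assert (tmp_path / "ck" / "sim_0000.csv").exists()
        assert (tmp_path / "ck" / "sim_0001.csv").exists()


class TestEpsilonMonotonicity:
    def test_denominator_error_shrinks_with_epsilon(self):
        """Mean absolute denominator MAPE against the truth arm is
        non-increasing across the privacy-budget grid, averaged over seeds."""
        from dpsmr import (
            AgeRateTable,
            build_lattice_adjacency,
            expected_counts,
            generate_population,
            privatize,
        )
        from dpsmr.standardize import DEFAULT_REFERENCE_RATES

        g = build_lattice_adjacency(6, 6)
        grid = [0.5, 1.0, 2.0, 6.0, 46.24]
        mean_errs = []
        for eps in grid:
            errs = []
            for seed in range(20):
                pop = generate_population(g, "concentrated", seed=seed)
                rates = AgeRateTable(np.asarray(DEFAULT_REFERENCE_RATES), pop.age_bands)
                base = expected_counts(pop, rates)
                noised = expected_counts(
                    privatize(pop, PrivacyConfig(epsilon=eps, seed=seed)), rates
                )
                ok = base.values > 0
                errs.append(
                    np.mean(np.abs(noised.values[ok] - base.values[ok]) / base.values[ok])
                )
            mean_errs.append(np.mean(errs))
        assert all(a >= b for a, b in zip(mean_errs, mean_errs[1:]))
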