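"""Evaluation statistics for the simulation study.

Given K simulated datasets and a model fit per dataset and denominator arm,
the per-stratum SMR error metrics are

    Bias_ij = (1/K) * sum_k (SMRhat_ijk - lambda_ijk / P_ij)
    MAPE_ij = (1/K) * sum_k |SMRhat_ijk - lambda_ijk / P_ij| / (lambda_ijk / P_ij)

where P_ij are the *true* (baseline-arm) expected counts, so the truth
being estimated is the same in every arm.  Coefficient-level metrics are
raw bias, percent bias and 95% credible-interval coverage across
simulations.  Denominator-level metrics compare each arm's expected counts
with the baseline arm's (percent differences, underestimation fraction,
zero and small-count fractions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgp import GeneratingParameters
from .model import COEF_NAMES, CARPoissonResults
from .standardize import ExpectedCounts

__all__ = [
    "percent_difference",
    "denominator_summaries",
    "coefficient_bias",
    "interval_coverage",
    "smr_errors",
]


def percent_difference(test: ExpectedCounts, baseline: ExpectedCounts) -> pd.DataFrame:
    """Per-stratum percent difference 100*(P_test - P_base)/P_base.

    Strata with a zero baseline are excluded from the percent differences
    and counted in the ``excluded`` column instead.
    """
    if test.values.shape != baseline.values.shape:
        raise ValueError("misaligned expected-count tables")
    n_i, n_j = baseline.values.shape
    idx = pd.MultiIndex.from_product(
        [np.arange(1, n_i + 1), np.arange(n_j)], names=["area", "group"]
    )
    base = baseline.values.ravel()
    tst = test.values.ravel()
    ok = base > 0
    pct = np.full(base.shape, np.nan)
    pct[ok] = 100.0 * (tst[ok] - base[ok]) / base[ok]
    out = pd.DataFrame({"percent_diff": pct, "excluded": ~ok}, index=idx).reset_index()
    return out


def denominator_summaries(test: ExpectedCounts, baseline: ExpectedCounts) -> pd.DataFrame:
    """Per-group summary of denominator error.

    Columns: quartiles and median of percent differences (over strata with
    positive baseline), percent of strata underestimated (P_test < P_base),
    percent of test strata equal to zero, and percent below 5.
    """
    pct = percent_difference(test, baseline)
    rows = []
    for j in range(baseline.values.shape[1]):
        base_j = baseline.values[:, j]
        test_j = test.values[:, j]
        pd_j = pct.loc[(pct["group"] == j) & (~pct["excluded"]), "percent_diff"]
        q1, med, q3 = (
            np.percentile(pd_j, [25, 50, 75]) if len(pd_j) else (np.nan, np.nan, np.nan)
        )
        rows.append(
            {
                "group": j,
                "pct_diff_q1": q1,
                "pct_diff_median": med,
                "pct_diff_q3": q3,
                "pct_underestimated": 100.0 * float(np.mean(test_j < base_j)),
                "pct_zero": 100.0 * float(np.mean(test_j == 0)),
                "pct_below_5": 100.0 * float(np.mean(test_j < 5)),
                "n_excluded": int(((base_j == 0)).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def coefficient_bias(
    fits: list[CARPoissonResults] | list[np.ndarray],
    truth: GeneratingParameters,
) -> pd.DataFrame:
    """Per-simulation coefficient bias records.

    Raw bias = posterior mean - true value (always emitted); percent bias =
    100 * raw / truth, emitted only where the true value is nonzero.

    ``fits`` may be results objects or bare posterior-mean vectors.
    """
    if not fits:
        raise ValueError("need at least one fit")
    true_beta = truth.beta
    rows = []
    for k, fit in enumerate(fits):
        means = fit.beta_mean if isinstance(fit, CARPoissonResults) else np.asarray(fit)
        for c, name in enumerate(COEF_NAMES):
            raw = float(means[c] - true_beta[c])
            rows.append(
                {
                    "simulation": k,
                    "coefficient": name,
                    "estimate": float(means[c]),
                    "truth": float(true_beta[c]),
                    "raw_bias": raw,
                    "percent_bias": 100.0 * raw / true_beta[c] if true_beta[c] != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def interval_coverage(
    fits: list[CARPoissonResults] | list[dict],
    truth: GeneratingParameters,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percent of simulations whose credible interval covers the truth.

    Intervals are closed: a truth exactly on an endpoint counts as covered.
    ``fits`` may be results objects or ``{coef: (lo, hi)}`` dicts.
    """
    if not fits:
        raise ValueError("need at least one fit")
    true_beta = truth.beta
    cover = {name: 0 for name in COEF_NAMES}
    for fit in fits:
        for c, name in enumerate(COEF_NAMES):
            lo, hi = (
                fit.credible_interval(name, level)
                if isinstance(fit, CARPoissonResults)
                else fit[name]
            )
            if lo <= true_beta[c] <= hi:
                cover[name] += 1
    return pd.DataFrame(
        {
            "coefficient": list(COEF_NAMES),
            "coverage_pct": [100.0 * cover[n] / len(fits) for n in COEF_NAMES],
        }
    ).set_index("coefficient")


def smr_errors(
    smr_hats: np.ndarray,
    lambda_truths: np.ndarray,
    baseline_expected: ExpectedCounts,
) -> pd.DataFrame:
    """Per-stratum SMR bias and MAPE across K simulations.

    Parameters
    ----------
    smr_hats : ndarray, shape (K, n_areas, n_groups)
        Model SMR estimates per simulation (nan on unmodeled strata).
    lambda_truths : ndarray, shape (K, n_areas, n_groups)
        Generating means per simulation.
    baseline_expected : ExpectedCounts
        True (baseline-arm) expected counts P_ij used for the truth
        SMR lambda/P.

    Returns a tidy frame with Bias_ij and MAPE_ij per area x group plus an
    attached attribute frame of group-level summaries including the
    fraction of strata biased upward.
    """
    smr_hats = np.asarray(smr_hats, dtype=float)
    lambda_truths = np.asarray(lambda_truths, dtype=float)
    if smr_hats.shape != lambda_truths.shape or smr_hats.ndim != 3:
        raise ValueError("smr_hats and lambda_truths must share shape (K, areas, groups)")
    P = baseline_expected.values
    if P.shape != smr_hats.shape[1:]:
        raise ValueError("baseline expected counts misaligned with estimates")

    with np.errstate(invalid="ignore", divide="ignore"):
        truth = lambda_truths / P[None, :, :]
        err = smr_hats - truth
        bias = np.nanmean(err, axis=0)
        mape = np.nanmean(np.abs(err) / truth, axis=0)
    valid = np.isfinite(bias)

    n_i, n_j = P.shape
    idx = pd.MultiIndex.from_product(
        [np.arange(1, n_i + 1), np.arange(n_j)], names=["area", "group"]
    )
    out = pd.DataFrame(
        {"bias": bias.ravel(), "mape": mape.ravel(), "modeled": valid.ravel()}, index=idx
    ).reset_index()

    summaries = []
    for j in range(n_j):
        sel = out[(out["group"] == j) & out["modeled"]]
        summaries.append(
            {
                "group": j,
                "mean_bias": sel["bias"].mean(),
                "median_bias": sel["bias"].median(),
                "median_mape": sel["mape"].median(),
                "mean_mape": sel["mape"].mean(),
                "pct_biased_upward": 100.0 * float((sel["bias"] > 0).mean()),
                "n_strata": int(len(sel)),
            }
        )
    out.attrs["group_summary"] = pd.DataFrame(summaries).set_index("group")
    return out
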