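"""Bayesian multilevel spatial Poisson model for small-area SMR estimation.

The model, for event count ``Y_ij`` in area *i* and group *j* with expected
count (offset) ``P_ij``:

    Y_ij ~ Poisson(lambda_ij)
    log(lambda_ij) = beta0 + beta1*I(minority)_ij + beta2*deprivation_i
                     + theta_i + phi_ij + log(P_ij)

Priors:
    theta  ~ N(0, tau2 * (D - rho*W)^{-1})          (proper CAR)
    phi_ij ~ N(0, sigma2) i.i.d.                    (overdispersion)
    beta_k ~ N(0, beta_prior_sd^2)
    tau2, sigma2 ~ InverseGamma(shape, scale);  rho ~ Uniform(0, rho_max)

Inference is Metropolis-within-Gibbs: adaptive random-walk Metropolis for
beta (block) and for theta and phi (single-site, with conditionally
independent sites updated simultaneously — graph-colored blocks for theta),
conjugate inverse-gamma draws for tau2 and sigma2, and Metropolis for rho
using precomputed eigenvalues for the CAR log-determinant.  Proposal scales
follow a Robbins-Monro recursion toward target acceptance rates and are
frozen at the end of burn-in, so the post-adaptation chain has the correct
stationary distribution.

Usage follows the Model/Results convention::

    model = CARPoissonModel(outcomes, expected, covariates, graph)
    res = model.fit(MCMCConfig(seed=1))
    print(res.summary())
    res.rate_ratios()
    res.predict_smr()
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .dgp import OutcomeData
from .population import CovariateTable
from .spatial import AdjacencyGraph
from .standardize import ExpectedCounts

__all__ = [
    "MCMCConfig",
    "CARPoissonModel",
    "CARPoissonResults",
    "fit_car_poisson",
    "rate_ratios",
    "predict_smr",
]

COEF_NAMES = ("beta0", "beta1", "beta2")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings and priors.

    Defaults (20,000 iterations, half burn-in, thinning 5) are reference-run
    settings; tests and quick exploration use shorter chains via
    :meth:`quick`.
    """

    n_iterations: int = 20_000
    n_burnin: int = 10_000
    thinning: int = 5
    seed: int = 0
    # priors
    beta_prior_sd: float = 10.0
    tau2_shape: float = 1.0
    tau2_scale: float = 0.01
    sigma2_shape: float = 1.0
    sigma2_scale: float = 0.01
    rho_max: float = 0.99
    # proposal adaptation
    target_accept_single: float = 0.44
    target_accept_block: float = 0.23
    init_scale_beta: float = 0.05
    init_scale_site: float = 0.3
    init_scale_rho: float = 0.1
    # component switches / pinned hyperparameters
    sample_theta: bool = True
    sample_phi: bool = True
    fixed_tau2: float | None = None
    fixed_sigma2: float | None = None
    fixed_rho: float | None = None

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not 0 < self.rho_max < 1:
            raise ValueError("rho_max must lie in (0, 1)")

    def replace(self, **kw) -> "MCMCConfig":
        return _dc_replace(self, **kw)

    @classmethod
    def quick(cls, seed: int = 0, **kw) -> "MCMCConfig":
        """Short test-grade chain (2,000 iterations, 1,000 burn-in, thin 2)."""
        defaults = dict(n_iterations=2_000, n_burnin=1_000, thinning=2, seed=seed)
        defaults.update(kw)
        return cls(**defaults)


def _irls_poisson(X: np.ndarray, y: np.ndarray, offset: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Newton/IRLS fit of a fixed-effects Poisson GLM with log link; used
    only to initialize the chain near the posterior mode."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu
        XtWX = X.T @ (X * W[:, None]) + 1e-8 * np.eye(X.shape[1])
        score = X.T @ (y - mu)
        step = np.linalg.solve(XtWX, score)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


class CARPoissonModel:
    """Spatial Poisson disease-mapping model bound to one dataset.

    Parameters
    ----------
    outcomes : OutcomeData
        Event counts; its ``mask`` marks modeled strata.
    expected : ExpectedCounts
        Offsets P_ij; must be strictly positive on every modeled stratum.
    covariates : CovariateTable
        Centered/scaled deprivation covariate (and the implied group
        indicator).
    graph : AdjacencyGraph
        Neighbor structure for the CAR prior.
    """

    def __init__(
        self,
        outcomes: OutcomeData,
        expected: ExpectedCounts,
        covariates: CovariateTable,
        graph: AdjacencyGraph,
    ) -> None:
        n_areas, n_groups = outcomes.y.shape
        if expected.values.shape != (n_areas, n_groups):
            raise ValueError("expected counts misaligned with outcomes")
        if covariates.n_areas != n_areas or graph.n_areas != n_areas:
            raise ValueError("covariates/graph misaligned with outcomes")
        mask = outcomes.mask & (expected.values > 0)
        if not mask.any():
            raise ValueError("no modeled strata (all expected counts are zero)")
        if (outcomes.mask & ~(expected.values > 0)).any():
            raise ValueError("non-positive expected count on a modeled stratum")

        self.outcomes = outcomes
        self.expected = expected
        self.covariates = covariates
        self.graph = graph
        self.mask = mask

        # flatten modeled strata
        area_grid, group_grid = np.meshgrid(
            np.arange(n_areas), np.arange(n_groups), indexing="ij"
        )
        self.area_idx = area_grid[mask]
        self.group_idx = group_grid[mask]
        self.y = outcomes.y[mask].astype(float)
        self.log_offset = np.log(expected.values[mask])
        ind = covariates.group_indicator(n_groups)
        self.X = np.column_stack(
            [
                np.ones(self.y.size),
                ind[mask],
                covariates.prop_pov[self.area_idx],
            ]
        )
        self.n_strata = self.y.size
        self.n_areas = n_areas
        self.n_groups = n_groups

    # ------------------------------------------------------------------ fit
    def fit(self, config: MCMCConfig | None = None) -> "CARPoissonResults":
        """Run the Metropolis-within-Gibbs sampler and return results."""
        cfg = config or MCMCConfig()
        rng = np.random.default_rng(cfg.seed)
        W = self.graph.weight_matrix
        degrees = self.graph.degrees.astype(float)
        N, M = self.n_areas, self.n_strata

        # per-area aggregation of strata
        y_area = np.zeros(N)
        np.add.at(y_area, self.area_idx, self.y)
        color_classes = self.graph.coloring() if cfg.sample_theta else []

        # eigenvalues of D^{-1/2} W D^{-1/2} for the CAR log-determinant
        if cfg.sample_theta and cfg.fixed_rho is None:
            d_inv_sqrt = 1.0 / np.sqrt(degrees)
            B = W.toarray() * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
            car_eigs = eigh(B, eigvals_only=True)
        else:
            car_eigs = None

        # state
        beta = _irls_poisson(self.X, self.y, self.log_offset)
        theta = np.zeros(N)
        phi = np.zeros(M)
        tau2 = cfg.fixed_tau2 if cfg.fixed_tau2 is not None else 0.1
        sigma2 = cfg.fixed_sigma2 if cfg.fixed_sigma2 is not None else 0.1
        rho = cfg.fixed_rho if cfg.fixed_rho is not None else 0.5

        eta = self.X @ beta + theta[self.area_idx] + phi + self.log_offset
        lam = np.exp(eta)
        if not np.all(np.isfinite(lam)):
            raise RuntimeError("non-finite likelihood at initialization")

        # proposal scales (adapted during burn-in, then frozen)
        s_beta = cfg.init_scale_beta
        s_theta = np.full(N, cfg.init_scale_site)
        s_phi = np.full(M, cfg.init_scale_site)
        s_rho = cfg.init_scale_rho
        s_swap0 = s_swap1 = s_swap_t = s_swap_x = s_scale = 0.1

        # running moments of beta for the adaptive (Haario) block proposal
        beta_mean_run = beta.copy()
        beta_cov_run = np.eye(3) * cfg.init_scale_beta**2
        minority = self.X[:, 1] == 1.0

        n_retained = -(-(cfg.n_iterations - cfg.n_burnin) // cfg.thinning)
        draws_beta = np.empty((n_retained, 3))
        draws_theta = np.empty((n_retained, N))
        draws_phi = np.empty((n_retained, M))
        draws_tau2 = np.empty(n_retained)
        draws_sigma2 = np.empty(n_retained)
        draws_rho = np.empty(n_retained)
        lam_sum = np.zeros(M)

        acc_counts = {"beta": 0.0, "theta": 0.0, "phi": 0.0, "rho": 0.0}
        post_counts = {"beta": 0, "theta": 0, "phi": 0, "rho": 0}

        prior_prec_beta = 1.0 / cfg.beta_prior_sd**2
        keep = 0
        for it in range(cfg.n_iterations):
            adapting = it < cfg.n_burnin
            gamma = 2.0 / (1.0 + it) ** 0.6 if adapting else 0.0

            # ---- beta block (adaptive-covariance random-walk Metropolis)
            if it == 200:
                s_beta = 1.0  # switch to covariance-shaped proposals
            if it >= 200:
                try:
                    L = np.linalg.cholesky(beta_cov_run + 1e-10 * np.eye(3))
                except np.linalg.LinAlgError:
                    L = np.eye(3) * cfg.init_scale_beta
                prop = beta + s_beta * (L @ rng.standard_normal(3))
            else:
                prop = beta + s_beta * rng.standard_normal(3)
            delta_eta = self.X @ (prop - beta)
            lam_new = lam * np.exp(delta_eta)
            dlog = np.sum(self.y * delta_eta - (lam_new - lam))
            dlog += -0.5 * prior_prec_beta * (np.sum(prop**2) - np.sum(beta**2))
            a = float(np.exp(min(dlog, 0.0)))
            if rng.random() < a:
                beta = prop
                lam = lam_new
                if not adapting:
                    acc_counts["beta"] += 1
            if adapting:
                s_beta *= np.exp(gamma * (a - cfg.target_accept_block))
                # running mean/covariance for the Haario proposal
                w = 1.0 / (it + 2)
                dev = beta - beta_mean_run
                beta_mean_run = beta_mean_run + w * dev
                beta_cov_run = (1 - w) * (beta_cov_run + w * np.outer(dev, dev))
            else:
                post_counts["beta"] += 1

            # ---- likelihood-invariant swap moves: shift mass between the
            # intercept/group coefficients and the random-effect means.
            # eta is unchanged, so only the priors enter the accept ratio.
            if cfg.sample_phi:
                # (beta0 + d, phi - d)
                d = s_swap0 * rng.standard_normal()
                dlog = -0.5 * prior_prec_beta * ((beta[0] + d) ** 2 - beta[0] ** 2)
                dlog += (2 * d * float(phi.sum()) - M * d * d) / (2.0 * sigma2)
                a = float(np.exp(min(dlog, 0.0)))
                if rng.random() < a:
                    beta = beta + np.array([d, 0.0, 0.0])
                    phi = phi - d
                if adapting:
                    s_swap0 *= np.exp(gamma * (a - cfg.target_accept_single))
                # (beta1 + d, phi_minority - d)
                d = s_swap1 * rng.standard_normal()
                n_min = int(minority.sum())
                dlog = -0.5 * prior_prec_beta * ((beta[1] + d) ** 2 - beta[1] ** 2)
                dlog += (2 * d * float(phi[minority].sum()) - n_min * d * d) / (2.0 * sigma2)
                a = float(np.exp(min(dlog, 0.0)))
                if rng.random() < a:
                    beta = beta + np.array([0.0, d, 0.0])
                    phi = phi - d * minority
                if adapting:
                    s_swap1 *= np.exp(gamma * (a - cfg.target_accept_single))
            if cfg.sample_theta:
                # (beta0 + d, theta - d); 1'Q1 = (1-rho)*sum(d_i), 1'Q theta = (1-rho)*d'theta
                d = s_swap_t * rng.standard_normal()
                one_Q_theta = (1.0 - rho) * float(degrees @ theta)
                one_Q_one = (1.0 - rho) * float(degrees.sum())
                dlog = -0.5 * prior_prec_beta * ((beta[0] + d) ** 2 - beta[0] ** 2)
                dlog += (2 * d * one_Q_theta - d * d * one_Q_one) / (2.0 * tau2)
                a = float(np.exp(min(dlog, 0.0)))
                if rng.random() < a:
                    beta = beta + np.array([d, 0.0, 0.0])
                    theta = theta - d
                if adapting:
                    s_swap_t *= np.exp(gamma * (a - cfg.target_accept_single))
                # (beta2 + d, theta - d*x): the area-level covariate direction
                d = s_swap_x * rng.standard_normal()
                x = self.covariates.prop_pov
                x_Q_theta = float(x @ (degrees * theta) - rho * (x @ (W @ theta)))
                x_Q_x = float(x @ (degrees * x) - rho * (x @ (W @ x)))
                dlog = -0.5 * prior_prec_beta * ((beta[2] + d) ** 2 - beta[2] ** 2)
                dlog += (2 * d * x_Q_theta - d * d * x_Q_x) / (2.0 * tau2)
                a = float(np.exp(min(dlog, 0.0)))
                if rng.random() < a:
                    beta = beta + np.array([0.0, 0.0, d])
                    theta = theta - d * x
                if adapting:
                    s_swap_x *= np.exp(gamma * (a - cfg.target_accept_single))

            # ---- phi single-site (all sites at once; conditionally independent)
            if cfg.sample_phi:
                z = rng.standard_normal(M)
                u = rng.random(M)
                delta = s_phi * z
                dlog = self.y * delta - lam * np.expm1(delta)
                dlog += -(2 * phi * delta + delta**2) / (2.0 * sigma2)
                a_vec = np.minimum(1.0, np.exp(np.minimum(dlog, 0.0)))
                accept = u < a_vec
                phi = phi + np.where(accept, delta, 0.0)
                lam = lam * np.where(accept, np.exp(delta), 1.0)
                if adapting:
                    s_phi *= np.exp(gamma * (a_vec - cfg.target_accept_single))
                else:
                    acc_counts["phi"] += float(accept.mean())
                    post_counts["phi"] += 1

            # ---- theta by graph-colored blocks
            if cfg.sample_theta:
                lam_area = np.zeros(N)
                np.add.at(lam_area, self.area_idx, lam)
                acc_prob_accum = 0.0
                for cls_idx in color_classes:
                    w_theta = W @ theta  # neighbor sums (refreshed per class)
                    m = rho * w_theta[cls_idx] / degrees[cls_idx]
                    prec = degrees[cls_idx] / tau2
                    delta = s_theta[cls_idx] * rng.standard_normal(cls_idx.size)
                    th_old = theta[cls_idx]
                    th_new = th_old + delta
                    dlog = y_area[cls_idx] * delta - lam_area[cls_idx] * np.expm1(delta)
                    dlog += -0.5 * prec * ((th_new - m) ** 2 - (th_old - m) ** 2)
                    a_vec = np.minimum(1.0, np.exp(np.minimum(dlog, 0.0)))
                    accept = rng.random(cls_idx.size) < a_vec
                    theta[cls_idx] = np.where(accept, th_new, th_old)
                    lam_area[cls_idx] *= np.where(accept, np.exp(delta), 1.0)
                    if adapting:
                        s_theta[cls_idx] *= np.exp(gamma * (a_vec - cfg.target_accept_single))
                    acc_prob_accum += float(accept.sum())
                # refresh stratum-level lambda once after all classes
                lam = np.exp(self.X @ beta + theta[self.area_idx] + phi + self.log_offset)
                if not adapting:
                    acc_counts["theta"] += acc_prob_accum / N
                    post_counts["theta"] += 1

                # ---- tau2 conjugate inverse-gamma
                if cfg.fixed_tau2 is None:
                    quad = float(theta @ (degrees * theta) - rho * (theta @ (W @ theta)))
                    tau2 = 1.0 / rng.gamma(cfg.tau2_shape + 0.5 * N, 1.0 / (cfg.tau2_scale + 0.5 * quad))

                    # joint rescale (theta, tau2) -> (c*theta, c^2*tau2):
                    # moves the field amplitude without fighting the prior.
                    c = float(np.exp(s_scale * rng.standard_normal()))
                    delta_eta = (c - 1.0) * theta[self.area_idx]
                    dlog = float(np.sum(self.y * delta_eta - lam * np.expm1(delta_eta)))
                    dlog += -2.0 * cfg.tau2_shape * np.log(c)
                    dlog += -cfg.tau2_scale * (1.0 / (c * c * tau2) - 1.0 / tau2)
                    a = float(np.exp(min(dlog, 0.0)))
                    if rng.random() < a:
                        theta = c * theta
                        tau2 = c * c * tau2
                        lam = lam * np.exp(delta_eta)
                    if adapting:
                        s_scale *= np.exp(gamma * (a - cfg.target_accept_single))

                # ---- rho Metropolis
                if cfg.fixed_rho is None:
                    prop_rho = rho + s_rho * rng.standard_normal()
                    if 0.0 <= prop_rho <= cfg.rho_max:
                        tDt = float(theta @ (degrees * theta))
                        tWt = float(theta @ (W @ theta))

                        def _rho_logpost(r: float) -> float:
                            return 0.5 * float(np.sum(np.log1p(-r * car_eigs))) - (
                                tDt - r * tWt
                            ) / (2.0 * tau2)

                        dlog = _rho_logpost(prop_rho) - _rho_logpost(rho)
                        a = min(1.0, float(np.exp(min(dlog, 0.0))))
                        if rng.random() < a:
                            rho = prop_rho
                    else:
                        a = 0.0
                    if adapting:
                        s_rho *= np.exp(gamma * (a - cfg.target_accept_single))
                    else:
                        acc_counts["rho"] += float(a)
                        post_counts["rho"] += 1

            # ---- sigma2 conjugate inverse-gamma
            if cfg.sample_phi and cfg.fixed_sigma2 is None:
                sigma2 = 1.0 / rng.gamma(
                    cfg.sigma2_shape + 0.5 * M, 1.0 / (cfg.sigma2_scale + 0.5 * float(phi @ phi))
                )

            # ---- retain
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thinning == 0:
                draws_beta[keep] = beta
                draws_theta[keep] = theta
                draws_phi[keep] = phi
                draws_tau2[keep] = tau2
                draws_sigma2[keep] = sigma2
                draws_rho[keep] = rho
                lam_sum += lam
                keep += 1

        acceptance = {
            k: (acc_counts[k] / post_counts[k]) if post_counts[k] else np.nan
            for k in acc_counts
        }
        if post_counts["beta"] and acceptance["beta"] == 0.0:
            raise RuntimeError("sampler divergence: beta acceptance pinned at 0 after adaptation")

        fitted = np.full((self.n_areas, self.n_groups), np.nan)
        fitted[self.mask] = lam_sum / keep
        return CARPoissonResults(
            model=self,
            config=cfg,
            beta_draws=draws_beta[:keep],
            theta_draws=draws_theta[:keep],
            phi_draws=draws_phi[:keep],
            tau2_draws=draws_tau2[:keep],
            sigma2_draws=draws_sigma2[:keep],
            rho_draws=draws_rho[:keep],
            fitted_lambda=fitted,
            acceptance=acceptance,
        )


@dataclass
class CARPoissonResults:
    """Posterior draws, fitted values and diagnostics from a model fit."""

    model: CARPoissonModel
    config: MCMCConfig
    beta_draws: np.ndarray  # (S, 3)
    theta_draws: np.ndarray  # (S, n_areas)
    phi_draws: np.ndarray  # (S, n_strata)
    tau2_draws: np.ndarray
    sigma2_draws: np.ndarray
    rho_draws: np.ndarray
    fitted_lambda: np.ndarray  # (n_areas, n_groups); nan on unmodeled strata
    acceptance: dict

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    @property
    def beta_mean(self) -> np.ndarray:
        return self.beta_draws.mean(axis=0)

    def credible_interval(self, which: str = "beta1", level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed posterior credible interval for a scalar parameter."""
        draws = self._scalar_draws(which)
        lo, hi = np.percentile(draws, [50 * (1 - level), 100 - 50 * (1 - level)])
        return float(lo), float(hi)

    def _scalar_draws(self, which: str) -> np.ndarray:
        if which in COEF_NAMES:
            return self.beta_draws[:, COEF_NAMES.index(which)]
        if which == "tau2":
            return self.tau2_draws
        if which == "sigma2":
            return self.sigma2_draws
        if which == "rho":
            return self.rho_draws
        raise KeyError(which)

    def ess(self, which: str = "beta1") -> float:
        """Effective sample size (bulk) of a scalar parameter's chain."""
        import arviz as az

        return float(az.ess(np.asarray(self._scalar_draws(which))[None, :]))

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, 95% interval, ESS per parameter."""
        rows = []
        names = list(COEF_NAMES) + ["tau2", "sigma2", "rho"]
        for name in names:
            draws = self._scalar_draws(name)
            if draws.size == 0 or not np.isfinite(draws).all():
                continue
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "param": name,
                    "mean": draws.mean(),
                    "sd": draws.std(ddof=1),
                    "2.5%": lo,
                    "97.5%": hi,
                    "ess": self.ess(name),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def rate_ratios(self) -> pd.DataFrame:
        """Rate-ratio table: exp(posterior mean) and exponentiated 2.5/97.5
        posterior percentiles per regression coefficient.

        Requires at least 100 retained draws.
        """
        if self.n_draws < 100:
            raise ValueError("need at least 100 retained draws for rate ratios")
        rows = []
        for k, name in enumerate(COEF_NAMES):
            draws = self.beta_draws[:, k]
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "coefficient": name,
                    "rate_ratio": float(np.exp(draws.mean())),
                    "ci_low": float(np.exp(lo)),
                    "ci_high": float(np.exp(hi)),
                }
            )
        return pd.DataFrame(rows).set_index("coefficient")

    def predict_smr(self, expected: ExpectedCounts | None = None) -> np.ndarray:
        """Model-based SMR estimates: posterior-mean lambda divided by the
        expected count, per area x group (nan on unmodeled strata)."""
        exp_vals = (expected or self.model.expected).values
        if exp_vals.shape != self.fitted_lambda.shape:
            raise ValueError("expected counts misaligned with fit")
        out = np.full(exp_vals.shape, np.nan)
        ok = ~np.isnan(self.fitted_lambda)
        if (exp_vals[ok] <= 0).any():
            raise ValueError("SMR undefined where expected count is zero")
        out[ok] = self.fitted_lambda[ok] / exp_vals[ok]
        return out

    def draws_frame(self) -> pd.DataFrame:
        """Scalar-parameter draws as a tidy DataFrame (one column each)."""
        return pd.DataFrame(
            {
                "beta0": self.beta_draws[:, 0],
                "beta1": self.beta_draws[:, 1],
                "beta2": self.beta_draws[:, 2],
                "tau2": self.tau2_draws,
                "sigma2": self.sigma2_draws,
                "rho": self.rho_draws,
            }
        )


def fit_car_poisson(
    outcomes: OutcomeData,
    expected: ExpectedCounts,
    covariates: CovariateTable,
    graph: AdjacencyGraph,
    config: MCMCConfig | None = None,
) -> CARPoissonResults:
    """Functional wrapper: build a :class:`CARPoissonModel` and fit it."""
    return CARPoissonModel(outcomes, expected, covariates, graph).fit(config)


def rate_ratios(fit: CARPoissonResults) -> pd.DataFrame:
    """Rate-ratio summary of a fit (see :meth:`CARPoissonResults.rate_ratios`)."""
    return fit.rate_ratios()


def predict_smr(fit: CARPoissonResults, expected: ExpectedCounts | None = None) -> np.ndarray:
    """SMR estimates from a fit (see :meth:`CARPoissonResults.predict_smr`)."""
    return fit.predict_smr(expected)
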