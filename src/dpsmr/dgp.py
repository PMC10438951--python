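"""Data-generating process for the simulation study.

Outcome counts follow the same multilevel spatial Poisson model that is
later fitted:

    Y_ij ~ Poisson(lambda_ij)
    log(lambda_ij) = beta0 + beta1*I(minority)_ij + beta2*deprivation_i
                     + theta_i + phi_ij + log(P_ij)

with theta a proper-CAR Gaussian field on the area graph — conditionals
``theta_i | theta_{-i} ~ Normal(rho * w_i+^{-1} * sum_g w_ig theta_g,
tau2_gen / w_i+)`` — and phi_ij i.i.d. unstructured overdispersion.

Defaults are the generating constants of the study design: beta = (0, 0.4,
0.01), rho = 0.2 with unit CAR scale, and phi variance 0.25 (sd 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .population import CovariateTable
from .spatial import AdjacencyGraph
from .standardize import ExpectedCounts

__all__ = [
    "GeneratingParameters",
    "SpatialEffects",
    "OutcomeData",
    "car_precision",
    "sample_car_effects",
    "simulate_outcomes",
]


@dataclass(frozen=True)
class GeneratingParameters:
    """True parameters of the outcome model.

    Attributes
    ----------
    beta0, beta1, beta2 : float
        Intercept, minority-group effect, and deprivation effect on the log
        rate scale.
    rho : float
        CAR conditional-mean coefficient, in [0, 1).
    tau2_gen : float
        CAR scale (conditional variance is ``tau2_gen / w_i+``); the study
        design fixes this at 1.
    phi_sd : float
        Standard deviation of the unstructured overdispersion effect.
    seed : int
        Base seed for effect and outcome draws.
    """

    beta0: float = 0.0
    beta1: float = 0.4
    beta2: float = 0.01
    rho: float = 0.2
    tau2_gen: float = 1.0
    phi_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.phi_sd < 0:
            raise ValueError("phi_sd must be non-negative")
        if self.tau2_gen <= 0:
            raise ValueError("tau2_gen must be positive")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])


@dataclass(frozen=True)
class SpatialEffects:
    """Realized random effects: per-area theta and per-stratum phi."""

    theta: np.ndarray  # (n_areas,)
    phi: np.ndarray  # (n_areas, n_groups)

    def to_frame(self) -> pd.DataFrame:
        n_i, n_j = self.phi.shape
        idx = pd.MultiIndex.from_product(
            [np.arange(1, n_i + 1), np.arange(n_j)], names=["area", "group"]
        )
        df = pd.DataFrame({"phi": self.phi.ravel()}, index=idx).reset_index()
        df["theta"] = np.repeat(self.theta, n_j)
        return df[["area", "group", "theta", "phi"]]


@dataclass(frozen=True)
class OutcomeData:
    """Simulated (or observed) event counts with their generating means.

    ``lam`` is retained so evaluation can compare model SMR estimates
    against the simulation truth ``lam / P``.  ``mask`` marks the modeled
    strata (those with a positive expected count).
    """

    y: np.ndarray  # (n_areas, n_groups), int
    lam: np.ndarray | None = None  # generating means, same shape
    mask: np.ndarray | None = None  # bool, same shape; True = modeled stratum

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if (y < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "y", y.astype(np.int64))
        if self.mask is None:
            object.__setattr__(self, "mask", np.ones(y.shape, dtype=bool))
        if self.lam is not None and (np.asarray(self.lam)[self.mask] <= 0).any():
            raise ValueError("generating means must be positive on modeled strata")

    def to_frame(self) -> pd.DataFrame:
        n_i, n_j = self.y.shape
        idx = pd.MultiIndex.from_product(
            [np.arange(1, n_i + 1), np.arange(n_j)], names=["area", "group"]
        )
        df = pd.DataFrame({"y": self.y.ravel()}, index=idx).reset_index()
        df["lambda_true"] = (self.lam if self.lam is not None else np.full(self.y.shape, np.nan)).ravel()
        df["modeled"] = self.mask.ravel()
        return df


def car_precision(graph: AdjacencyGraph, rho: float, tau2: float = 1.0) -> np.ndarray:
    """Dense CAR precision matrix (D - rho*W) / tau2."""
    D = np.diag(graph.degrees.astype(float))
    return (D - rho * graph.weight_matrix.toarray()) / tau2


def sample_car_effects(
    graph: AdjacencyGraph,
    rho: float,
    seed: int | np.random.Generator = 0,
    tau2: float = 1.0,
    size: int | None = None,
) -> np.ndarray:
    """Draw from the zero-mean proper-CAR Gaussian field on ``graph``.

    The joint distribution is N(0, tau2 * (D - rho*W)^{-1}) with D the
    degree matrix; equivalently each conditional is
    Normal(rho * w_i+^{-1} * sum_g w_ig theta_g, tau2 / w_i+).

    Draws by solving ``L' x = z`` with L the upper Cholesky factor of the
    precision matrix and z standard normal.

    Parameters
    ----------
    size : int, optional
        Number of independent draws; returns shape (size, n_areas) if
        given, else (n_areas,).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    Q = car_precision(graph, rho, tau2)
    try:
        U = cholesky(Q, lower=False)  # Q = U'U
    except np.linalg.LinAlgError as err:  # pragma: no cover - cannot occur for rho in [0,1)
        raise ValueError("CAR precision matrix is not positive definite") from err
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = graph.n_areas
    z = rng.standard_normal((n, size if size is not None else 1))
    x = solve_triangular(U, z, lower=False)  # U x = z  ->  cov(x) = Q^{-1}
    return x[:, 0] if size is None else x.T


def simulate_outcomes(
    expected: ExpectedCounts,
    covariates: CovariateTable,
    params: GeneratingParameters,
    graph: AdjacencyGraph,
    rng: np.random.Generator | None = None,
    effects: SpatialEffects | None = None,
) -> tuple[OutcomeData, SpatialEffects]:
    """Simulate outcome counts from the spatial Poisson model.

    Fresh theta and phi are drawn on every call (each simulated dataset has
    its own realization of the random effects) unless ``effects`` is
    supplied, which injects fixed effects — used both for oracle tests and
    for the alternative fixed-effects-across-simulations reading.

    Strata with zero expected count are excluded from the model (masked);
    their counts are reported as 0.
    """
    P = expected.values
    if covariates.n_areas != P.shape[0] or graph.n_areas != P.shape[0]:
        raise ValueError("expected counts, covariates and graph disagree on the number of areas")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_areas, n_groups = P.shape
    if effects is None:
        theta = sample_car_effects(graph, params.rho, rng, tau2=params.tau2_gen)
        phi = rng.normal(0.0, params.phi_sd, size=(n_areas, n_groups))
        effects = SpatialEffects(theta, phi)

    ind = covariates.group_indicator(n_groups)
    eta = (
        params.beta0
        + params.beta1 * ind
        + params.beta2 * covariates.prop_pov[:, None]
        + effects.theta[:, None]
        + effects.phi
    )
    mask = P > 0
    lam = np.where(mask, P * np.exp(eta), np.nan)
    y = np.zeros(P.shape, dtype=np.int64)
    y[mask] = rng.poisson(lam[mask])
    return OutcomeData(y, lam=lam, mask=mask), effects
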