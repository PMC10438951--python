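"""Disclosure-avoidance noise for stratified population counts.

Emulates the qualitative behavior of census disclosure-avoidance systems:
independent integer-valued noise is added to every (area, group, age) cell
at a scale governed by the privacy-loss budget epsilon, followed by
postprocessing to non-negative integers.  Small counts therefore suffer
much larger *relative* perturbation than large counts — the phenomenon that
drives downstream distortion of small-group health estimates.

Mechanisms
----------
``discrete-laplace``
    Two-sided geometric distribution, P(k) proportional to exp(-eps*|k|),
    the canonical epsilon-DP mechanism for integer counts.  Pre-truncation
    variance 2*e^{-eps} / (1 - e^{-eps})^2.
``discrete-gaussian``
    Integer-rounded Gaussian with the same variance as the discrete-laplace
    mechanism at the given epsilon (stand-in for zero-concentrated-DP
    mechanisms used in production systems).

Postprocessing
--------------
``truncate-round``
    Clamp negative cells at zero.  Introduces a positive bias for cells with
    small true counts.
``controlled-total``
    After truncation, rescale each group's grand total back to the true
    total and re-integerize by largest-remainder rounding (ties broken by
    lowest cell index), mimicking the invariant-preserving step of
    production systems.

This emulator makes no claim to reproduce any production algorithm's budget
allocation or hierarchical multipass postprocessing; noise is applied once,
at the cell level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .population import PopulationTable

__all__ = ["PrivacyConfig", "privatize", "noise_scale"]

_MECHANISMS = ("discrete-laplace", "discrete-gaussian")
_POSTPROCESS = ("truncate-round", "controlled-total")


@dataclass(frozen=True)
class PrivacyConfig:
    """Privacy-noise settings.

    Attributes
    ----------
    epsilon : float
        Privacy-loss budget; must be > 0.  ``math.inf`` selects the
        identity mechanism (no noise — the "perfect accuracy" endpoint).
    mechanism : {"discrete-laplace", "discrete-gaussian"}
    postprocess : {"truncate-round", "controlled-total"}
    seed : int
        Noise stream seed; identical config and input give identical output.
    """

    epsilon: float = 6.0
    mechanism: str = "discrete-laplace"
    postprocess: str = "truncate-round"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be positive")
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if self.postprocess not in _POSTPROCESS:
            raise ValueError(f"postprocess must be one of {_POSTPROCESS}")

    def replace(self, **kw) -> "PrivacyConfig":
        return _dc_replace(self, **kw)


def noise_scale(epsilon: float, mechanism: str = "discrete-laplace") -> float:
    """Pre-truncation noise standard deviation for a mechanism at ``epsilon``.

    For the discrete Laplace (two-sided geometric) mechanism the variance is
    ``2 p / (1 - p)^2`` with ``p = e^{-epsilon}``; the discrete Gaussian is
    calibrated to the same variance.  Strictly decreasing in epsilon, and 0
    at ``epsilon = inf``.
    """
    if not (epsilon > 0):
        raise ValueError("epsilon must be positive")
    if mechanism not in _MECHANISMS:
        raise ValueError(f"mechanism must be one of {_MECHANISMS}")
    if math.isinf(epsilon):
        return 0.0
    p = math.exp(-epsilon)
    return math.sqrt(2.0 * p / (1.0 - p) ** 2)


def _sample_discrete_laplace(rng: np.random.Generator, epsilon: float, size) -> np.ndarray:
    """Two-sided geometric: difference of two i.i.d. geometric(1-p) - 1 draws.

    If G1, G2 are the number of failures before the first success with
    success probability 1 - p, then G1 - G2 has P(k) = (1-p)/(1+p) p^{|k|}.
    """
    p = math.exp(-epsilon)
    g1 = rng.geometric(1.0 - p, size=size) - 1
    g2 = rng.geometric(1.0 - p, size=size) - 1
    return g1 - g2


def sample_noise(rng: np.random.Generator, epsilon: float, mechanism: str, size) -> np.ndarray:
    """Raw integer noise draws (pre-postprocessing); exposed for calibration checks."""
    if mechanism == "discrete-laplace":
        return _sample_discrete_laplace(rng, epsilon, size)
    if mechanism == "discrete-gaussian":
        sd = noise_scale(epsilon, "discrete-laplace")
        return np.round(rng.normal(0.0, sd, size=size)).astype(np.int64)
    raise ValueError(f"mechanism must be one of {_MECHANISMS}")


def _largest_remainder_round(values: np.ndarray, target_total: int) -> np.ndarray:
    """Round non-negative reals to integers summing to ``target_total``.

    Floors every value, then distributes the shortfall one unit at a time to
    the largest fractional remainders; ties broken by lowest flat index.
    """
    floors = np.floor(values).astype(np.int64)
    shortfall = int(target_total - floors.sum())
    if shortfall <= 0:
        # over-allocation can only occur from numerical slop; trim greedily
        order = np.argsort(values - floors, kind="stable")
        out = floors.copy()
        for idx in order:
            if shortfall >= 0:
                break
            if out[idx] > 0:
                out[idx] -= 1
                shortfall += 1
        return out
    remainders = values - floors
    # stable argsort on -remainder -> ties resolved by lowest index
    order = np.argsort(-remainders, kind="stable")
    out = floors.copy()
    out[order[:shortfall]] += 1
    return out


def privatize(pop: PopulationTable, config: PrivacyConfig) -> PopulationTable:
    """Apply privacy noise and postprocessing to every cell of a table.

    With ``epsilon = inf`` the input is returned unchanged.  Output always
    satisfies the population-table invariants (non-negative integers on the
    full cross product).  Deterministic given ``config.seed``.
    """
    if math.isinf(config.epsilon):
        return pop
    rng = np.random.default_rng(config.seed)
    noise = sample_noise(rng, config.epsilon, config.mechanism, pop.counts.shape)
    noised = np.maximum(pop.counts + noise, 0).astype(np.int64)

    if config.postprocess == "controlled-total":
        out = np.empty_like(noised)
        for j in range(pop.n_groups):
            true_total = int(pop.counts[:, j, :].sum())
            grp = noised[:, j, :].astype(float)
            grp_total = grp.sum()
            if grp_total > 0:
                scaled = grp * (true_total / grp_total)
            else:
                # noise wiped out the whole group: spread the total uniformly
                scaled = np.full_like(grp, true_total / grp.size)
            out[:, j, :] = _largest_remainder_round(scaled.ravel(), true_total).reshape(grp.shape)
        noised = out

    return PopulationTable(
        noised, age_bands=pop.age_bands, group_labels=pop.group_labels, regime=pop.regime
    )
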