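"""Synthetic stratified populations and area-level covariates.

Generates area x racialized-group x age-band population count tables with
two demographic regimes observed in real state populations:

``concentrated``
    a small minority group clustered in a contiguous set of areas (like the
    Black population of Massachusetts, 6.6% statewide and concentrated
    around one metro area), producing many small and zero minority counts;
``diffuse``
    a large minority group spread broadly across areas (like the Black
    population of Georgia, 30.5% statewide).

These regimes are what make the downstream privacy-noise experiments
meaningful: relative noise is largest exactly where stratified counts are
small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial import AdjacencyGraph

__all__ = [
    "PopulationTable",
    "CovariateTable",
    "PopulationParams",
    "DEFAULT_AGE_BANDS",
    "generate_population",
    "generate_covariates",
]

# Seven age bands spanning ages 0-64, the premature-mortality range.
DEFAULT_AGE_BANDS: tuple[str, ...] = (
    "0-4",
    "5-14",
    "15-24",
    "25-34",
    "35-44",
    "45-54",
    "55-64",
)

# Mildly adult-weighted age composition; must sum to 1.
_DEFAULT_AGE_DIST: tuple[float, ...] = (0.07, 0.13, 0.14, 0.14, 0.15, 0.19, 0.18)


@dataclass(frozen=True)
class PopulationTable:
    """Non-negative integer counts ``n[i, j, a]`` by area, group, age band.

    The index set is the complete cross product of areas x groups x age
    bands; structural zeros are explicit.  Group 0 is the majority
    (NHW-like) group, group 1 the minority (Black-like) group.
    """

    counts: np.ndarray  # shape (n_areas, n_groups, n_age_bands), int64
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    group_labels: tuple[str, ...] = ("majority", "minority")
    regime: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("counts must be a 3-d array (area, group, age band)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integer-valued")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.shape[2] != len(self.age_bands):
            raise ValueError("age-band labels do not match counts shape")
        if counts.shape[1] != len(self.group_labels):
            raise ValueError("group labels do not match counts shape")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_areas(self) -> int:
        return self.counts.shape[0]

    @property
    def n_groups(self) -> int:
        return self.counts.shape[1]

    @property
    def n_age_bands(self) -> int:
        return self.counts.shape[2]

    def group_share(self, group: int = 1) -> float:
        """Fraction of the total population belonging to ``group``."""
        total = self.counts.sum()
        return float(self.counts[:, group, :].sum() / total) if total else 0.0

    def area_group_totals(self) -> np.ndarray:
        """Counts summed over age bands, shape (n_areas, n_groups)."""
        return self.counts.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with 1-based area indices."""
        n_i, n_j, n_a = self.counts.shape
        idx = pd.MultiIndex.from_product(
            [np.arange(1, n_i + 1), np.arange(n_j), list(self.age_bands)],
            names=["area", "group", "age_band"],
        )
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, regime: str = "") -> "PopulationTable":
        required = {"area", "group", "age_band", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"population table needs columns {sorted(required)}")
        areas = np.sort(df["area"].unique())
        groups = np.sort(df["group"].unique())
        bands = list(dict.fromkeys(df["age_band"]))  # keep file order
        pivot = df.set_index(["area", "group", "age_band"])["count"]
        full = pd.MultiIndex.from_product([areas, groups, bands])
        if len(df) != len(full) or pivot.index.duplicated().any():
            raise ValueError("population table must cover the complete area x group x age cross product exactly once")
        counts = pivot.reindex(full).to_numpy().reshape(len(areas), len(groups), len(bands))
        if np.isnan(counts).any():
            raise ValueError("population table has missing cells")
        labels = tuple(f"group{g}" for g in groups) if len(groups) != 2 else ("majority", "minority")
        return cls(counts.astype(np.int64), tuple(str(b) for b in bands), labels, regime)

    @classmethod
    def read_csv(cls, path, regime: str = "") -> "PopulationTable":
        return cls.from_frame(pd.read_csv(path), regime=regime)


@dataclass(frozen=True)
class CovariateTable:
    """Per-area deprivation covariate, centered and scaled across areas.

    ``prop_pov`` plays the role of an economic-deprivation proxy (share of
    residents in poverty); it enters the disease-mapping model standardized
    to sample mean 0 and standard deviation 1.
    """

    prop_pov: np.ndarray  # shape (n_areas,)

    def __post_init__(self) -> None:
        x = np.asarray(self.prop_pov, dtype=float)
        if x.ndim != 1:
            raise ValueError("prop_pov must be one-dimensional")
        if abs(x.mean()) > 1e-8 or abs(x.std(ddof=0) - 1.0) > 1e-8:
            raise ValueError("prop_pov must be centered and scaled (mean 0, sd 1)")
        object.__setattr__(self, "prop_pov", x)

    @property
    def n_areas(self) -> int:
        return self.prop_pov.shape[0]

    def group_indicator(self, n_groups: int = 2) -> np.ndarray:
        """Minority-group indicator I(group=1) expanded to (n_areas, n_groups)."""
        ind = np.zeros((self.n_areas, n_groups))
        ind[:, 1:] = 1.0
        return ind[:, : n_groups]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area": np.arange(1, self.n_areas + 1), "prop_pov": self.prop_pov}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CovariateTable":
        df = pd.read_csv(path).sort_values("area")
        return cls(df["prop_pov"].to_numpy())


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the stratified-population generator.

    Attributes
    ----------
    mean_total : float
        Mean total population per area; drawn negative-binomial around this
        (default 4000, census-tract-like).
    total_dispersion : float
        Negative-binomial size parameter; larger = less dispersed.
    minority_share : float
        Target statewide share of group 1, in (0, 1).
    age_dist : tuple of float
        Age-band composition simplex (shared by groups).
    concentration : float
        Sharpness of the spatial field controlling group-1 share; higher
        values concentrate the minority population more tightly.
    cluster_fraction : float
        Concentrated regime only: fraction of areas forming the contiguous
        high-minority cluster.
    """

    mean_total: float = 4000.0
    total_dispersion: float = 8.0
    minority_share: float = 0.305
    age_dist: tuple[float, ...] = _DEFAULT_AGE_DIST
    concentration: float = 4.0
    cluster_fraction: float = 0.12

    def __post_init__(self) -> None:
        if not 0.0 < self.minority_share < 1.0:
            raise ValueError("minority share must lie in (0, 1)")
        dist = np.asarray(self.age_dist, dtype=float)
        if dist.ndim != 1 or dist.size < 1 or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-8:
            raise ValueError("age distribution must be a simplex (non-negative, sums to 1)")


def _spatial_field(graph: AdjacencyGraph, rng: np.random.Generator, smooth_steps: int = 2) -> np.ndarray:
    """i.i.d. normal field smoothed by neighbor averaging: cheap spatial GP proxy."""
    x = rng.standard_normal(graph.n_areas)
    for _ in range(smooth_steps):
        x = 0.5 * x + 0.5 * graph.neighbor_sum(x) / graph.degrees
    return x


def _calibrate_shares(logits: np.ndarray, weights: np.ndarray, target: float) -> np.ndarray:
    """Shift logits by a constant so the weighted mean share hits ``target``."""
    from scipy.optimize import brentq

    def gap(c: float) -> float:
        p = 1.0 / (1.0 + np.exp(-(logits + c)))
        return float(np.average(p, weights=weights)) - target

    c = brentq(gap, -40.0, 40.0)
    return 1.0 / (1.0 + np.exp(-(logits + c)))


def generate_population(
    graph: AdjacencyGraph,
    regime: str,
    params: PopulationParams | None = None,
    seed: int = 0,
) -> PopulationTable:
    """Generate a stratified population table under a demographic regime.

    Per-area totals are negative-binomial around ``params.mean_total``.  The
    group-1 (minority) share of each area comes from a logistic-transformed
    spatial Gaussian field, recentered so the realized statewide share
    matches ``params.minority_share`` in expectation.  Under
    ``regime="concentrated"`` the field is dominated by a contiguous cluster
    grown from a seed area (high spatial autocorrelation of minority share);
    under ``regime="diffuse"`` the field is broad and mild.  Age-band counts
    are multinomial over ``params.age_dist``.

    Deterministic given ``seed``.
    """
    if regime not in ("concentrated", "diffuse"):
        raise ValueError(f"regime must be 'concentrated' or 'diffuse', got {regime!r}")
    if params is None:
        params = PopulationParams(minority_share=0.066 if regime == "concentrated" else 0.305)
    rng = np.random.default_rng(seed)

    n = graph.n_areas
    # total population per area: negative binomial via gamma-Poisson mixture
    size = params.total_dispersion
    lam = rng.gamma(shape=size, scale=params.mean_total / size, size=n)
    totals = rng.poisson(lam) + 1  # avoid fully empty areas

    field_vals = _spatial_field(graph, rng)
    if regime == "concentrated":
        # grow a contiguous cluster from a seed area by breadth-first search
        n_cluster = max(1, int(round(params.cluster_fraction * n)))
        seed_area = int(rng.integers(n))
        in_cluster = np.zeros(n, dtype=bool)
        frontier = [seed_area]
        in_cluster[seed_area] = True
        count = 1
        while count < n_cluster and frontier:
            nxt: list[int] = []
            for a in frontier:
                nbrs = np.flatnonzero(graph.weight_matrix[[a], :].toarray().ravel())
                for b in nbrs:
                    if not in_cluster[b] and count < n_cluster:
                        in_cluster[b] = True
                        nxt.append(int(b))
                        count += 1
            frontier = nxt
        logits = params.concentration * (in_cluster.astype(float) - 0.5) + 0.6 * field_vals
    else:
        logits = 0.8 * field_vals

    shares = _calibrate_shares(logits, totals.astype(float), params.minority_share)
    minority = rng.binomial(totals, shares)
    majority = totals - minority

    age_dist = np.asarray(params.age_dist, dtype=float)
    counts = np.empty((n, 2, age_dist.size), dtype=np.int64)
    counts[:, 0, :] = rng.multinomial(majority, age_dist)
    counts[:, 1, :] = rng.multinomial(minority, age_dist)
    return PopulationTable(counts, regime=regime)


def generate_covariates(
    graph: AdjacencyGraph,
    pop: PopulationTable,
    seed: int = 0,
    spatial_weight: float = 0.5,
) -> CovariateTable:
    """Draw a per-area deprivation proxy with mild positive spatial
    autocorrelation, then center and scale it to mean 0, sd 1.

    The raw draw is an i.i.d. normal field averaged once with its neighbor
    means (``spatial_weight`` controls the mix), giving plausible positive
    spatial autocorrelation without building in any dependence on the
    population's group structure.
    """
    if pop.n_areas != graph.n_areas:
        raise ValueError("population and graph disagree on the number of areas")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(graph.n_areas)
    x = (1.0 - spatial_weight) * x + spatial_weight * graph.neighbor_sum(x) / graph.degrees
    sd = x.std(ddof=0)
    if sd < 1e-12:
        raise ValueError("degenerate covariate draw: zero variance, cannot scale")
    return CovariateTable((x - x.mean()) / sd)
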