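"""Indirect age standardization: expected event counts and SMRs.

Indirect standardization applies reference (e.g., statewide) age-specific
event rates to a local age-stratified population, giving the event count
expected if the local population experienced the reference rates:

    P_ij = years * sum_a n_{i,j,a} * r_a

The standardized mortality (morbidity) ratio is then observed / expected.
Expected counts are the denominators — and model offsets — everywhere in
this package, so noise injected into the population counts propagates to
them directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import PopulationTable

__all__ = [
    "AgeRateTable",
    "ExpectedCounts",
    "compute_reference_rates",
    "expected_counts",
    "smr",
    "DEFAULT_REFERENCE_RATES",
]

# Plausible all-cause premature-mortality rates (events per person-year) for
# the default 7 age bands 0-4 ... 55-64; rise steeply with age as observed
# US mortality does.  Used when no empirical death counts are supplied.
DEFAULT_REFERENCE_RATES: tuple[float, ...] = (
    0.0012,
    0.0002,
    0.0008,
    0.0012,
    0.0020,
    0.0045,
    0.0095,
)


@dataclass(frozen=True)
class AgeRateTable:
    """Reference event rates per age band (events per person per year).

    Rates are shared across groups by default (total-population reference
    rates); group-specific rates can be represented by a 2-d array of shape
    (n_groups, n_age_bands).
    """

    rates: np.ndarray  # (n_age_bands,) or (n_groups, n_age_bands)
    age_bands: tuple[str, ...]
    period_years: int = 1

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim not in (1, 2):
            raise ValueError("rates must be 1-d (shared) or 2-d (group-specific)")
        if ((r < 0) | (r > 1)).any():
            raise ValueError("rates must lie in [0, 1]")
        if r.shape[-1] != len(self.age_bands):
            raise ValueError("one rate per age band required")
        if self.period_years < 1:
            raise ValueError("period_years must be a positive integer")
        object.__setattr__(self, "rates", r)

    def to_frame(self) -> pd.DataFrame:
        if self.rates.ndim == 1:
            return pd.DataFrame({"age_band": list(self.age_bands), "rate": self.rates})
        rows = [
            {"group": j, "age_band": band, "rate": self.rates[j, a]}
            for j in range(self.rates.shape[0])
            for a, band in enumerate(self.age_bands)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "AgeRateTable":
        df = pd.read_csv(path)
        if "group" in df.columns:
            bands = list(dict.fromkeys(df["age_band"]))
            groups = np.sort(df["group"].unique())
            rates = (
                df.set_index(["group", "age_band"])["rate"]
                .reindex(pd.MultiIndex.from_product([groups, bands]))
                .to_numpy()
                .reshape(len(groups), len(bands))
            )
            return cls(rates, tuple(str(b) for b in bands))
        return cls(df["rate"].to_numpy(), tuple(str(b) for b in df["age_band"]))


@dataclass(frozen=True)
class ExpectedCounts:
    """Age-standardized expected event counts P_ij per area x group.

    ``provenance`` records which population table and privacy configuration
    produced the denominators, so simulation-study reports can state exactly
    which arm each offset came from.
    """

    values: np.ndarray  # (n_areas, n_groups), float, >= 0
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("expected counts must be 2-d (area x group)")
        if (v < 0).any():
            raise ValueError("expected counts must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n_i, n_j = self.values.shape
        idx = pd.MultiIndex.from_product(
            [np.arange(1, n_i + 1), np.arange(n_j)], names=["area", "group"]
        )
        return pd.DataFrame({"expected": self.values.ravel()}, index=idx).reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, provenance: str = "") -> "ExpectedCounts":
        df = pd.read_csv(path)
        areas = np.sort(df["area"].unique())
        groups = np.sort(df["group"].unique())
        values = (
            df.set_index(["area", "group"])["expected"]
            .reindex(pd.MultiIndex.from_product([areas, groups]))
            .to_numpy()
            .reshape(len(areas), len(groups))
        )
        return cls(values, provenance=provenance)


def compute_reference_rates(
    pop: PopulationTable, deaths_by_age: np.ndarray
) -> AgeRateTable:
    """Reference rates r_a = (total deaths in band a) / (total population in band a).

    Deaths and populations are pooled over all areas and groups, giving
    total-population (race-shared) reference rates.

    Raises if any band has deaths but zero population.
    """
    deaths = np.asarray(deaths_by_age, dtype=float)
    if deaths.shape != (pop.n_age_bands,):
        raise ValueError("deaths_by_age must have one entry per age band")
    if (deaths < 0).any():
        raise ValueError("death counts must be non-negative")
    band_pop = pop.counts.sum(axis=(0, 1)).astype(float)
    bad = (deaths > 0) & (band_pop == 0)
    if bad.any():
        band = pop.age_bands[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"deaths recorded in age band {band!r} with zero population")
    rates = np.divide(deaths, band_pop, out=np.zeros_like(deaths), where=band_pop > 0)
    return AgeRateTable(rates, pop.age_bands)


def expected_counts(
    pop: PopulationTable, rates: AgeRateTable, years: int = 1, provenance: str = ""
) -> ExpectedCounts:
    """Indirectly standardized expected counts P_ij = years * sum_a n_ija * r_a.

    Age bands of the population table and rate table must match exactly.
    Multi-year expected counts are the 1-year counts scaled by ``years``.
    """
    if tuple(rates.age_bands) != tuple(pop.age_bands):
        raise ValueError(
            f"age bands mismatch: population has {pop.age_bands}, rates have {rates.age_bands}"
        )
    if years < 1 or int(years) != years:
        raise ValueError("years must be a positive integer")
    if rates.rates.ndim == 1:
        p = pop.counts.astype(float) @ rates.rates
    else:
        if rates.rates.shape[0] != pop.n_groups:
            raise ValueError("group-specific rates must cover every group")
        p = np.einsum("ija,ja->ij", pop.counts.astype(float), rates.rates)
    return ExpectedCounts(float(years) * p, provenance=provenance)


def smr(observed: float, expected: float) -> float:
    """Standardized mortality ratio: observed / expected; expected must be > 0."""
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if not expected > 0:
        raise ValueError("SMR undefined for expected count <= 0")
    return float(observed) / float(expected)
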