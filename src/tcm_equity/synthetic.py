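"""Synthetic province-year panels with controllable equity structure.

The generator emulates the statistical shape of the real panel: 31 provinces
in 4 regions, heavy-tailed population and area, a regional per-capita GDP
gradient (Eastern > Central > Northeast > Western by default), resource
allocation coupled to wealth through an exponent ``gamma``, and
near-exponential national growth.  It exists so every equity and
forecasting stage can be exercised end to end without any external data:

* ``gamma = 0`` with zero noise allocates every resource proportionally to
  population, so the concentration index and by-population Theil index are
  zero up to integer rounding;
* ``gamma > 0`` shifts resources toward richer provinces (CI > 0), and
  ``gamma < 0`` toward poorer ones (CI < 0);
* national totals grow by a factor e^g per year, so GM(1,1) fits them
  nearly exactly.

Resource counts are rounded last, with largest-remainder correction, so the
yearly national totals match the target exactly and aggregation identities
hold in integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigError
from .panel import (
    INDICATORS,
    REGION_ORDER,
    DEFAULT_PARTITION,
    ProvinceYearRecord,
    RegionPartition,
)

#: Per-capita GDP ordering of the regions, poorest first.
_GDP_RANK = {"Western": 0, "Northeast": 1, "Central": 2, "Eastern": 3}

#: First-year national totals, matching the scale of the real 2016 values.
_BASE_TOTALS = {
    "institutions": 50_000,
    "beds": 1_000_000,
    "practitioners": 480_000,
    "pharmacists": 120_000,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic panel generator.

    Parameters
    ----------
    seed : random seed; a fixed seed yields a byte-identical panel.
    n_years : number of consecutive years (default 5).
    first_year : first calendar year.
    provinces_per_region : counts per region in REGION_ORDER, default
        (3, 10, 6, 12) matching the real partition.
    population_dispersion, area_dispersion : log-scale sigma of the
        lognormal draws for resident population and land area.
    gdp_gradient : ratio of richest-region to poorest-region mean
        per-capita GDP.
    gamma : wealth-gradient exponent coupling allocation to per-capita GDP.
    growth : annual exponential growth rate g of national totals.
    noise : sigma of multiplicative lognormal noise on allocations and on
        yearly growth.
    """

    seed: int = 0
    n_years: int = 5
    first_year: int = 2016
    provinces_per_region: tuple[int, ...] = (3, 10, 6, 12)
    population_dispersion: float = 0.8
    area_dispersion: float = 1.0
    gdp_gradient: float = 2.5
    gamma: float = 0.0
    growth: float = 0.08
    noise: float = 0.0
    base_totals: dict[str, int] = field(default_factory=lambda: dict(_BASE_TOTALS))

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        if len(self.provinces_per_region) != len(REGION_ORDER):
            raise ConfigError("provinces_per_region must list one count per region")
        if any(c < 1 for c in self.provinces_per_region):
            raise ConfigError("each region needs at least one province")
        if self.population_dispersion < 0 or self.area_dispersion < 0:
            raise ConfigError("dispersions must be nonnegative")
        if self.gdp_gradient <= 0:
            raise ConfigError("gdp_gradient must be positive")
        if self.noise < 0:
            raise ConfigError("noise must be nonnegative")
        if any(t <= 0 for t in self.base_totals.values()):
            raise ConfigError("base totals must be positive")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``.

    Floors the exact quotas and hands the remaining units to the largest
    fractional parts (ties broken by index order), so the result sums to
    ``total`` exactly.
    """
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def _partition_for(config: SyntheticConfig) -> RegionPartition:
    if config.provinces_per_region == (3, 10, 6, 12):
        return DEFAULT_PARTITION
    mapping = {}
    for region, count in zip(REGION_ORDER, config.provinces_per_region):
        for i in range(count):
            mapping[f"{region}-{i + 1:02d}"] = region
    return RegionPartition(mapping=mapping)


def generate_panel(config: SyntheticConfig) -> list[ProvinceYearRecord]:
    """Draw a full province-year panel under the given configuration."""
    rng = np.random.default_rng(config.seed)
    partition = _partition_for(config)
    provinces = []
    for region in REGION_ORDER:
        provinces.extend(sorted(partition.provinces(region)))
    regions = [partition.region_of(p) for p in provinces]
    n = len(provinces)

    population = 30e6 * rng.lognormal(0.0, config.population_dispersion, n)
    area = 300e3 * rng.lognormal(0.0, config.area_dispersion, n)
    rank = np.array([_GDP_RANK[r] for r in regions], dtype=float)
    pc_gdp = (
        50e3
        * config.gdp_gradient ** (rank / (len(REGION_ORDER) - 1))
        * rng.lognormal(0.0, 0.5 * config.noise, n)
    )
    gdp = pc_gdp * population

    # Allocation weights are drawn once per province-indicator, so a
    # province's relative endowment is stable across years.
    rel_wealth = pc_gdp / pc_gdp.mean()
    alloc = {
        ind: population
        * rel_wealth**config.gamma
        * rng.lognormal(0.0, config.noise, n)
        for ind in INDICATORS
    }

    growth_noise = rng.normal(0.0, 0.25 * config.noise, config.n_years)
    records = []
    for t in range(config.n_years):
        year = config.first_year + t
        counts = {}
        for ind in INDICATORS:
            total = int(
                round(
                    config.base_totals[ind]
                    * np.exp(config.growth * t + growth_noise[t])
                )
            )
            counts[ind] = _largest_remainder(alloc[ind], total)
        for i, prov in enumerate(provinces):
            records.append(
                ProvinceYearRecord(
                    province=prov,
                    region=regions[i],
                    year=year,
                    population=float(np.round(population[i])),
                    area_km2=float(np.round(area[i])),
                    gdp=float(np.round(gdp[i])),
                    resources={ind: int(counts[ind][i]) for ind in INDICATORS},
                )
            )
    return records


def generate(seed: int = 0, **overrides) -> list[ProvinceYearRecord]:
    """Convenience wrapper: generate a panel from keyword overrides."""
    return generate_panel(replace(SyntheticConfig(seed=seed), **overrides))
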