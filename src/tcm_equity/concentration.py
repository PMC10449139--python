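"""Concentration index of a resource with respect to economic rank.

The concentration index (CI) summarises whether a health resource is
disproportionately held by units ranked higher on per-capita GDP.  Units are
ordered poorest-first; X_i is the cumulative population share and Y_i the
cumulative resource share (X_0 = Y_0 = 0).  The index is twice the area
between the concentration curve and the diagonal, computed in trapezoid
form:

    CI = 1 - sum_i (X_i - X_{i-1}) (Y_i + Y_{i-1})

CI lies in [-1, 1]; CI > 0 means the resource favours richer units, CI < 0
poorer units, and CI = 0 proportional allocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, InsufficientDataError, UndefinedIndexError
from .panel import (
    INDICATORS,
    ProvinceYearRecord,
    RegionPartition,
    panel_years,
    records_for_year,
    region_aggregate,
)

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class ShareSeries:
    """Aligned weight and resource shares of ordered units.

    ``rank_values``, when given, are the values (here per-capita GDP) that
    the units were ordered by; they let the index computation verify the
    poorest-first contract instead of trusting the caller.
    """

    units: tuple[str, ...]
    weight_shares: tuple[float, ...]
    resource_shares: tuple[float, ...]
    rank_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.units)
        if len(self.weight_shares) != n or len(self.resource_shares) != n:
            raise ContractError("units, weight and resource shares must align")
        w = np.asarray(self.weight_shares)
        y = np.asarray(self.resource_shares)
        if (w < -_SHARE_TOL).any() or (y < -_SHARE_TOL).any():
            raise ContractError("shares must be nonnegative")
        if abs(w.sum() - 1.0) > _SHARE_TOL or abs(y.sum() - 1.0) > _SHARE_TOL:
            raise ContractError("weight and resource shares must each sum to 1")

    @property
    def cumulative_weight(self) -> np.ndarray:
        """X_0..X_n with X_0 = 0."""
        return np.concatenate([[0.0], np.cumsum(self.weight_shares)])

    @property
    def cumulative_resource(self) -> np.ndarray:
        """Y_0..Y_n with Y_0 = 0."""
        return np.concatenate([[0.0], np.cumsum(self.resource_shares)])


def rank_by_gdp_per_capita(
    records: Sequence[ProvinceYearRecord],
) -> list[ProvinceYearRecord]:
    """Order one year's records ascending by per-capita GDP.

    Ties are broken by ascending province name so the ordering is
    deterministic and reproducible.
    """
    if len(records) < 2:
        raise InsufficientDataError("ranking needs at least 2 units")
    return sorted(records, key=lambda r: (r.gdp_per_capita, r.province))


def share_series(
    records: Sequence[ProvinceYearRecord],
    indicator: str,
    partition: RegionPartition | None = None,
    unit: str = "province",
) -> ShareSeries:
    """Build the poorest-first ShareSeries for one year of records.

    ``unit='province'`` ranks the individual provinces; ``unit='region'``
    first aggregates to the four regions and ranks those.
    """
    if indicator not in INDICATORS:
        raise KeyError(f"unknown indicator {indicator!r}")
    if unit == "region":
        year = records[0].year
        agg = region_aggregate(records, indicator, year)
        rows = [
            (region, t.population, t.resource, t.gdp / t.population)
            for region, t in agg.items()
        ]
        rows.sort(key=lambda r: (r[3], r[0]))
        names = tuple(r[0] for r in rows)
        pops = np.array([r[1] for r in rows], dtype=float)
        res = np.array([r[2] for r in rows], dtype=float)
        ranks = tuple(r[3] for r in rows)
    elif unit == "province":
        ordered = rank_by_gdp_per_capita(records)
        names = tuple(r.province for r in ordered)
        pops = np.array([r.population for r in ordered], dtype=float)
        res = np.array([r.resources[indicator] for r in ordered], dtype=float)
        ranks = tuple(r.gdp_per_capita for r in ordered)
    else:
        raise ContractError(f"unit must be 'province' or 'region', got {unit!r}")
    if res.sum() <= 0:
        raise UndefinedIndexError(
            f"total {indicator} is zero; concentration index undefined"
        )
    return ShareSeries(
        units=names,
        weight_shares=tuple(pops / pops.sum()),
        resource_shares=tuple(res / res.sum()),
        rank_values=ranks,
    )


def concentration_index(shares: ShareSeries) -> float:
    """Trapezoid-form CI of an ordered ShareSeries.

    Raises ContractError if ``rank_values`` are present but not ascending
    (the units must be ordered poorest-first).
    """
    if shares.rank_values is not None:
        rv = np.asarray(shares.rank_values)
        if (np.diff(rv) < 0).any():
            raise ContractError("units must be ordered ascending by rank value")
    x = shares.cumulative_weight
    y = shares.cumulative_resource
    return float(1.0 - np.sum(np.diff(x) * (y[1:] + y[:-1])))


def concentration_table(
    records: Sequence[ProvinceYearRecord],
    partition: RegionPartition | None = None,
    unit: str = "province",
) -> pd.DataFrame:
    """Per-year x per-indicator CI table (rows = years, columns = indicators)."""
    rows = []
    for year in panel_years(records):
        year_records = records_for_year(records, year)
        row: dict[str, float | int] = {"year": year}
        for ind in INDICATORS:
            row[ind] = concentration_index(
                share_series(year_records, ind, partition, unit=unit)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")
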