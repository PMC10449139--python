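"""Theil index of resource allocation and its within/between decomposition.

T = sum_i P_i log(P_i / Y_i), where P_i is a unit's share of the weight
basis (population, or land area for the geographic variant) and Y_i its
share of the resource.  T >= 0, with T = 0 iff the resource is allocated
proportionally to the weight.  Over provinces grouped into regions the index
decomposes exactly:

    T_total = T_between + sum_g P_g T_g   (within term)

where T_between is the Theil index over region aggregates and T_g the index
inside region g on renormalised shares.  Contribution rates express the two
components as percentages of the total; they are invariant to the logarithm
base, which therefore only affects the absolute index values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, TCMEquityError, UndefinedIndexError
from .panel import (
    INDICATORS,
    ProvinceYearRecord,
    RegionPartition,
    panel_years,
    records_for_year,
)

_DECOMP_TOL = 1e-9

WEIGHT_BASES = ("population", "geography")


@dataclass(frozen=True)
class TheilDecomposition:
    total: float
    within: float
    between: float
    per_region_within: Mapping[str, float]
    log_base: float | None  # None means natural log

    @property
    def within_pct(self) -> float:
        return contribution_rates(self)[0]

    @property
    def between_pct(self) -> float:
        return contribution_rates(self)[1]


def theil_index(
    weight_shares: Sequence[float],
    resource_shares: Sequence[float],
    base: float | None = None,
) -> float:
    """T = sum_i P_i log(P_i / Y_i); units with P_i = 0 contribute 0.

    ``base=None`` selects the natural logarithm.
    """
    p = np.asarray(weight_shares, dtype=float)
    y = np.asarray(resource_shares, dtype=float)
    if p.shape != y.shape:
        raise ContractError("weight and resource shares must align")
    if abs(p.sum() - 1.0) > 1e-9 or abs(y.sum() - 1.0) > 1e-9:
        raise ContractError("weight and resource shares must each sum to 1")
    bad = np.nonzero((p > 0) & (y == 0))[0]
    if bad.size:
        raise UndefinedIndexError(
            f"unit(s) {bad.tolist()} have positive weight but zero resource; "
            "Theil index diverges"
        )
    mask = p > 0
    t = float(np.sum(p[mask] * np.log(p[mask] / y[mask])))
    if base is not None:
        t /= math.log(base)
    return t


def _shares(records: Sequence[ProvinceYearRecord], indicator: str, weight: str):
    if weight == "population":
        w = np.array([r.population for r in records], dtype=float)
    elif weight == "geography":
        w = np.array([r.area_km2 for r in records], dtype=float)
    else:
        raise ContractError(
            f"weight basis must be one of {WEIGHT_BASES}, got {weight!r}"
        )
    y = np.array([r.resources[indicator] for r in records], dtype=float)
    if y.sum() <= 0:
        raise UndefinedIndexError(f"total {indicator} is zero")
    return w / w.sum(), y / y.sum()


def theil_decompose(
    records: Sequence[ProvinceYearRecord],
    indicator: str,
    weight: str = "population",
    partition: RegionPartition | None = None,
    base: float | None = None,
    year: int | None = None,
) -> TheilDecomposition:
    """Decompose the province-level Theil index by region for one year.

    The total is computed twice — directly over provinces and as
    within + between — and a discrepancy beyond 1e-9 raises an
    internal-consistency error rather than returning silently wrong numbers.
    """
    if indicator not in INDICATORS:
        raise KeyError(f"unknown indicator {indicator!r}")
    if year is not None:
        records = records_for_year(records, year)
    years = {r.year for r in records}
    if len(years) != 1:
        raise ContractError("decomposition runs on a single year of records")

    p, y = _shares(records, indicator, weight)
    total_direct = theil_index(p, y, base=base)

    regions: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        regions.setdefault(r.region, []).append(i)

    between_p, between_y, labels = [], [], []
    within = 0.0
    per_region: dict[str, float] = {}
    for region, idx in regions.items():
        pg = float(p[idx].sum())
        yg = float(y[idx].sum())
        labels.append(region)
        between_p.append(pg)
        between_y.append(yg)
        if pg > 0:
            tg = theil_index(p[idx] / pg, y[idx] / yg, base=base)
        else:
            tg = 0.0
        per_region[region] = pg * tg
        within += pg * tg
    between = theil_index(between_p, between_y, base=base)

    if abs(total_direct - (within + between)) > _DECOMP_TOL:
        raise TCMEquityError(
            "internal consistency failure: direct Theil "
            f"{total_direct} != within+between {within + between}"
        )
    return TheilDecomposition(
        total=total_direct,
        within=within,
        between=between,
        per_region_within=per_region,
        log_base=base,
    )


def contribution_rates(decomposition: TheilDecomposition) -> tuple[float, float]:
    """(within%, between%) of the total; raises if the total is zero."""
    if decomposition.total <= 0:
        raise UndefinedIndexError(
            "contribution rates undefined for a zero total Theil index"
        )
    w = 100.0 * decomposition.within / decomposition.total
    b = 100.0 * decomposition.between / decomposition.total
    return w, b


def theil_table(
    records: Sequence[ProvinceYearRecord],
    weight: str = "population",
    partition: RegionPartition | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Tidy per-year x per-indicator table of total/within/between and rates."""
    rows = []
    for yr in panel_years(records):
        for ind in INDICATORS:
            d = theil_decompose(records, ind, weight, partition, base, year=yr)
            row = {
                "year": yr,
                "indicator": ind,
                "weight_basis": weight,
                "total": d.total,
                "within": d.within,
                "between": d.between,
            }
            if d.total > 0:
                row["within_pct"], row["between_pct"] = contribution_rates(d)
            else:
                row["within_pct"] = row["between_pct"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
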