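"""Health-resource and population agglomeration degrees (HRAD, PAD).

HRAD of a region is its share of the national resource divided by its share
of national land area — the amount of resource gathered on 1% of the
country's land area, relative to the national average density.  PAD is the
same ratio for population.  HRAD < 1 flags insufficient geographic
provision; HRAD/PAD compares resource density to population density, with
values above 1 meaning provision outpaces the agglomerated population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import TCMEquityError
from .panel import (
    INDICATORS,
    ProvinceYearRecord,
    RegionPartition,
    region_aggregate,
)


def agglomeration_degree(
    part: float, whole: float, area_part: float, area_whole: float
) -> float:
    """(part/whole) / (area_part/area_whole)."""
    if whole <= 0 or area_part <= 0 or area_whole <= 0:
        raise TCMEquityError("agglomeration degree needs positive totals and areas")
    return (part / whole) / (area_part / area_whole)


def _flag(value: float) -> str:
    if value > 1:
        return "above"
    if value < 1:
        return "below"
    return "balanced"


@dataclass(frozen=True)
class AgglomerationRow:
    region: str
    year: int
    pad: float
    hrad: Mapping[str, float]
    hrad_over_pad: Mapping[str, float]

    def hrad_flag(self, indicator: str) -> str:
        """'below' = geographic provision insufficient (HRAD < 1)."""
        return _flag(self.hrad[indicator])

    def ratio_flag(self, indicator: str) -> str:
        """'above' = provision better than the agglomerated population."""
        return _flag(self.hrad_over_pad[indicator])


def agglomeration_table(
    records: Sequence[ProvinceYearRecord],
    year: int,
    partition: RegionPartition | None = None,
) -> list[AgglomerationRow]:
    """One row per region with PAD, per-indicator HRAD, and HRAD/PAD."""
    aggs = {ind: region_aggregate(records, ind, year) for ind in INDICATORS}
    any_agg = aggs[INDICATORS[0]]
    area_whole = sum(t.area_km2 for t in any_agg.values())
    pop_whole = sum(t.population for t in any_agg.values())
    rows = []
    for region in any_agg:
        area_part = any_agg[region].area_km2
        pad = agglomeration_degree(
            any_agg[region].population, pop_whole, area_part, area_whole
        )
        hrad = {}
        for ind in INDICATORS:
            whole = sum(t.resource for t in aggs[ind].values())
            hrad[ind] = agglomeration_degree(
                aggs[ind][region].resource, whole, area_part, area_whole
            )
        rows.append(
            AgglomerationRow(
                region=region,
                year=year,
                pad=pad,
                hrad=hrad,
                hrad_over_pad={ind: hrad[ind] / pad for ind in INDICATORS},
            )
        )
    return rows


def agglomeration_frame(rows: Sequence[AgglomerationRow]) -> pd.DataFrame:
    """Flatten AgglomerationRows into a tidy table."""
    out = []
    for r in rows:
        rec: dict[str, object] = {"year": r.year, "region": r.region, "PAD": r.pad}
        for ind in INDICATORS:
            rec[f"HRAD_{ind}"] = r.hrad[ind]
            rec[f"HRAD_over_PAD_{ind}"] = r.hrad_over_pad[ind]
            rec[f"flag_hrad_{ind}"] = r.hrad_flag(ind)
            rec[f"flag_ratio_{ind}"] = r.ratio_flag(ind)
        out.append(rec)
    return pd.DataFrame(out)
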