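"""Province-year panel: records, region partition, loading and aggregation.

The unit of observation is one province in one calendar year, carrying
resident population, land area (km²), GDP, and four health-resource counts:
TCM medical institutions, TCM beds, practitioners (assistants) of TCM, and
Chinese pharmacists.  Provinces are partitioned into the four customary
economic regions of mainland China (Northeast, Eastern, Central, Western);
Hong Kong, Macao and Taiwan are outside the panel's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    AggregationError,
    PartitionError,
    SchemaError,
    ValidationError,
)

#: Canonical short names of the four resource indicators, in reporting order.
INDICATORS: tuple[str, ...] = ("institutions", "beds", "practitioners", "pharmacists")

#: Human-readable indicator labels used in printed tables.
INDICATOR_LABELS: dict[str, str] = {
    "institutions": "TCM medical institutions",
    "beds": "TCM beds",
    "practitioners": "Practitioners (assistants) of TCM",
    "pharmacists": "Chinese pharmacists",
}

REGION_ORDER: tuple[str, ...] = ("Northeast", "Eastern", "Central", "Western")

_DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "Northeast": ("Heilongjiang", "Jilin", "Liaoning"),
    "Eastern": (
        "Beijing", "Tianjin", "Hebei", "Shandong", "Jiangsu",
        "Shanghai", "Zhejiang", "Fujian", "Guangdong", "Hainan",
    ),
    "Central": ("Shanxi", "Henan", "Hunan", "Hubei", "Jiangxi", "Anhui"),
    "Western": (
        "Chongqing", "Sichuan", "Guangxi", "Yunnan", "Guizhou", "Shaanxi",
        "Gansu", "Inner Mongolia", "Qinghai", "Ningxia", "Xinjiang", "Tibet",
    ),
}

PANEL_COLUMNS: tuple[str, ...] = (
    "province", "region", "year", "population", "area_km2", "gdp",
) + INDICATORS


@dataclass(frozen=True)
class RegionPartition:
    """Mapping of province names to one of the four region labels.

    Province names are matched exactly after whitespace trimming; no fuzzy
    aliasing is attempted, so data errors surface rather than being absorbed.
    """

    mapping: Mapping[str, str]
    region_order: tuple[str, ...] = REGION_ORDER

    def __post_init__(self) -> None:
        labels = set(self.mapping.values())
        unknown = labels - set(self.region_order)
        if unknown:
            raise PartitionError(f"unknown region labels: {sorted(unknown)}")

    def region_of(self, province: str) -> str:
        name = province.strip()
        try:
            return self.mapping[name]
        except KeyError:
            raise PartitionError(
                f"province {name!r} not covered by the region partition"
            ) from None

    def provinces(self, region: str | None = None) -> tuple[str, ...]:
        if region is None:
            return tuple(self.mapping)
        return tuple(p for p, r in self.mapping.items() if r == region)

    @classmethod
    def default(cls) -> "RegionPartition":
        """The 31-province partition of mainland China into four regions."""
        mapping = {
            p: region for region, provs in _DEFAULT_REGIONS.items() for p in provs
        }
        return cls(mapping=mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionPartition":
        """Read a two-column ``province,region`` override file."""
        df = pd.read_csv(path, comment="#")
        missing = {"province", "region"} - set(df.columns)
        if missing:
            raise SchemaError(f"partition file missing columns: {sorted(missing)}")
        return cls(
            mapping={
                str(p).strip(): str(r).strip()
                for p, r in zip(df["province"], df["region"])
            }
        )


DEFAULT_PARTITION = RegionPartition.default()


@dataclass(frozen=True)
class ProvinceYearRecord:
    """One province in one year: covariates plus the four resource counts."""

    province: str
    region: str
    year: int
    population: float
    area_km2: float
    gdp: float
    resources: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in (
            ("population", self.population),
            ("area_km2", self.area_km2),
            ("gdp", self.gdp),
        ):
            if not value > 0:
                raise ValidationError(
                    f"{self.province} {self.year}: {name} must be > 0, got {value}"
                )
        for ind in INDICATORS:
            if ind not in self.resources:
                raise ValidationError(
                    f"{self.province} {self.year}: missing resource {ind!r}"
                )
            if self.resources[ind] < 0:
                raise ValidationError(
                    f"{self.province} {self.year}: resource {ind!r} must be >= 0"
                )

    @property
    def gdp_per_capita(self) -> float:
        """Per-capita GDP, always derived on demand to avoid unit drift."""
        return self.gdp / self.population


@dataclass(frozen=True)
class NationalSeries:
    """A national annual total for one indicator over consecutive years."""

    indicator: str
    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValidationError("years and values must have equal length")
        if len(self.years) < 4:
            raise ValidationError("national series needs at least 4 years")
        if any(b - a != 1 for a, b in zip(self.years, self.years[1:])):
            raise ValidationError("years must be consecutive and ascending")
        if any(v <= 0 for v in self.values):
            raise ValidationError("series values must be strictly positive")


def _records_to_frame(records: Iterable[ProvinceYearRecord]) -> pd.DataFrame:
    rows = [
        {
            "province": r.province,
            "region": r.region,
            "year": r.year,
            "population": r.population,
            "area_km2": r.area_km2,
            "gdp": r.gdp,
            **{ind: r.resources[ind] for ind in INDICATORS},
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(PANEL_COLUMNS))


def to_frame(records: Iterable[ProvinceYearRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a panel, one row per province-year."""
    return _records_to_frame(records)


def load_panel(
    path: str | Path,
    partition: RegionPartition | None = None,
) -> list[ProvinceYearRecord]:
    """Read and validate a province-year panel from a delimited file.

    The file is comma-separated UTF-8 with header
    ``province,region,year,population,area_km2,gdp,institutions,beds,
    practitioners,pharmacists`` (the ``region`` column is optional but, if
    present, must agree with the partition).  Lines starting with ``#`` are
    treated as comments.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If a row violates positivity or uniqueness invariants.
    PartitionError
        If a province is unknown to the partition, or the stated region
        disagrees with it.
    """
    partition = partition or DEFAULT_PARTITION
    df = pd.read_csv(path, comment="#")
    required = set(PANEL_COLUMNS) - {"region"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"panel file missing columns: {sorted(missing)}")

    records: list[ProvinceYearRecord] = []
    seen: set[tuple[str, int]] = set()
    for _, row in df.iterrows():
        province = str(row["province"]).strip()
        year = int(row["year"])
        if (province, year) in seen:
            raise ValidationError(f"duplicate record for {province} {year}")
        seen.add((province, year))
        region = partition.region_of(province)
        if "region" in df.columns and not pd.isna(row["region"]):
            stated = str(row["region"]).strip()
            if stated != region:
                raise PartitionError(
                    f"{province} {year}: stated region {stated!r} disagrees "
                    f"with partition ({region!r})"
                )
        records.append(
            ProvinceYearRecord(
                province=province,
                region=region,
                year=year,
                population=float(row["population"]),
                area_km2=float(row["area_km2"]),
                gdp=float(row["gdp"]),
                resources={ind: float(row[ind]) for ind in INDICATORS},
            )
        )
    return records


def write_panel(
    records: Sequence[ProvinceYearRecord],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a panel in the standard delimited format (round-trips load_panel)."""
    df = _records_to_frame(records)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def panel_years(records: Iterable[ProvinceYearRecord]) -> tuple[int, ...]:
    return tuple(sorted({r.year for r in records}))


def records_for_year(
    records: Iterable[ProvinceYearRecord], year: int
) -> list[ProvinceYearRecord]:
    out = [r for r in records if r.year == year]
    if not out:
        raise AggregationError(f"year {year} absent from panel")
    return out


def national_series(
    records: Sequence[ProvinceYearRecord], indicator: str
) -> NationalSeries:
    """Per-year national sum of one indicator, years ascending.

    Requires every year to cover the same province set, so that the series
    is a consistent national aggregate.
    """
    if indicator not in INDICATORS:
        raise KeyError(f"unknown indicator {indicator!r}")
    by_year: dict[int, set[str]] = {}
    totals: dict[int, float] = {}
    for r in records:
        by_year.setdefault(r.year, set()).add(r.province)
        totals[r.year] = totals.get(r.year, 0.0) + r.resources[indicator]
    province_sets = {frozenset(v) for v in by_year.values()}
    if len(province_sets) > 1:
        reference = max(by_year.values(), key=len)
        ragged = [y for y, s in by_year.items() if s != reference]
        raise AggregationError(
            f"province sets differ across years; offending years: {sorted(ragged)}"
        )
    years = tuple(sorted(totals))
    return NationalSeries(
        indicator=indicator,
        years=years,
        values=tuple(totals[y] for y in years),
    )


@dataclass(frozen=True)
class RegionTotals:
    resource: float
    population: float
    area_km2: float
    gdp: float


def region_aggregate(
    records: Sequence[ProvinceYearRecord],
    indicator: str,
    year: int,
) -> dict[str, RegionTotals]:
    """Totals of one indicator plus covariates per region for one year."""
    if indicator not in INDICATORS:
        raise KeyError(f"unknown indicator {indicator!r}")
    year_records = records_for_year(records, year)
    acc: dict[str, dict[str, float]] = {}
    for r in year_records:
        slot = acc.setdefault(
            r.region, {"resource": 0.0, "population": 0.0, "area_km2": 0.0, "gdp": 0.0}
        )
        slot["resource"] += r.resources[indicator]
        slot["population"] += r.population
        slot["area_km2"] += r.area_km2
        slot["gdp"] += r.gdp
    return {region: RegionTotals(**vals) for region, vals in acc.items()}


def table1_series(indicator: str) -> NationalSeries:
    """The packaged 2016-2020 national series for one indicator.

    These are the published national annual totals of the four TCM resource
    indicators, shipped as a small fixture so the forecasting stage runs
    without any external data.
    """
    if indicator not in INDICATORS:
        raise KeyError(f"unknown indicator {indicator!r}")
    with resources.files("tcm_equity.data").joinpath(
        "national_series_2016_2020.csv"
    ).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, comment="#")
    return NationalSeries(
        indicator=indicator,
        years=tuple(int(y) for y in df["year"]),
        values=tuple(float(v) for v in df[indicator]),
    )
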