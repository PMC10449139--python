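"""End-to-end report: equity tables and grey forecasts from one input.

Given a province-year panel (or only the packaged national series), this
writes one delimited file per analysis stage — concentration index, Theil
decomposition under both weight bases, agglomeration degrees, GM(1,1)
summaries and forecasts — plus a machine-readable run manifest.  Outputs are
deterministic: identical input and configuration produce byte-identical
files.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agglomeration import agglomeration_frame, agglomeration_table
from .concentration import concentration_table
from .exceptions import ConfigError
from .grey import accuracy_test, fit_gm11, forecast_table
from .panel import (
    INDICATORS,
    ProvinceYearRecord,
    RegionPartition,
    load_panel,
    national_series,
    panel_years,
    table1_series,
)
from .theil import theil_table

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Options of one report run."""

    input_path: str | None = None  # None -> packaged national series only
    output_dir: str = "report"
    weight_bases: tuple[str, ...] = ("population", "geography")
    log_base: float | None = None  # None = natural log
    horizon_year: int = 2025
    ci_unit: str = "province"
    partition_path: str | None = None


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def _rounded(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    return df.round(decimals)


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest: dict[str, object] = {
        "version": __version__,
        "input": config.input_path,
        "horizon_year": config.horizon_year,
        "weight_bases": list(config.weight_bases),
        "log_base": config.log_base,
        "ci_unit": config.ci_unit,
    }

    partition = (
        RegionPartition.from_file(config.partition_path)
        if config.partition_path
        else None
    )

    records: list[ProvinceYearRecord] | None = None
    if config.input_path is not None:
        records = load_panel(config.input_path, partition)

    if records is not None:
        ci = concentration_table(records, partition, unit=config.ci_unit)
        path = out / "concentration_index.csv"
        _write(ci, path, index=True)
        _write(_rounded(ci, 4), out / "concentration_index_printed.csv", index=True)
        written["concentration_index"] = path

        for basis in config.weight_bases:
            th = theil_table(records, basis, partition, config.log_base)
            path = out / f"theil_{basis}.csv"
            _write(th, path)
            printed = th.copy()
            printed[["total", "within", "between"]] = printed[
                ["total", "within", "between"]
            ].round(4)
            printed[["within_pct", "between_pct"]] = printed[
                ["within_pct", "between_pct"]
            ].round(2)
            _write(printed, out / f"theil_{basis}_printed.csv")
            written[f"theil_{basis}"] = path

        frames = [
            agglomeration_frame(agglomeration_table(records, y, partition))
            for y in panel_years(records)
        ]
        agg = pd.concat(frames, ignore_index=True)
        path = out / "agglomeration.csv"
        _write(agg, path)
        num = agg.select_dtypes("number").columns
        printed = agg.copy()
        printed[num] = printed[num].round(2)
        _write(printed, out / "agglomeration_printed.csv")
        written["agglomeration"] = path

    grey_rows = []
    fc_frames = []
    for ind in INDICATORS:
        series = (
            national_series(records, ind) if records is not None
            else table1_series(ind)
        )
        if config.horizon_year <= series.years[-1]:
            raise ConfigError("horizon year must be after the last observed year")
        model = fit_gm11(series)
        report = accuracy_test(model)
        grey_rows.append(
            {
                "indicator": ind,
                "a": model.a,
                "u": model.u,
                "time_response": model.response_string(),
                "C": report.C,
                "P": report.P,
                "level": report.level,
            }
        )
        fc = forecast_table(model, config.horizon_year)
        fc.insert(0, "indicator", ind)
        fc_frames.append(fc)

    grey = pd.DataFrame(grey_rows)
    path = out / "grey_models.csv"
    _write(grey, path)
    printed = grey.copy()
    printed[["a", "u", "C", "P"]] = printed[["a", "u", "C", "P"]].round(3)
    _write(printed, out / "grey_models_printed.csv")
    written["grey_models"] = path

    fc_all = pd.concat(fc_frames, ignore_index=True)
    path = out / "grey_forecasts.csv"
    _write(fc_all, path)
    printed = fc_all.copy()
    printed[["value", "relative_error_pct"]] = printed[
        ["value", "relative_error_pct"]
    ].round(3)
    _write(printed, out / "grey_forecasts_printed.csv")
    written["grey_forecasts"] = path

    manifest["outputs"] = {k: p.name for k, p in written.items()}
    manifest["python"] = "%d.%d" % sys.version_info[:2]
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path
    return written
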