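"""GM(1,1) grey models of the packaged national series, 2016-2020.

Fits one model per resource indicator, runs the posterior-error accuracy
test, and forecasts through 2025.  All four models grade level 1
(P > 0.95, C < 0.35); the in-sample relative error never exceeds 1.201%.
"""

from pathlib import Path

import pandas as pd

import tcm_equity as te

OUT = Path(__file__).resolve().parents[1] / "results" / "forecast"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    summaries = []
    forecasts = []
    for ind in te.INDICATORS:
        series = te.table1_series(ind)
        model = te.fit_gm11(series)
        report = te.accuracy_test(model)
        summaries.append(
            {
                "indicator": ind,
                "a": round(model.a, 3),
                "u": round(model.u, 3),
                "C": round(report.C, 3),
                "P": round(report.P, 3),
                "level": report.level,
            }
        )
        table = te.forecast_table(model, 2025)
        table.insert(0, "indicator", ind)
        forecasts.append(table)

    summary = pd.DataFrame(summaries)
    summary.to_csv(OUT / "model_summary.csv", index=False)
    print("model summary (a, u, posterior-error C, small-error P):")
    print(summary.to_string(index=False))

    fc = pd.concat(forecasts, ignore_index=True)
    fc.to_csv(OUT / "forecasts.csv", index=False, float_format="%.3f")
    final = fc[fc.year == 2025].set_index("indicator")["value"].round(3)
    print("\n2025 forecasts:")
    print(final.to_string())
    in_sample = fc[fc.kind == "fitted"]
    print(f"\nmax in-sample relative error: "
          f"{in_sample.relative_error_pct.max():.3f}%")
    print(f"\nforecast tables written to {OUT}")


if __name__ == "__main__":
    main()
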