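"""Generate the synthetic province-year panels used by the later stages.

Writes three panels under results/panels/:

  proportional.csv   gamma = 0, no noise  — allocation exactly proportional
                     to population, the equitable benchmark
  wealth_skewed.csv  gamma = 1, no noise  — resources concentrate in richer
                     provinces
  realistic.csv      gamma = 0.5, noise 0.3 — a plausibly messy panel

All three share the default structure: 31 provinces in 4 regions, 5 years,
8% annual national growth, Eastern > Central > Northeast > Western
per-capita GDP gradient.
"""

from pathlib import Path

import tcm_equity as te

OUT = Path(__file__).resolve().parents[1] / "results" / "panels"
OUT.mkdir(parents=True, exist_ok=True)

CONFIGS = {
    "proportional": te.SyntheticConfig(seed=11, gamma=0.0, noise=0.0),
    "wealth_skewed": te.SyntheticConfig(seed=11, gamma=1.0, noise=0.0),
    "realistic": te.SyntheticConfig(seed=7, gamma=0.5, noise=0.3),
}


def main() -> None:
    for name, config in CONFIGS.items():
        records = te.generate_panel(config)
        path = OUT / f"{name}.csv"
        te.write_panel(
            records, path,
            header_comments=[f"synthetic panel '{name}': {config}"],
        )
        series = te.national_series(records, "institutions")
        print(
            f"{name}: {len(records)} records; national institutions "
            f"{series.values[0]:.0f} -> {series.values[-1]:.0f} "
            f"({series.years[0]}-{series.years[-1]})"
        )
    print(f"panels written to {OUT}")


if __name__ == "__main__":
    main()
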