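"""Nonfatal and fatal attributable DALYs and their monetary value.

Multiplies the PAF table into the baseline-DALY table (the bundled
reverse-engineered validation fixture), applies the mental-disorders
envelope rule at aggregation, adds the fatal years-of-life-lost from
the homicide age bands, and values everything at per-capita GDP.
"""

from pathlib import Path

from vacburden import datasets, pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = pipeline.RunConfig.from_yaml(datasets.reproduction_config_path())
    report = pipeline.run_pipeline(config)

    RESULTS.mkdir(exist_ok=True)
    report["burden_cells"].to_csv(RESULTS / "05_burden_cells.csv", index=False)
    report["burden_totals"].to_csv(RESULTS / "05_burden_totals.csv", index=False)

    print(report["burden_totals"].to_string(index=False))
    print(f"\nNonfatal: {report['nonfatal_dalys']:,.0f} DALYs "
          f"= ZAR {report['nonfatal_value'] / 1e9:.1f} bn")
    print(f"Fatal:    {report['fatal_dalys']:,.0f} DALYs "
          f"= ZAR {report['fatal_value'] / 1e9:.1f} bn")
    print(f"Total economic value: ZAR {report['total_value'] / 1e9:.1f} bn "
          f"({100 * report['shares_of_gdp']['total']:.1f}% of GDP)")


if __name__ == "__main__":
    main()
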