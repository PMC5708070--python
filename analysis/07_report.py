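"""Full pipeline run: burden, earnings, welfare, and the combined report.

Everything from the bundled run configuration in one pass, with all
machine-readable outputs and the text report under results/07_report/.
"""

from pathlib import Path

from vacburden import datasets, pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results" / "07_report"


def main() -> None:
    config = pipeline.RunConfig.from_yaml(datasets.reproduction_config_path())
    report = pipeline.run_pipeline(config)
    pipeline.write_outputs(report, RESULTS)
    print(pipeline.format_report(report))
    print(f"\nOutputs written under {RESULTS}")


if __name__ == "__main__":
    main()
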