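"""Pool the published study-level relative risks.

The bundled effects table already carries one pooled RR per exposure ×
outcome × sex cell (singletons under sample-size weighting pass
through unchanged), so this step mainly demonstrates the pooling
surface and writes the harmonised RR table consumed by step 04.
"""

from pathlib import Path

from vacburden import datasets
from vacburden.effect_pooling import StudyEffect, pool_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    raw = datasets.load_study_rr()
    effects = [
        StudyEffect(
            study_id=r.study_id, exposure=r.exposure, outcome=r.outcome,
            sex=r.sex, measure="RR", value=float(r.rr), n=float(r.n),
        )
        for r in raw.itertuples(index=False)
    ]
    pooled = pool_table(effects, scale="log")
    RESULTS.mkdir(exist_ok=True)
    pooled.to_csv(RESULTS / "03_pooled_rr.csv", index=False)
    print(pooled.to_string(index=False))
    print(f"\n{len(pooled)} pooled cells "
          f"({(pooled['exposure'] == 'witnessing').sum()} witnessing rows kept "
          "here but excluded from burden totals downstream).")


if __name__ == "__main__":
    main()
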