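"""Annual productivity losses from childhood physical and emotional violence.

Runs the unrounded earnings chain: CPI-adjusted median monthly earnings
× proportional reduction × victims in the labour force × 12.
"""

from pathlib import Path

import pandas as pd

from vacburden import datasets
from vacburden.earnings_loss import productivity_loss, round_half_up

RESULTS = Path(__file__).resolve().parents[1] / "results"

REDUCTIONS = {"physical": 0.117, "emotional": 0.092}


def main() -> None:
    econ = datasets.load_econ_params()
    prevalence = datasets.load_prevalence().set_index(["exposure", "sex"])

    rows = []
    for exposure, reduction in REDUCTIONS.items():
        pl = productivity_loss(
            exposure, float(prevalence.loc[(exposure, "total"), "p"]),
            reduction, econ,
        )
        rows.append({
            "exposure": exposure,
            "victims_in_labour_force": round_half_up(pl.victims_in_labour_force),
            "per_victim_monthly_zar": round_half_up(pl.per_victim_monthly_loss),
            "monthly_loss_zar": round(pl.monthly_loss),
            "annual_loss_bn_zar": round(pl.annual_loss / 1e9, 1),
            "share_of_gdp_pct": round(100 * pl.share_of_gdp, 2),
        })
    out = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "06_earnings_losses.csv", index=False)
    print(out.to_string(index=False))
    print("\nDisplayed victim counts and per-victim losses are rounded; the "
          "totals come from the unrounded chain.")


if __name__ == "__main__":
    main()
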