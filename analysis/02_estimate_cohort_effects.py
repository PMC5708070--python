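"""Recover the generating parameters from the synthetic cohort.

Fits the log-binomial RR models and the Heckman-corrected wage equation
on the cohort from step 01 and tabulates estimates against truth.  This
is the validation of the estimation stage: adjusted RRs recover the
generating log-risk coefficients, and the two-stage wage model recovers
the 11.7% / 9.2% proportional reductions despite selection (rho = 0.5).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vacburden import datasets
from vacburden.cohort_effects import estimate_rr, estimate_wage_effect
from vacburden.synthetic_cohort import generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"

ADJUST = ["female", "childhood_poverty", "mother_edu"]
SELECTION = ["female", "childhood_poverty", "mother_edu", "partner_employed"]


def main() -> None:
    spec = datasets.load_cohort_spec()
    cohort = generate_cohort(spec)
    exposures = list(spec.exposure_prevalences)

    rows = []
    for outcome, om in spec.outcomes.items():
        for exposure in exposures:
            others = [e for e in exposures if e != exposure]
            est = estimate_rr(cohort, exposure, outcome, ADJUST + others)
            truth = float(np.exp(om.exposure_log_rr.get(exposure, 0.0)))
            rows.append({
                "exposure": exposure, "outcome": outcome, "kind": "rr",
                "truth": truth, "estimate": est.rr, "se": est.log_rr_se,
                "z_vs_truth": (np.log(est.rr) - np.log(truth)) / est.log_rr_se,
                "method": est.method, "n": est.n,
            })
    for exposure in exposures:
        others = [e for e in exposures if e != exposure]
        we = estimate_wage_effect(
            cohort, exposure, adjust_for=ADJUST + others,
            selection_covariates=SELECTION, n_boot=200, seed=spec.seed,
        )
        truth = spec.wage_model.reductions[exposure]
        rows.append({
            "exposure": exposure, "outcome": "monthly_wage",
            "kind": "wage_reduction", "truth": truth,
            "estimate": we.proportional_reduction, "se": we.se,
            "z_vs_truth": (we.proportional_reduction - truth) / we.se,
            "method": f"heckman (rho_hat={we.rho_hat:.3f})", "n": we.n_selected,
        })

    out = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "02_cohort_effects.csv", index=False)
    print(out.to_string(index=False))
    worst = out["z_vs_truth"].abs().max()
    print(f"\nLargest |z| against truth: {worst:.2f} "
          "(every generating parameter recovered within 3 SE)"
          if worst < 3 else
          f"\nWARNING: largest |z| = {worst:.2f} exceeds 3")


if __name__ == "__main__":
    main()
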