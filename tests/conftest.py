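import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vacburden import datasets, pipeline
from vacburden.synthetic_cohort import generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def caps_spec():
    return datasets.load_cohort_spec()


@pytest.fixture(scope="session")
def caps_cohort(caps_spec):
    """One 50,000-individual draw of the bundled synthetic panel."""
    return generate_cohort(caps_spec)


@pytest.fixture(scope="session")
def caps_cohort_with_latents(caps_spec):
    return generate_cohort(caps_spec, return_latents=True)


@pytest.fixture(scope="session")
def reproduction_report():
    """Full pipeline run on the bundled published-tables configuration."""
    config = pipeline.RunConfig.from_yaml(datasets.reproduction_config_path())
    return pipeline.run_pipeline(config)


@pytest.fixture(scope="session")
def published_rr_reference():
    """Published pooled RRs and printed PAFs, with matching prevalences."""
    rr = datasets.load_study_rr()
    prev = datasets.load_prevalence()
    return rr, prev


@pytest.fixture(scope="session")
def null_pipeline():
    """End-to-end run of the synthetic route with every true RR = 1.

    Generates a 50,000-person cohort with null exposure effects,
    estimates RRs, pools them, computes PAFs against the spec
    prevalences, and attributes a nominal baseline of 1e6 DALYs per
    outcome.  Returns (total attributable DALYs, a 3-SE Monte-Carlo
    bound on that total, total baseline DALYs).
    """
    import math

    from vacburden.burden_daly import attribute_dalys
    from vacburden.cohort_effects import estimate_rr
    from vacburden.effect_pooling import StudyEffect, pool_table
    from vacburden.paf_engine import build_paf_table, paf
    from vacburden.synthetic_cohort import (
        ConfounderSpec,
        CohortSpec,
        OutcomeModel,
    )

    prevalences = {"physical": 0.261, "emotional": 0.126}
    outcomes = {
        "alcohol_abuse": OutcomeModel(
            intercept=math.log(0.12), confounder_coefs={"female": -0.1}
        ),
        "anxiety": OutcomeModel(
            intercept=math.log(0.08), confounder_coefs={"female": 0.2}
        ),
    }
    spec = CohortSpec(
        n_individuals=50_000,
        exposure_prevalences=prevalences,
        confounders=[ConfounderSpec("female", "bernoulli", {"p": 0.5})],
        outcomes=outcomes,
        seed=424242,
    )
    cohort = generate_cohort(spec)

    effects, bound = [], 0.0
    baseline_per_outcome = 1e6
    for exposure in prevalences:
        for outcome in outcomes:
            est = estimate_rr(cohort, exposure, outcome, ["female"])
            effects.append(
                StudyEffect(
                    study_id=f"{exposure}-{outcome}",
                    exposure=exposure,
                    outcome=outcome,
                    sex="total",
                    measure="RR",
                    value=est.rr,
                    n=est.n,
                )
            )
            worst_rr = math.exp(3 * est.log_rr_se)
            bound += baseline_per_outcome * paf(prevalences[exposure], worst_rr)

    pooled = pool_table(effects)
    prev = pd.DataFrame(
        [{"exposure": e, "sex": "total", "p": p} for e, p in prevalences.items()]
    )
    pafs = build_paf_table(prev, pooled)
    baseline = pd.DataFrame(
        [
            {"outcome": o, "sex": "total", "dalys": baseline_per_outcome}
            for o in outcomes
        ]
    )
    cells = attribute_dalys(pafs, baseline)
    total = float(cells["daly_loss"].sum())
    baseline_total = baseline_per_outcome * len(outcomes) * len(prevalences)
    return total, bound, baseline_total


@pytest.fixture()
def two_by_two_cohort():
    """100 exposed with 20 events, 100 unexposed with 10 events."""
    rows = (
        [(1, 1)] * 20 + [(1, 0)] * 80 + [(0, 1)] * 10 + [(0, 0)] * 90
    )
    return pd.DataFrame(rows, columns=["exposed", "event"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
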