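"""Generator invariants: determinism, marginal moments, selection structure."""

import math

import numpy as np
import pandas as pd
import pytest

from vacburden.synthetic_cohort import (
    CohortSpec,
    ConfounderSpec,
    OutcomeModel,
    SelectionModel,
    SpecValidationError,
    WageModel,
    empirical_summary,
    generate_cohort,
)


def small_spec(**overrides):
    base = dict(
        n_individuals=2000,
        exposure_prevalences={"physical": 0.3},
        outcomes={
            "harm": OutcomeModel(
                intercept=math.log(0.1), exposure_log_rr={"physical": math.log(2.0)}
            )
        },
        wage_model=WageModel(intercept=8.0, reductions={"physical": 0.1}, sigma=0.4),
        selection_model=SelectionModel(intercept=0.2, rho=0.3),
        seed=7,
    )
    base.update(overrides)
    return CohortSpec(**base)


class TestValidation:
    def test_bad_prevalence_names_parameter(self):
        with pytest.raises(SpecValidationError, match="physical"):
            small_spec(exposure_prevalences={"physical": 1.3}).validate()

    def test_rho_on_boundary_rejected(self):
        spec = small_spec(
            selection_model=SelectionModel(intercept=0.0, rho=1.0)
        )
        with pytest.raises(SpecValidationError, match="rho"):
            spec.validate()

    def test_implied_risk_above_one_rejected_naming_outcome(self):
        spec = small_spec(
            outcomes={
                "harm": OutcomeModel(
                    intercept=math.log(0.8),
                    exposure_log_rr={"physical": math.log(2.0)},
                )
            }
        )
        with pytest.raises(SpecValidationError, match="harm"):
            generate_cohort(spec)

    def test_reduction_outside_unit_interval_rejected(self):
        spec = small_spec(
            wage_model=WageModel(intercept=8.0, reductions={"physical": 1.2})
        )
        with pytest.raises(SpecValidationError, match="reductions"):
            spec.validate()


class TestGeneration:
    def test_zero_prevalence_gives_all_zero_exposures(self):
        spec = small_spec(exposure_prevalences={"physical": 0.0})
        cohort = generate_cohort(spec)
        assert (cohort["physical"] == 0).all()

    def test_seeded_determinism(self):
        a = generate_cohort(small_spec())
        b = generate_cohort(small_spec())
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_cohort(small_spec(seed=1))
        b = generate_cohort(small_spec(seed=2))
        assert not a["physical"].equals(b["physical"])

    def test_wage_present_iff_participating(self, caps_cohort):
        working = caps_cohort["participates"] == 1
        assert caps_cohort.loc[working, "monthly_wage"].notna().all()
        assert caps_cohort.loc[~working, "monthly_wage"].isna().all()

    def test_empirical_prevalence_within_4se(self, caps_cohort, caps_spec):
        n = caps_spec.n_individuals
        for exposure, p in caps_spec.exposure_prevalences.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(caps_cohort[exposure].mean() - p) < 4 * se

    def test_participation_rate_plausible(self, caps_cohort):
        # probit with mean linear predictor ~0.2 over unit-variance noise
        assert 0.4 < caps_cohort["participates"].mean() < 0.75

    def test_selection_latent_correlation_matches_rho(
        self, caps_cohort_with_latents, caps_spec
    ):
        _, latents = caps_cohort_with_latents
        r = np.corrcoef(latents["u"], latents["v"])[0, 1]
        mc_se = 1.0 / math.sqrt(caps_spec.n_individuals)
        assert abs(r - caps_spec.selection_model.rho) < 4 * mc_se

    def test_categorical_confounder_levels(self):
        spec = small_spec(
            confounders=[
                ConfounderSpec(
                    "race",
                    "categorical",
                    {"levels": ["a", "b", "c"], "probs": [0.5, 0.3, 0.2]},
                )
            ]
        )
        cohort = generate_cohort(spec)
        assert set(cohort["race"]) <= {"a", "b", "c"}


class TestEmpiricalSummary:
    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_summary(
                pd.DataFrame(columns=["e", "o"]), exposures=["e"], outcomes=["o"]
            )

    def test_handmade_equal_risks_give_rr_one(self):
        cohort = pd.DataFrame(
            {"e": [1, 1, 0, 0], "o": [1, 0, 1, 0]}
        )
        summ = empirical_summary(cohort, exposures=["e"], outcomes=["o"])
        assert summ["crude_rr"][("e", "o")] == 1.0

    def test_undefined_stratum_absent_not_zero(self):
        cohort = pd.DataFrame({"e": [1, 1, 1], "o": [1, 0, 1]})
        summ = empirical_summary(cohort, exposures=["e"], outcomes=["o"])
        assert ("e", "o") not in summ["crude_rr"]
        assert 0 not in summ["risk_by_stratum"][("e", "o")]

    def test_null_effect_crude_rr_near_one(self):
        spec = small_spec(
            n_individuals=50_000,
            outcomes={
                "harm": OutcomeModel(intercept=math.log(0.2), exposure_log_rr={})
            },
            seed=11,
        )
        cohort = generate_cohort(spec)
        summ = empirical_summary(cohort, exposures=["physical"], outcomes=["harm"])
        rr = summ["crude_rr"][("physical", "harm")]
        # log-RR sampling SE for risks ~0.2 in strata of ~15k/35k
        se = math.sqrt((1 - 0.2) / (0.2 * 15_000) + (1 - 0.2) / (0.2 * 35_000))
        assert abs(math.log(rr)) < 4 * se

    def test_known_rr_recovered_without_confounding(self):
        true_rr = 1.55
        spec = small_spec(
            n_individuals=50_000,
            exposure_prevalences={"physical": 0.261},
            outcomes={
                "alcohol": OutcomeModel(
                    intercept=math.log(0.12),
                    exposure_log_rr={"physical": math.log(true_rr)},
                )
            },
            seed=3,
        )
        cohort = generate_cohort(spec)
        summ = empirical_summary(cohort, exposures=["physical"], outcomes=["alcohol"])
        rr = summ["crude_rr"][("physical", "alcohol")]
        n1 = int(cohort["physical"].sum())
        n0 = len(cohort) - n1
        se = math.sqrt(
            (1 - 0.12 * true_rr) / (0.12 * true_rr * n1) + (1 - 0.12) / (0.12 * n0)
        )
        assert abs(math.log(rr) - math.log(true_rr)) < 3 * se
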