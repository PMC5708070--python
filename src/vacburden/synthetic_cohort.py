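"""Synthetic cross-sectional cohort with known effect sizes.

Emulates a youth-panel survey of the Cape Area Panel Study kind: binary
childhood violence exposures, socio-demographic confounders, binary
adult outcomes generated under a *log-risk* model (so the generating
coefficients are log relative risks, the scale the downstream PAF
machinery consumes), and monthly wages generated jointly with a probit
labour-force-participation equation whose latent error is correlated
with the wage error.  Because every parameter is known, the estimators
in :mod:`vacburden.cohort_effects` can be validated by parameter
recovery.

Deliberate simplifications relative to real survey data: exposures are
drawn independently across violence types (no poly-victimisation), a
single cross-section replaces the panel's waves, and there is no
clustering or stratification.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfounderSpec",
    "OutcomeModel",
    "WageModel",
    "SelectionModel",
    "CohortSpec",
    "generate_cohort",
    "empirical_summary",
]


class SpecValidationError(ValueError):
    """A cohort specification violates an invariant; names the parameter."""


@dataclass(frozen=True)
class ConfounderSpec:
    """One confounder column.

    family:
        ``"bernoulli"`` with ``params={"p": ...}``;
        ``"categorical"`` with ``params={"levels": [...], "probs": [...]}``
        (levels are strings, the first is the reference level);
        ``"standard-normal"`` with no params.
    """

    name: str
    family: str
    params: Mapping = field(default_factory=dict)

    def validate(self) -> None:
        if self.family == "bernoulli":
            p = self.params.get("p")
            if p is None or not 0.0 <= p <= 1.0:
                raise SpecValidationError(
                    f"confounder {self.name!r}: bernoulli p must be in [0,1], got {p!r}"
                )
        elif self.family == "categorical":
            levels = self.params.get("levels")
            probs = self.params.get("probs")
            if not levels or probs is None or len(levels) != len(probs):
                raise SpecValidationError(
                    f"confounder {self.name!r}: categorical needs matching levels/probs"
                )
            if any(q < 0 for q in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"confounder {self.name!r}: categorical probs must be a distribution"
                )
        elif self.family != "standard-normal":
            raise SpecValidationError(
                f"confounder {self.name!r}: unknown family {self.family!r}"
            )


@dataclass(frozen=True)
class OutcomeModel:
    """Log-risk model for one binary outcome.

    risk = exp(intercept + sum(log_rr * exposure) + sum(coef * confounder));
    the exposure coefficients are therefore log relative risks.
    Categorical confounder coefficients are keyed ``"name=level"``.
    """

    intercept: float
    exposure_log_rr: Mapping[str, float] = field(default_factory=dict)
    confounder_coefs: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class WageModel:
    """Log-normal monthly wage with multiplicative exposure penalties.

    log(wage) = intercept + sum(log(1 - reduction) * exposure)
                + sum(coef * confounder) + v,   v ~ N(0, sigma^2).
    ``reductions`` maps exposure -> proportional earnings reduction in [0, 1).
    """

    intercept: float
    reductions: Mapping[str, float] = field(default_factory=dict)
    confounder_coefs: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 0.5


@dataclass(frozen=True)
class SelectionModel:
    """Probit participation equation with error correlated with the wage error.

    P(participate) = Phi(intercept + sum(coef * covariate) + u), with
    corr(u, v) = rho; u is standard normal.  Covariates may be
    confounders or exposures; a covariate used here but not in the wage
    equation acts as the exclusion restriction.
    """

    intercept: float
    coefs: Mapping[str, float] = field(default_factory=dict)
    rho: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    n_individuals: int
    exposure_prevalences: Mapping[str, float] = field(default_factory=dict)
    confounders: Sequence[ConfounderSpec] = ()
    outcomes: Mapping[str, OutcomeModel] = field(default_factory=dict)
    wage_model: WageModel | None = None
    selection_model: SelectionModel | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise SpecValidationError("n_individuals must be positive")
        for exp, p in self.exposure_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(
                    f"exposure_prevalences[{exp!r}] = {p!r} outside [0,1]"
                )
        for c in self.confounders:
            c.validate()
        bounds = self._covariate_bounds()
        for name, om in self.outcomes.items():
            worst = om.intercept
            for exp, b in om.exposure_log_rr.items():
                if exp not in self.exposure_prevalences:
                    raise SpecValidationError(
                        f"outcome {name!r} references unknown exposure {exp!r}"
                    )
                worst += max(0.0, b)
            for key, b in om.confounder_coefs.items():
                lo, hi = bounds.get(key.split("=")[0], (None, None))
                if lo is None:
                    # unbounded (standard-normal): checked on realised draws
                    continue
                worst += max(b * lo, b * hi)
            if worst > 1e-12:
                raise SpecValidationError(
                    f"outcome {name!r}: worst-case log-risk {worst:.4f} > 0 "
                    f"(implied risk exceeds 1); lower the intercept or coefficients"
                )
        if self.selection_model is not None:
            rho = self.selection_model.rho
            if not -1.0 < rho < 1.0:
                raise SpecValidationError(
                    f"selection_model.rho = {rho!r} not strictly inside (-1, 1)"
                )
        if self.wage_model is not None:
            for exp, r in self.wage_model.reductions.items():
                if not 0.0 <= r < 1.0:
                    raise SpecValidationError(
                        f"wage_model.reductions[{exp!r}] = {r!r} outside [0, 1)"
                    )
            if self.wage_model.sigma < 0:
                raise SpecValidationError("wage_model.sigma must be non-negative")

    def _covariate_bounds(self) -> dict[str, tuple[float, float] | tuple[None, None]]:
        bounds: dict = {e: (0.0, 1.0) for e in self.exposure_prevalences}
        for c in self.confounders:
            if c.family in ("bernoulli", "categorical"):
                bounds[c.name] = (0.0, 1.0)
            else:
                bounds[c.name] = (None, None)
        return bounds

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        confs = [
            ConfounderSpec(c["name"], c["family"], c.get("params", {}))
            for c in d.get("confounders", [])
        ]
        outcomes = {
            name: OutcomeModel(
                intercept=om["intercept"],
                exposure_log_rr=om.get("exposure_log_rr", {}),
                confounder_coefs=om.get("confounder_coefs", {}),
            )
            for name, om in d.get("outcomes", {}).items()
        }
        wage = d.get("wage_model")
        if wage is not None:
            wage = WageModel(
                intercept=wage["intercept"],
                reductions=wage.get("reductions", {}),
                confounder_coefs=wage.get("confounder_coefs", {}),
                sigma=wage.get("sigma", 0.5),
            )
        sel = d.get("selection_model")
        if sel is not None:
            sel = SelectionModel(
                intercept=sel["intercept"],
                coefs=sel.get("coefs", {}),
                rho=sel.get("rho", 0.0),
            )
        return cls(
            n_individuals=d["n_individuals"],
            exposure_prevalences=d.get("exposure_prevalences", {}),
            confounders=confs,
            outcomes=outcomes,
            wage_model=wage,
            selection_model=sel,
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


def _design_value(row_values: Mapping[str, np.ndarray], key: str) -> np.ndarray:
    """Resolve a coefficient key against generated columns.

    Plain names index numeric columns; ``"name=level"`` indexes a
    categorical dummy.
    """
    if key in row_values:
        col = row_values[key]
        if col.dtype == object:
            raise SpecValidationError(
                f"coefficient on categorical {key!r} must name a level (\"{key}=level\")"
            )
        return col.astype(float)
    if "=" in key:
        name, level = key.split("=", 1)
        if name in row_values:
            return (row_values[name] == level).astype(float)
    raise SpecValidationError(f"coefficient references unknown covariate {key!r}")


def generate_cohort(
    spec: CohortSpec, return_latents: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic cohort.

    Deterministic given ``spec.seed``.  Exposures are independent
    Bernoulli draws at their stated prevalences; each binary outcome is
    Bernoulli with risk ``exp(linear predictor)`` (generation fails if
    any individual's risk exceeds 1); the participation latent and the
    log-wage error are bivariate normal with correlation ``rho``, and
    the wage column is missing (NaN) for non-participants.

    With ``return_latents=True`` also returns the latent draws
    (participation error ``u``, wage error ``v``) for tests that
    instrument the selection structure directly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    cols: dict[str, np.ndarray] = {}

    for exp, p in spec.exposure_prevalences.items():
        cols[exp] = (rng.random(n) < p).astype(np.int8)

    for c in spec.confounders:
        if c.family == "bernoulli":
            cols[c.name] = (rng.random(n) < c.params["p"]).astype(np.int8)
        elif c.family == "categorical":
            cols[c.name] = rng.choice(
                np.asarray(c.params["levels"], dtype=object),
                size=n,
                p=c.params["probs"],
            )
        else:
            cols[c.name] = rng.standard_normal(n)

    for name, om in spec.outcomes.items():
        lp = np.full(n, om.intercept, dtype=float)
        for exp, b in om.exposure_log_rr.items():
            lp += b * cols[exp].astype(float)
        for key, b in om.confounder_coefs.items():
            lp += b * _design_value(cols, key)
        risk = np.exp(lp)
        if np.any(risk > 1.0 + 1e-12):
            raise SpecValidationError(
                f"outcome {name!r}: realised risk exceeds 1 "
                f"(max {risk.max():.4f}); the log-risk model is misspecified"
            )
        cols[name] = (rng.random(n) < risk).astype(np.int8)

    latents = None
    if spec.wage_model is not None:
        sel = spec.selection_model or SelectionModel(intercept=10.0)
        rho = sel.rho
        uv = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n
        )
        u = uv[:, 0]
        v = uv[:, 1] * spec.wage_model.sigma

        sel_lp = np.full(n, sel.intercept, dtype=float)
        for key, b in sel.coefs.items():
            sel_lp += b * _design_value(cols, key)
        participates = (sel_lp + u > 0).astype(np.int8)

        wm = spec.wage_model
        wage_lp = np.full(n, wm.intercept, dtype=float)
        for exp, r in wm.reductions.items():
            wage_lp += math.log1p(-r) * cols[exp].astype(float)
        for key, b in wm.confounder_coefs.items():
            wage_lp += b * _design_value(cols, key)
        wage = np.exp(wage_lp + v)
        wage[participates == 0] = np.nan

        cols["participates"] = participates
        cols["monthly_wage"] = wage
        latents = pd.DataFrame({"u": u, "v": v, "selection_lp": sel_lp})

    table = pd.DataFrame(cols)
    if return_latents:
        if latents is None:
            latents = pd.DataFrame(index=table.index)
        return table, latents
    return table


def empirical_summary(
    cohort: pd.DataFrame,
    exposures: Sequence[str] | None = None,
    outcomes: Sequence[str] | None = None,
) -> dict:
    """Empirical prevalences, stratified risks and crude risk ratios.

    Crude RR for (exposure, outcome) is risk(exposed)/risk(unexposed);
    strata with no individuals, or an unexposed risk of zero, are
    reported as absent rather than zero.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    binary = [
        c
        for c in cohort.columns
        if cohort[c].dropna().isin([0, 1]).all() and c != "participates"
    ]
    if exposures is None or outcomes is None:
        raise ValueError("exposures and outcomes column lists are required")
    for c in list(exposures) + list(outcomes):
        if c not in cohort.columns:
            raise KeyError(f"column {c!r} not in cohort")
        if c not in binary:
            raise ValueError(f"column {c!r} is not binary")

    out: dict = {
        "prevalence": {e: float(cohort[e].mean()) for e in exposures},
        "risk_by_stratum": {},
        "crude_rr": {},
    }
    if "participates" in cohort.columns:
        out["participation_rate"] = float(cohort["participates"].mean())
        out["mean_log_wage_by_stratum"] = {}
    for e in exposures:
        for o in outcomes:
            strata = {}
            for level in (0, 1):
                sub = cohort.loc[cohort[e] == level, o]
                if len(sub):
                    strata[level] = float(sub.mean())
            out["risk_by_stratum"][(e, o)] = strata
            if 0 in strata and 1 in strata and strata[0] > 0:
                out["crude_rr"][(e, o)] = strata[1] / strata[0]
        if "participates" in cohort.columns:
            logw = {}
            for level in (0, 1):
                w = cohort.loc[
                    (cohort[e] == level) & (cohort["participates"] == 1),
                    "monthly_wage",
                ]
                if len(w):
                    logw[level] = float(np.log(w).mean())
            out["mean_log_wage_by_stratum"][e] = logw
    return out
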