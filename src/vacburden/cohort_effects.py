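"""Relative risks and selection-corrected wage effects from a cohort table.

Two estimators over a cross-sectional cohort:

* :func:`estimate_rr` — a log-link binomial GLM (log-binomial model)
  whose exposure coefficient is a log relative risk, with a
  robust-variance log-link Poisson fallback when the log-binomial fit
  fails to converge (the standard modified-Poisson workaround).
* :func:`estimate_wage_effect` — the Heckman two-stage correction for
  non-random selection into employment: a probit participation
  equation, then a log-wage regression augmented with the inverse
  Mills ratio evaluated at the probit linear predictor.  The exposure
  effect is reported as a proportional earnings reduction
  ``1 - exp(beta)``; standard errors come from a nonparametric
  bootstrap over individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "RREstimate",
    "WageEffect",
    "estimate_rr",
    "estimate_wage_effect",
    "inverse_mills_ratio",
]


@dataclass(frozen=True)
class RREstimate:
    exposure: str
    outcome: str
    rr: float
    log_rr_se: float
    n: int
    method: str = "log-binomial"


@dataclass(frozen=True)
class WageEffect:
    exposure: str
    proportional_reduction: float
    se: float
    rho_hat: float
    mills_coef: float
    mills_se: float
    n_selected: int
    n: int


def _design(cohort: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design block; categorical columns expand to reference-coded dummies."""
    parts = []
    for c in columns:
        if c not in cohort.columns:
            raise KeyError(f"unknown column {c!r}")
        col = cohort[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, prefix_sep="=", dtype=float)
            parts.append(dummies.iloc[:, 1:])  # first level is the reference
        else:
            parts.append(col.astype(float))
    if not parts:
        return pd.DataFrame(index=cohort.index)
    return pd.concat(parts, axis=1)


def estimate_rr(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    adjust_for: Sequence[str] = (),
) -> RREstimate:
    """Relative risk of ``outcome`` for ``exposure``, adjusted for confounders.

    Fits a log-link binomial GLM; ``rr`` is the exponentiated exposure
    coefficient.  If that fit does not converge (log-binomial models
    often fail near the boundary), refits a log-link Poisson model with
    HC1 robust variance and flags the estimate's ``method``.

    Raises
    ------
    ValueError
        if either exposure stratum is empty or has zero outcome events
        (add a continuity correction or pool strata upstream).
    """
    for col in (exposure, outcome):
        if col not in cohort.columns:
            raise KeyError(f"unknown column {col!r}")
        vals = cohort[col].dropna().unique()
        if not set(vals) <= {0, 1}:
            raise ValueError(f"column {col!r} must be binary 0/1")
    counts = cohort.groupby(exposure)[outcome].agg(["sum", "count"])
    for level in (0, 1):
        if level not in counts.index or counts.loc[level, "count"] == 0:
            raise ValueError(f"exposure stratum {level} of {exposure!r} is empty")
        if counts.loc[level, "sum"] == 0:
            raise ValueError(
                f"zero {outcome!r} events among {exposure!r}={level}; the relative "
                "risk is not estimable — apply a continuity correction or collapse "
                "strata before fitting"
            )

    X = pd.concat(
        [cohort[exposure].astype(float), _design(cohort, adjust_for)], axis=1
    )
    X = sm.add_constant(X, prepend=True)
    y = cohort[outcome].astype(float)
    n = len(cohort)

    start = np.zeros(X.shape[1])
    start[0] = np.log(max(y.mean(), 1e-8))
    method = "log-binomial"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log())).fit(
                start_params=start, maxiter=200
            )
            if not fit.converged or not np.all(np.isfinite(fit.bse)):
                raise RuntimeError("log-binomial fit did not converge")
        except Exception:
            log.warning(
                "log-binomial fit failed for %s~%s; falling back to robust Poisson",
                outcome,
                exposure,
            )
            method = "robust-poisson"
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC1")

    beta = float(fit.params.iloc[1])
    se = float(fit.bse.iloc[1])
    return RREstimate(
        exposure=exposure,
        outcome=outcome,
        rr=float(np.exp(beta)),
        log_rr_se=se,
        n=n,
        method=method,
    )


def inverse_mills_ratio(z: np.ndarray | float) -> np.ndarray | float:
    """phi(z)/Phi(z) — the expected truncation shift of a standard normal.

    At z = 0 this equals sqrt(2/pi) ≈ 0.79788.  Evaluated on the log
    scale for numerical stability deep in the left tail.
    """
    return np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))


def _heckman_two_stage(
    cohort: pd.DataFrame,
    exposure: str,
    adjust_for: Sequence[str],
    selection_covariates: Sequence[str],
    mills_override: np.ndarray | None = None,
):
    """One pass of the two-stage estimator; returns (beta, mills stats, fits)."""
    part = cohort["participates"].astype(float)
    Z = sm.add_constant(_design(cohort, selection_covariates), prepend=True)
    probit = sm.Probit(part, Z).fit(disp=0, maxiter=200)
    if not probit.mle_retvals.get("converged", False):
        raise RuntimeError(
            "probit participation model failed to converge (possible separation)"
        )
    lp = np.asarray(Z @ probit.params, dtype=float)
    mills = inverse_mills_ratio(lp) if mills_override is None else mills_override

    sel = cohort["participates"] == 1
    if sel.sum() == 0:
        raise ValueError("no wage observations (nobody participates)")
    wage = cohort.loc[sel, "monthly_wage"].astype(float)
    Xw = pd.concat(
        [cohort[exposure].astype(float), _design(cohort, adjust_for)], axis=1
    )
    Xw = sm.add_constant(Xw, prepend=True)
    Xw["_mills"] = mills
    Xw = Xw.loc[sel]
    ols = sm.OLS(np.log(wage), Xw).fit()

    beta = float(ols.params.iloc[1])
    beta_m = float(ols.params["_mills"])
    se_m = float(ols.bse["_mills"])
    # Heckman variance decomposition: sigma^2 = RSS/N + mean(delta) * beta_m^2
    lam = np.asarray(mills)[np.asarray(sel)]
    delta = lam * (lam + lp[np.asarray(sel)])
    sigma2 = float(ols.resid @ ols.resid) / len(wage) + float(np.mean(delta)) * beta_m**2
    rho_hat = beta_m / np.sqrt(sigma2) if sigma2 > 0 else np.nan
    if np.isfinite(rho_hat):
        rho_hat = float(np.clip(rho_hat, -1.0, 1.0))
    return beta, beta_m, se_m, rho_hat, int(sel.sum())


def estimate_wage_effect(
    cohort: pd.DataFrame,
    exposure: str,
    adjust_for: Sequence[str] = (),
    selection_covariates: Sequence[str] = (),
    n_boot: int = 200,
    seed: int = 0,
) -> WageEffect:
    """Selection-corrected proportional wage reduction for one exposure.

    Stage 1 fits a probit of participation on ``selection_covariates``
    by maximum likelihood; stage 2 regresses log wage on the exposure,
    confounders and the inverse Mills ratio at the stage-1 linear
    predictor, over participants only.  ``proportional_reduction`` is
    ``1 - exp(beta_exposure)``; its standard error is a nonparametric
    bootstrap over individuals (seeded, ``n_boot`` replicates).

    At least one selection covariate should be excluded from the wage
    equation (the exclusion restriction); if none is, the estimator is
    identified only by the nonlinearity of the Mills ratio and a
    warning is logged.
    """
    if "participates" not in cohort.columns:
        raise KeyError("cohort has no 'participates' column")
    extra = set(selection_covariates) - set(adjust_for) - {exposure}
    if not extra:
        log.warning(
            "no exclusion restriction: every selection covariate also enters the "
            "wage equation; identification rests on the Mills-ratio nonlinearity"
        )

    beta, beta_m, se_m, rho_hat, n_sel = _heckman_two_stage(
        cohort, exposure, adjust_for, selection_covariates
    )
    reduction = 1.0 - float(np.exp(beta))

    rng = np.random.default_rng(seed)
    reps = []
    n = len(cohort)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = cohort.iloc[idx].reset_index(drop=True)
        try:
            b, *_ = _heckman_two_stage(
                resampled, exposure, adjust_for, selection_covariates
            )
            reps.append(1.0 - np.exp(b))
        except (RuntimeError, ValueError):
            continue
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else np.nan

    return WageEffect(
        exposure=exposure,
        proportional_reduction=reduction,
        se=se,
        rho_hat=rho_hat,
        mills_coef=beta_m,
        mills_se=se_m,
        n_selected=n_sel,
        n=len(cohort),
    )
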