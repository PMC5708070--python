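"""Harmonising and pooling study-level effect sizes.

Three steps bring heterogeneous published effects onto a common
relative-risk scale before attribution:

* :func:`adjust_or` — rescale an unadjusted odds ratio by an externally
  supplied ratio of adjusted to unadjusted ORs from comparable studies.
* :func:`or_to_rr` — the Zhang–Yu conversion
  ``RR = OR / ((1 - P0) + P0 * OR)`` where ``P0`` is the outcome risk
  among the unexposed.
* :func:`pool_rr` — sample-size-weighted meta-analytic pooling, by
  default on the log-RR scale (the weighted geometric mean), so that
  reciprocal effects pool symmetrically.  A linear-scale mode (the
  weighted arithmetic mean of RRs) is available and recorded in the
  result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["StudyEffect", "PooledRR", "adjust_or", "or_to_rr", "pool_rr", "pool_table"]


@dataclass(frozen=True)
class StudyEffect:
    study_id: str
    exposure: str
    outcome: str
    sex: str  # total | male | female
    measure: str  # OR | RR
    value: float
    adjusted: bool = True
    n: float = 1.0
    p0: float | None = None  # unexposed outcome risk, needed for OR -> RR

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"effect value must be positive, got {self.value}")
        if self.measure not in ("OR", "RR"):
            raise ValueError(f"measure must be OR or RR, got {self.measure!r}")
        if self.n <= 0:
            raise ValueError("sample size must be positive")


@dataclass(frozen=True)
class PooledRR:
    exposure: str
    outcome: str
    sex: str
    rr: float
    total_n: float
    k_studies: int
    scale: str = "log"


def adjust_or(unadjusted_or: float, adjustment_ratio: float) -> float:
    """Approximate an adjusted OR as unadjusted OR × (adjusted/unadjusted ratio)."""
    if unadjusted_or <= 0 or adjustment_ratio <= 0:
        raise ValueError("unadjusted OR and adjustment ratio must both be positive")
    return unadjusted_or * adjustment_ratio


def or_to_rr(or_value: float, p0: float) -> float:
    """Zhang–Yu conversion of an odds ratio to a relative risk.

    ``p0`` is the outcome risk among the unexposed.  As ``p0 -> 0`` the
    RR tends to the OR (rare-outcome limit); an OR of 1 maps to an RR
    of 1 for any ``p0``.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 <= p0 < 1.0:
        raise ValueError(f"unexposed risk p0 must be in [0, 1), got {p0}")
    return or_value / ((1.0 - p0) + p0 * or_value)


def to_rr(effect: StudyEffect, rare_outcome: bool = False) -> StudyEffect:
    """Return the effect on the RR scale, converting ORs via Zhang–Yu.

    With ``rare_outcome=True``, ORs are taken as RRs (p0 = 0 limit).
    """
    if effect.measure == "RR":
        return effect
    if rare_outcome:
        rr = effect.value
    else:
        if effect.p0 is None:
            raise ValueError(
                f"study {effect.study_id!r}: OR -> RR conversion needs the "
                "unexposed risk p0 (or rare_outcome mode)"
            )
        rr = or_to_rr(effect.value, effect.p0)
    return StudyEffect(
        study_id=effect.study_id,
        exposure=effect.exposure,
        outcome=effect.outcome,
        sex=effect.sex,
        measure="RR",
        value=rr,
        adjusted=effect.adjusted,
        n=effect.n,
        p0=effect.p0,
    )


def pool_rr(effects: Sequence[StudyEffect], scale: str = "log") -> PooledRR:
    """Sample-size-weighted pooled RR for one (exposure, outcome, sex) cell.

    ``scale="log"`` (default): exp(sum(n_i log rr_i) / sum(n_i));
    ``scale="linear"``: sum(n_i rr_i) / sum(n_i).  Either way the pooled
    value lies within the closed range of the inputs.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    keys = {(e.exposure, e.outcome, e.sex) for e in effects}
    if len(keys) != 1:
        raise ValueError(f"mixed grouping keys in pool: {sorted(keys)}")
    if any(e.measure != "RR" for e in effects):
        raise ValueError("all effects must be on the RR scale before pooling")
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown pooling scale {scale!r}")

    w = np.array([e.n for e in effects], dtype=float)
    rr = np.array([e.value for e in effects], dtype=float)
    if scale == "log":
        pooled = float(np.exp(np.sum(w * np.log(rr)) / w.sum()))
    else:
        pooled = float(np.sum(w * rr) / w.sum())
    (exposure, outcome, sex), = keys
    return PooledRR(
        exposure=exposure,
        outcome=outcome,
        sex=sex,
        rr=pooled,
        total_n=float(w.sum()),
        k_studies=len(effects),
        scale=scale,
    )


def pool_table(
    effects: Iterable[StudyEffect],
    scale: str = "log",
    rare_outcome: bool = False,
) -> pd.DataFrame:
    """Convert all effects to RRs and pool per (exposure, outcome, sex)."""
    converted: dict[tuple, list[StudyEffect]] = {}
    for e in effects:
        e = to_rr(e, rare_outcome=rare_outcome)
        converted.setdefault((e.exposure, e.outcome, e.sex), []).append(e)
    rows = [pool_rr(group, scale=scale) for group in converted.values()]
    return pd.DataFrame(
        [
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "sex": r.sex,
                "rr": r.rr,
                "total_n": r.total_n,
                "k_studies": r.k_studies,
                "scale": r.scale,
            }
            for r in rows
        ]
    )
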