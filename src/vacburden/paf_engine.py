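"""Population attributable fractions.

PAF = p(RR - 1) / (1 + p(RR - 1)), the Levin formula for a binary
exposure with prevalence ``p`` and relative risk ``RR``: the proportion
of the outcome's population burden that would disappear if the exposed
had the risk of the unexposed.  Sex-stratified cells use sex-specific
prevalence; cells with no pooled RR are simply absent from the output
(never zero-filled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["PAFRecord", "paf", "build_paf_table"]


@dataclass(frozen=True)
class PAFRecord:
    exposure: str
    outcome: str
    sex: str
    paf: float
    rr_used: float
    p_used: float


def paf(p: float, rr: float) -> float:
    """Levin attributable fraction for prevalence ``p`` and relative risk ``rr``.

    Equivalent to the counterfactual contrast (I - I0)/I where
    I = p·r0·rr + (1-p)·r0 is the factual incidence and I0 = r0 the
    incidence with exposure removed, for any baseline risk r0 > 0.
    A protective rr < 1 yields a negative fraction (logged as a
    warning); rr = 1 or p = 0 yields exactly 0.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if rr < 1.0:
        log.warning("rr = %.4g < 1: protective exposure, PAF will be negative", rr)
    excess = p * (rr - 1.0)
    return excess / (1.0 + excess)


def build_paf_table(
    prevalences: pd.DataFrame, pooled: pd.DataFrame
) -> pd.DataFrame:
    """One PAF row per pooled-RR row.

    ``prevalences`` needs columns (exposure, sex, p); ``pooled`` needs
    (exposure, outcome, sex, rr).  Every pooled row must find a
    prevalence for its (exposure, sex) — a missing one is an error
    naming the cell, because silently dropping it would understate the
    burden.
    """
    if pooled.empty:
        return pd.DataFrame(
            columns=["exposure", "outcome", "sex", "paf", "rr_used", "p_used"]
        )
    prev = prevalences.set_index(["exposure", "sex"])["p"]
    if prev.index.has_duplicates:
        raise ValueError("duplicate (exposure, sex) rows in prevalence table")
    records = []
    for row in pooled.itertuples(index=False):
        key = (row.exposure, row.sex)
        if key not in prev.index:
            raise KeyError(
                f"no prevalence for exposure={row.exposure!r}, sex={row.sex!r} "
                f"(needed by outcome {row.outcome!r})"
            )
        p = float(prev.loc[key])
        records.append(
            {
                "exposure": row.exposure,
                "outcome": row.outcome,
                "sex": row.sex,
                "paf": paf(p, float(row.rr)),
                "rr_used": float(row.rr),
                "p_used": p,
            }
        )
    return pd.DataFrame(records)
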