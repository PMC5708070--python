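"""Attributable DALYs — nonfatal attribution, fatal YLL, and monetisation.

Nonfatal: a PAF for an (exposure, outcome, sex) cell multiplies the
baseline DALYs for that outcome (GBD-style totals, age 15+, supplied as
a table), after subtracting any cause-category contributions listed in
a cause-exclusion map (double-count removal, e.g. self-harm and
HIV/AIDS removed from the drug-use envelope when attributed
separately).  Sex strata are attributed with sex-specific baselines and
then summed to exposure × outcome cells.

Fatal: deaths per age band × expected years of life lost at the band's
representative age, read off a standard life table by piecewise-linear
interpolation.  The representative age is the floored midpoint of the
band (0–4 → 2, 5–9 → 7, 10–14 → 12, 15–17 → 16).

Monetisation follows the human-capital convention: one DALY is valued
at the country's per-capita GDP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "HomicideCounts",
    "validate_exclusion_map",
    "yll_at_age",
    "fatal_dalys",
    "attribute_dalys",
    "aggregate_burden",
    "monetise",
]


@dataclass(frozen=True)
class LifeTable:
    """Anchor points (age, expected YLL for a death at that age)."""

    ages: tuple[float, ...]
    yll: tuple[float, ...]

    def __post_init__(self):
        if len(self.ages) != len(self.yll) or len(self.ages) < 2:
            raise ValueError("life table needs >= 2 (age, yll) anchors")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("life-table ages must be strictly increasing")
        if any(b >= a for a, b in zip(self.yll, self.yll[1:])):
            raise ValueError("life-table YLL must be strictly decreasing with age")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        df = df.sort_values("age")
        return cls(tuple(df["age"].astype(float)), tuple(df["yll"].astype(float)))

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class HomicideCounts:
    """Child homicide deaths per inclusive age band, for one reference year."""

    bands: tuple[tuple[float, float, int], ...]  # (low, high, deaths)
    reference_year: int

    def __post_init__(self):
        spans = sorted((lo, hi) for lo, hi, _ in self.bands)
        for (lo, hi, d) in self.bands:
            if hi < lo:
                raise ValueError(f"age band [{lo}, {hi}] is inverted")
            if d < 0 or d != int(d):
                raise ValueError(f"deaths must be a non-negative integer, got {d}")
        for (_, h1), (l2, _) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ValueError("age bands overlap")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_year: int) -> "HomicideCounts":
        bands = tuple(
            (float(r.band_low), float(r.band_high), int(r.deaths))
            for r in df.itertuples(index=False)
        )
        return cls(bands, reference_year)


def yll_at_age(age: float, table: LifeTable) -> float:
    """Expected years of life lost for a death at ``age`` (interpolated)."""
    if age < table.ages[0] or age > table.ages[-1]:
        raise ValueError(
            f"age {age} outside life-table range [{table.ages[0]}, {table.ages[-1]}]"
        )
    return float(np.interp(age, table.ages, table.yll))


def representative_age(low: float, high: float) -> float:
    """Floored midpoint of an inclusive age band."""
    return float(math.floor((low + high) / 2.0))


def fatal_dalys(counts: HomicideCounts, table: LifeTable) -> float:
    """Sum over bands of deaths × YLL at the band's representative age.

    Full precision; round to an integer only when reporting.
    """
    if not counts.bands:
        log.warning("no homicide age bands supplied; fatal DALYs are 0")
        return 0.0
    total = 0.0
    for lo, hi, deaths in counts.bands:
        total += deaths * yll_at_age(representative_age(lo, hi), table)
    return total


def validate_exclusion_map(exclusions: Mapping[str, Sequence[str]]) -> None:
    """Reject self-referencing or cyclic cause-exclusion maps."""
    for risk, causes in exclusions.items():
        if risk in causes:
            raise ValueError(f"exclusion map: {risk!r} excludes itself")
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        state[node] = 1
        for nxt in exclusions.get(node, ()):
            if state.get(nxt) == 1:
                raise ValueError(f"exclusion map contains a cycle through {nxt!r}")
            if state.get(nxt) != 2:
                visit(nxt)
        state[node] = 2

    for node in exclusions:
        if state.get(node) != 2:
            visit(node)


def attribute_dalys(
    pafs: pd.DataFrame,
    baseline: pd.DataFrame,
    exclusions: Mapping[str, Sequence[str]] | None = None,
    cause_contributions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Multiply each PAF cell into its (possibly exclusion-reduced) baseline.

    ``pafs`` carries (exposure, outcome, sex, paf); ``baseline`` carries
    (outcome, sex, dalys) and may carry an ``exposure`` column when the
    caller supplies per-exposure baselines (as the bundled
    reverse-engineered validation fixture does).  ``exclusions`` maps a
    risk outcome to cause categories whose contributions — rows
    (outcome, cause, sex, dalys) of ``cause_contributions`` — are
    subtracted from its baseline before multiplication; a negative
    post-exclusion baseline is clipped to zero with a warning.

    Returns one row per (exposure, outcome) with the summed
    ``daly_loss`` across sex strata, plus the per-stratum detail in
    ``daly_loss`` of the returned ``detail`` attribute-free frame.
    """
    exclusions = dict(exclusions or {})
    validate_exclusion_map(exclusions)

    per_exposure = "exposure" in baseline.columns
    key_cols = ["exposure", "outcome", "sex"] if per_exposure else ["outcome", "sex"]
    base = baseline.set_index(key_cols)["dalys"]
    if base.index.has_duplicates:
        raise ValueError(f"duplicate {key_cols} rows in baseline table")

    contrib = None
    if cause_contributions is not None:
        contrib = cause_contributions.set_index(["outcome", "cause", "sex"])["dalys"]

    rows = []
    for row in pafs.itertuples(index=False):
        key = (
            (row.exposure, row.outcome, row.sex)
            if per_exposure
            else (row.outcome, row.sex)
        )
        if key not in base.index:
            raise KeyError(
                f"no baseline DALYs for exposure={row.exposure!r}, "
                f"outcome={row.outcome!r}, sex={row.sex!r}"
            )
        dalys = float(base.loc[key])
        for cause in exclusions.get(row.outcome, ()):
            ckey = (row.outcome, cause, row.sex)
            if contrib is not None and ckey in contrib.index:
                dalys -= float(contrib.loc[ckey])
        if dalys < 0:
            log.warning(
                "baseline for %s/%s went negative (%.1f) after cause exclusion; "
                "clipping to 0",
                row.outcome,
                row.sex,
                dalys,
            )
            dalys = 0.0
        rows.append(
            {
                "exposure": row.exposure,
                "outcome": row.outcome,
                "sex": row.sex,
                "daly_loss": float(row.paf) * dalys,
            }
        )
    detail = pd.DataFrame(rows)
    if detail.empty:
        return pd.DataFrame(columns=["exposure", "outcome", "daly_loss"])
    cells = (
        detail.groupby(["exposure", "outcome"], sort=False)["daly_loss"]
        .sum()
        .reset_index()
    )
    return cells


def aggregate_burden(
    cells: pd.DataFrame,
    envelope_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-exposure DALY totals with envelope double-count removal.

    ``envelope_map`` maps an envelope outcome (e.g. serious mental
    illness, matched to the GBD "mental disorders" envelope) to the
    sub-category outcomes it already contains (anxiety, depression).
    When an exposure has a cell for the envelope outcome, cells for the
    contained outcomes are left out of that exposure's total — they are
    already counted inside the envelope — though they remain in the
    per-cell output.
    """
    envelope_map = dict(envelope_map or {})
    validate_exclusion_map(envelope_map)
    totals = []
    for exposure, grp in cells.groupby("exposure", sort=False):
        present = set(grp["outcome"])
        drop: set[str] = set()
        for env, children in envelope_map.items():
            if env in present:
                drop |= set(children) & present
        kept = grp[~grp["outcome"].isin(drop)]
        totals.append(
            {
                "exposure": exposure,
                "daly_loss": float(kept["daly_loss"].sum()),
                "outcomes_excluded_from_total": ",".join(sorted(drop)),
            }
        )
    return pd.DataFrame(totals)


def monetise(daly_loss: float, gdp_per_capita: float) -> float:
    """Value DALYs at per-capita GDP (human-capital approach)."""
    if daly_loss < 0 or gdp_per_capita < 0:
        raise ValueError("daly_loss and gdp_per_capita must be non-negative")
    return daly_loss * gdp_per_capita
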