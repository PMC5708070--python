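"""National productivity loss from per-victim proportional wage reductions.

The chain is: CPI-adjust median monthly earnings to the costing year;
victims in the labour force = labour force × lifetime prevalence;
per-victim monthly loss = adjusted earnings × proportional reduction;
monthly national loss = victims × per-victim loss; annual = 12 ×
monthly.  All intermediates are kept at full precision — rounding the
victim count and the per-victim loss before multiplying shifts the
total by millions of Rand — and rounded only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

__all__ = [
    "EconParams",
    "ProductivityLoss",
    "adjust_earnings",
    "productivity_loss",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Commercial rounding for displayed counts (0.5 always rounds up)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EconParams:
    """Economy-level scalars for the costing year.

    All currency amounts are in ZAR.  ``cpi_ratio`` is the costing-year
    price level over the earnings reference year.  ``exchange_rate``
    (ZAR per USD) only feeds an optional reporting column.
    """

    gdp_per_capita: float
    median_monthly_earnings_base: float | None = None
    cpi_ratio: float | None = None
    labour_force: float | None = None
    gdp_total: float | None = None
    exchange_rate: float | None = None

    def __post_init__(self):
        for name in (
            "gdp_per_capita",
            "median_monthly_earnings_base",
            "cpi_ratio",
            "labour_force",
            "gdp_total",
            "exchange_rate",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"EconParams.{name} must be positive, got {v}")

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ValueError(f"EconParams.{name} is required but missing")

    @classmethod
    def from_yaml(cls, path) -> "EconParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: raw[k] for k in raw if not k.startswith("_")})


@dataclass(frozen=True)
class ProductivityLoss:
    exposure: str
    prevalence: float
    reduction: float
    victims_in_labour_force: float  # unrounded
    per_victim_monthly_loss: float  # unrounded, ZAR
    monthly_loss: float  # ZAR
    annual_loss: float  # ZAR
    share_of_gdp: float | None = None


def adjust_earnings(base: float, cpi_ratio: float) -> float:
    """Bring reference-year earnings to costing-year prices."""
    if base <= 0 or cpi_ratio <= 0:
        raise ValueError("earnings and CPI ratio must be positive")
    return base * cpi_ratio


def productivity_loss(
    exposure: str,
    prevalence: float,
    reduction: float,
    econ: EconParams,
) -> ProductivityLoss:
    """Annual national earnings loss attributable to one violence type.

    ``prevalence`` is the total-population lifetime prevalence of the
    exposure; ``reduction`` the proportional per-victim monthly
    earnings reduction.  Every intermediate stays unrounded.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    if not 0.0 <= reduction < 1.0:
        raise ValueError(f"reduction must be in [0, 1), got {reduction}")
    econ.require("median_monthly_earnings_base", "cpi_ratio", "labour_force")

    earnings = adjust_earnings(econ.median_monthly_earnings_base, econ.cpi_ratio)
    victims = econ.labour_force * prevalence
    per_victim = earnings * reduction
    monthly = victims * per_victim
    annual = 12.0 * monthly
    share = annual / econ.gdp_total if econ.gdp_total else None
    return ProductivityLoss(
        exposure=exposure,
        prevalence=prevalence,
        reduction=reduction,
        victims_in_labour_force=victims,
        per_victim_monthly_loss=per_victim,
        monthly_loss=monthly,
        annual_loss=annual,
        share_of_gdp=share,
    )
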