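"""End-to-end orchestration: tables in, burden report out.

Runs pooling → PAF → nonfatal DALY attribution → fatal YLL →
monetisation → earnings loss → welfare aggregation from a single YAML
run configuration, writing machine-readable CSVs and a text report.
Every mode in effect (pooling scale, exposure inclusion list, envelope
exclusions) is logged so a run is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from vacburden import burden_daly, earnings_loss, paf_engine
from vacburden.effect_pooling import StudyEffect, pool_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "aggregate_welfare", "run_pipeline", "format_report"]


@dataclass
class RunConfig:
    prevalence_path: Path
    effects_path: Path
    baseline_path: Path
    life_table_path: Path
    homicide_path: Path
    welfare_path: Path
    econ: earnings_loss.EconParams
    include_exposures: Sequence[str]
    wage_reductions: Mapping[str, float] = field(default_factory=dict)
    cause_exclusions: Mapping[str, Sequence[str]] = field(default_factory=dict)
    cause_contributions_path: Path | None = None
    envelope_map: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"smi": ["anxiety", "depression"]}
    )
    pooling_scale: str = "log"
    rare_outcome: bool = False
    homicide_reference_year: int = 2009
    seed: int = 0

    def __post_init__(self):
        if not self.include_exposures:
            raise ValueError("exposure inclusion list must be non-empty")
        for name in (
            "prevalence_path",
            "effects_path",
            "baseline_path",
            "life_table_path",
            "homicide_path",
            "welfare_path",
        ):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
            setattr(self, name, p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        econ = earnings_loss.EconParams(**raw["econ"])
        return cls(
            prevalence_path=resolve(raw["prevalence_path"]),
            effects_path=resolve(raw["effects_path"]),
            baseline_path=resolve(raw["baseline_path"]),
            life_table_path=resolve(raw["life_table_path"]),
            homicide_path=resolve(raw["homicide_path"]),
            welfare_path=resolve(raw["welfare_path"]),
            econ=econ,
            include_exposures=raw["include_exposures"],
            wage_reductions=raw.get("wage_reductions", {}),
            cause_exclusions=raw.get("cause_exclusions", {}),
            cause_contributions_path=(
                resolve(raw["cause_contributions_path"])
                if raw.get("cause_contributions_path")
                else None
            ),
            envelope_map=raw.get(
                "envelope_map", {"smi": ["anxiety", "depression"]}
            ),
            pooling_scale=raw.get("pooling_scale", "log"),
            rare_outcome=raw.get("rare_outcome", False),
            homicide_reference_year=raw.get("homicide_reference_year", 2009),
            seed=raw.get("seed", 0),
        )


def aggregate_welfare(spends: pd.DataFrame) -> float:
    """Exact sum of provincial child care and protection spending.

    Expects columns (province, amount_thousand_zar); amounts are in
    thousand ZAR and must be non-negative.
    """
    if len(spends) == 0:
        raise ValueError("empty welfare spending table")
    amounts = spends["amount_thousand_zar"]
    if (amounts < 0).any():
        bad = spends.loc[amounts < 0, "province"].tolist()
        raise ValueError(f"negative welfare spending for {bad}")
    return float(amounts.sum())


def _pool_effects(config: RunConfig) -> pd.DataFrame:
    df = pd.read_csv(config.effects_path)
    effects = []
    for i, row in enumerate(df.itertuples(index=False)):
        effects.append(
            StudyEffect(
                study_id=str(getattr(row, "study_id", i)),
                exposure=row.exposure,
                outcome=row.outcome,
                sex=row.sex,
                measure=getattr(row, "measure", "RR"),
                value=float(row.rr) if hasattr(row, "rr") else float(row.value),
                n=float(getattr(row, "n", 1.0)),
                p0=(
                    float(row.p0)
                    if hasattr(row, "p0") and pd.notna(row.p0)
                    else None
                ),
            )
        )
    return pool_table(
        effects, scale=config.pooling_scale, rare_outcome=config.rare_outcome
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full burden estimation; returns the report bundle.

    The bundle carries the pooled RRs, the PAF table, per-cell and
    per-exposure burden (DALYs and monetary value), fatal DALYs and
    their value, annual earnings losses, the welfare total, and shares
    of GDP where ``gdp_total`` is configured.
    """
    log.info(
        "pipeline modes: pooling=%s rare_outcome=%s exposures=%s envelope=%s",
        config.pooling_scale,
        config.rare_outcome,
        list(config.include_exposures),
        dict(config.envelope_map),
    )

    pooled = _pool_effects(config)
    dropped = sorted(set(pooled["exposure"]) - set(config.include_exposures))
    if dropped:
        log.info("exposures excluded from burden totals: %s", dropped)
    pooled = pooled[pooled["exposure"].isin(config.include_exposures)].reset_index(
        drop=True
    )

    prevalence = pd.read_csv(config.prevalence_path)
    pafs = paf_engine.build_paf_table(prevalence, pooled)

    baseline = pd.read_csv(config.baseline_path)
    contributions = (
        pd.read_csv(config.cause_contributions_path)
        if config.cause_contributions_path
        else None
    )
    cells = burden_daly.attribute_dalys(
        pafs, baseline, config.cause_exclusions, contributions
    )
    gdp = config.econ.gdp_per_capita
    cells = cells.assign(
        economic_value=lambda d: d["daly_loss"].map(
            lambda x: burden_daly.monetise(x, gdp)
        )
    )
    totals = burden_daly.aggregate_burden(cells, config.envelope_map)
    totals = totals.assign(economic_value=totals["daly_loss"] * gdp)
    nonfatal_dalys = float(totals["daly_loss"].sum())
    nonfatal_value = float(totals["economic_value"].sum())

    life = burden_daly.LifeTable.from_csv(config.life_table_path)
    homicides = burden_daly.HomicideCounts.from_frame(
        pd.read_csv(config.homicide_path), config.homicide_reference_year
    )
    fatal = burden_daly.fatal_dalys(homicides, life)
    fatal_value = burden_daly.monetise(fatal, gdp)

    losses = [
        earnings_loss.productivity_loss(
            exposure,
            float(
                prevalence.set_index(["exposure", "sex"]).loc[
                    (exposure, "total"), "p"
                ]
            ),
            reduction,
            config.econ,
        )
        for exposure, reduction in config.wage_reductions.items()
    ]

    welfare_total = aggregate_welfare(pd.read_csv(config.welfare_path))

    gdp_total = config.econ.gdp_total
    report = {
        "pooled_rr": pooled,
        "paf_table": pafs,
        "burden_cells": cells,
        "burden_totals": totals,
        "nonfatal_dalys": nonfatal_dalys,
        "nonfatal_value": nonfatal_value,
        "fatal_dalys": fatal,
        "fatal_value": fatal_value,
        "total_dalys": nonfatal_dalys + fatal,
        "total_value": nonfatal_value + fatal_value,
        "earnings_losses": losses,
        "welfare_total_thousand_zar": welfare_total,
        "shares_of_gdp": (
            {
                "nonfatal": nonfatal_value / gdp_total,
                "fatal": fatal_value / gdp_total,
                "total": (nonfatal_value + fatal_value) / gdp_total,
                "welfare": welfare_total * 1e3 / gdp_total,
                **{
                    f"earnings_{pl.exposure}": pl.annual_loss / gdp_total
                    for pl in losses
                },
            }
            if gdp_total
            else None
        ),
    }
    return report


def format_report(report: dict) -> str:
    """Human-readable report: DALYs as integers, values in million ZAR
    (burden table convention), earnings in Rand and billions."""
    lines = []
    lines.append("Attributable burden of violence against children")
    lines.append("=" * 48)
    lines.append("")
    lines.append("Nonfatal burden by violence type (age 15+ outcomes):")
    for row in report["burden_totals"].itertuples(index=False):
        note = (
            f"  [excluded from total: {row.outcomes_excluded_from_total}]"
            if row.outcomes_excluded_from_total
            else ""
        )
        lines.append(
            f"  {row.exposure:<12} {row.daly_loss:>12,.0f} DALYs   "
            f"ZAR {row.economic_value / 1e6:>10,.0f} m{note}"
        )
    lines.append(
        f"  {'TOTAL':<12} {report['nonfatal_dalys']:>12,.0f} DALYs   "
        f"ZAR {report['nonfatal_value'] / 1e6:>10,.0f} m"
    )
    lines.append("")
    lines.append(
        f"Fatal burden: {report['fatal_dalys']:,.0f} DALYs   "
        f"ZAR {report['fatal_value'] / 1e9:.1f} bn"
    )
    lines.append(
        f"Fatal + nonfatal economic value: ZAR {report['total_value'] / 1e9:.1f} bn"
    )
    lines.append("")
    lines.append("Annual productivity losses (reduced earnings):")
    for pl in report["earnings_losses"]:
        lines.append(
            f"  {pl.exposure:<12} victims "
            f"{earnings_loss.round_half_up(pl.victims_in_labour_force):>12,}   "
            f"per-victim ZAR {pl.per_victim_monthly_loss:,.0f}/month   "
            f"monthly ZAR {pl.monthly_loss:,.0f}   annual ZAR {pl.annual_loss / 1e9:.1f} bn"
        )
    lines.append("")
    lines.append(
        f"Child care and protection spending: "
        f"ZAR {report['welfare_total_thousand_zar']:,.0f} thousand "
        f"(ZAR {report['welfare_total_thousand_zar'] / 1e6:.2f} bn)"
    )
    shares = report.get("shares_of_gdp")
    if shares:
        lines.append("")
        lines.append("Shares of GDP:")
        for k, v in shares.items():
            lines.append(f"  {k:<22} {100 * v:.2f}%")
    return "\n".join(lines)


def write_outputs(report: dict, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["pooled_rr"].to_csv(outdir / "pooled_rr.csv", index=False)
    report["paf_table"].to_csv(outdir / "paf_table.csv", index=False)
    report["burden_cells"].to_csv(outdir / "burden_cells.csv", index=False)
    report["burden_totals"].to_csv(outdir / "burden_totals.csv", index=False)
    pd.DataFrame(
        [
            {
                "exposure": pl.exposure,
                "prevalence": pl.prevalence,
                "reduction": pl.reduction,
                "victims_in_labour_force": pl.victims_in_labour_force,
                "per_victim_monthly_loss": pl.per_victim_monthly_loss,
                "monthly_loss": pl.monthly_loss,
                "annual_loss": pl.annual_loss,
                "share_of_gdp": pl.share_of_gdp,
            }
            for pl in report["earnings_losses"]
        ]
    ).to_csv(outdir / "earnings_losses.csv", index=False)
    (outdir / "report.txt").write_text(format_report(report) + "\n")
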