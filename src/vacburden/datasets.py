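"""Bundled input tables.

Small CSV/YAML fixtures shipped with the package: the national
lifetime-prevalence table, the study-level relative risks with their
published attributable fractions (for cross-checking), provincial
child-welfare spending, child homicide counts, standard life-table YLL
anchors, economy-level scalars, and a **synthetic** baseline-DALY table
reverse-engineered from the published burden table so the attribution
path can be validated end-to-end (see ``baseline_dalys_synthetic.csv``
— it is a validation fixture, not GBD data).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "data_path",
    "load_prevalence",
    "load_study_rr",
    "load_baseline_dalys",
    "load_burden_reference",
    "load_life_table",
    "load_homicides",
    "load_welfare_spend",
    "load_econ_params",
    "load_cohort_spec",
    "reproduction_config_path",
]


def data_path(name: str = "") -> Path:
    base = resources.files("vacburden") / "data"
    return Path(str(base / name if name else base))


def load_prevalence() -> pd.DataFrame:
    """Lifetime prevalence of each violence type by sex stratum."""
    return pd.read_csv(data_path("prevalence_optimus.csv"))


def load_study_rr() -> pd.DataFrame:
    """Published pooled RRs per exposure × outcome × sex, with the
    published PAF (string, preserving printed precision) for cross-checks."""
    return pd.read_csv(data_path("study_rr_table.csv"), dtype={"paf_printed": str})


def load_baseline_dalys() -> pd.DataFrame:
    """Synthetic per-(exposure, outcome, sex) baseline DALYs (validation fixture)."""
    return pd.read_csv(data_path("baseline_dalys_synthetic.csv"))


def load_burden_reference() -> pd.DataFrame:
    """Published attributable DALYs and economic value per exposure × outcome."""
    return pd.read_csv(data_path("burden_reference.csv"))


def load_life_table():
    from vacburden.burden_daly import LifeTable

    return LifeTable.from_csv(data_path("life_table_yll.csv"))


def load_homicides():
    from vacburden.burden_daly import HomicideCounts

    df = pd.read_csv(data_path("homicides_2009.csv"))
    return HomicideCounts.from_frame(df, reference_year=2009)


def load_welfare_spend() -> pd.DataFrame:
    """Provincial child care and protection spending, thousand ZAR."""
    return pd.read_csv(data_path("welfare_spend_2015.csv"))


def load_econ_params():
    from vacburden.earnings_loss import EconParams

    return EconParams.from_yaml(data_path("econ_params.yaml"))


def load_cohort_spec():
    from vacburden.synthetic_cohort import CohortSpec

    return CohortSpec.from_yaml(data_path("caps_synthetic.yaml"))


def reproduction_config_path() -> Path:
    return data_path("reproduction_run.yaml")
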