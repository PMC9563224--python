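"""Bundled reference dataset: a Brazilian cold-pressed sunflower oil.

The package ships, as versioned data files, the measured fatty-acid
composition, the ICP OES trace-element panel with its LOD/LOQ values, the
regulatory limit tables (FAO/WHO, DRI/AI, RfD, slope factors), the Codex
identity/quality rules with the measured physicochemical parameters, and
the three exposure cohorts (8 y / 26 kg, 18 y / 62 kg, 30 y / 70 kg) with
their reference ingestion rates.  Every loader returns a fresh object, so
the full desk-scale reproduction needs no downloads.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import pandas as pd
import yaml

from .compliance import ParameterRule, read_parameters_csv, read_rules_yaml
from .elements import ElementPanel, LimitTable, read_element_csv
from .fatty_acids import FattyAcidProfile, read_fa_csv
from .risk import Cohort, ExposureScenario, UnitMode

__all__ = [
    "load_reference_fa_profile",
    "load_reference_element_panel",
    "load_default_limits",
    "load_reference_cohorts",
    "load_reference_scenarios",
    "load_default_targets",
    "load_codex_rules",
    "load_reference_quality_params",
]

_DATA = resources.files("oleosafe.data")


def _open(name: str):
    return (_DATA / name).open("r", encoding="utf-8")


def load_reference_fa_profile() -> FattyAcidProfile:
    """Measured fatty-acid composition (16 species, percents of total FAs)."""
    with _open("sunflower_fa.csv") as fh:
        return read_fa_csv(fh)


def load_reference_element_panel() -> ElementPanel:
    """ICP OES element panel: six quantified elements plus the non-detects."""
    with _open("sunflower_elements.csv") as fh:
        return read_element_csv(fh)


def load_default_limits() -> LimitTable:
    """FAO/WHO limits, DRI/AI by cohort, oral RfDs and slope factors."""
    with _open("limits.yaml") as fh:
        return LimitTable.from_yaml(fh)


def _cohort_config() -> dict[str, Any]:
    with _open("cohorts.yaml") as fh:
        return yaml.safe_load(fh)


def load_reference_cohorts() -> list[Cohort]:
    cfg = _cohort_config()
    return [
        Cohort(
            label=c["label"],
            age_years=float(c["age_years"]),
            body_weight=float(c["body_weight"]),
        )
        for c in cfg["cohorts"]
    ]


def load_reference_scenarios(unit_mode: UnitMode | str | None = None) -> list[ExposureScenario]:
    """Cohorts paired with their reference ingestion rates."""
    cfg = _cohort_config()
    mode = UnitMode(unit_mode) if unit_mode else UnitMode(cfg.get("unit_mode", "paper"))
    return [
        ExposureScenario(
            Cohort(
                label=c["label"],
                age_years=float(c["age_years"]),
                body_weight=float(c["body_weight"]),
            ),
            ingestion_rate=float(c["ingestion_rate"]),
            unit_mode=mode,
        )
        for c in cfg["cohorts"]
    ]


def load_default_targets() -> dict[str, float]:
    """Risk targets used by the bundled reproduction: HI and total CR."""
    cfg = _cohort_config()
    return {"hi": float(cfg["targets"]["hi"]), "cancer_risk": float(cfg["targets"]["cancer_risk"])}


def load_codex_rules() -> dict[str, ParameterRule]:
    with _open("codex_rules.yaml") as fh:
        return read_rules_yaml(fh)


def load_reference_quality_params() -> pd.DataFrame:
    with _open("oil_quality.csv") as fh:
        return read_parameters_csv(fh)
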