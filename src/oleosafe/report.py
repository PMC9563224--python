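"""End-to-end analysis report: indices, exceedances, risk chain, safe intakes.

:func:`run_full_analysis` composes the individual stages — fatty-acid class
sums and nutritional indices, FAO/WHO exceedance screening, the CDI→HQ→HI
and CDI→CR chains per cohort, the inverse safe-intake solve, and the Codex
compliance check — into one serialisable :class:`AnalysisReport`.  The JSON
form has stable key order, so identical inputs give byte-identical output;
provenance records a content hash of the inputs together with the package
version.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__ as _version
from .compliance import ComplianceEntry, ParameterRule, evaluate_panel
from .datasets import (
    load_codex_rules,
    load_default_limits,
    load_default_targets,
    load_reference_element_panel,
    load_reference_fa_profile,
    load_reference_quality_params,
    load_reference_scenarios,
)
from .elements import ElementPanel, ExceedanceEntry, LimitTable, exceedance_report
from .errors import DomainError, OleosafeError
from .fatty_acids import (
    FattyAcidProfile,
    atherogenicity_index,
    class_sums,
    hh_ratio,
    thrombogenicity_index,
)
from .risk import (
    RiskResult,
    SafeIntakeResult,
    UnitMode,
    hazard_index,
    risk_grid,
    safe_intake,
)

__all__ = ["AnalysisReport", "run_full_analysis"]


class StageError(OleosafeError):
    """An analysis stage failed; carries the stage name for error reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class AnalysisReport:
    class_sums: Mapping[str, float]
    indices: Mapping[str, float]
    exceedances: Mapping[str, ExceedanceEntry]
    risk: Mapping[str, RiskResult]
    safe_intakes: Mapping[str, SafeIntakeResult]
    compliance: tuple[ComplianceEntry, ...]
    provenance: Mapping[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "class_sums": dict(self.class_sums),
            "indices": dict(self.indices),
            "exceedances": {
                s: {
                    "limit_source": e.limit_source,
                    "evaluable": e.evaluable,
                    "ratio_percent": e.ratio_percent,
                    "exceeds": e.exceeds,
                    "limit": e.limit,
                }
                for s, e in self.exceedances.items()
            },
            "risk": {
                label: {
                    "ingestion_rate_g_per_day": r.scenario.ingestion_rate,
                    "body_weight_kg": r.scenario.cohort.body_weight,
                    "cdi": dict(r.cdi),
                    "hq": dict(r.hq),
                    "hi": r.hi,
                    "hi_safe": r.hi_safe,
                    "cancer_risk": dict(r.cancer_risk),
                    "cr_class": {s: c.value for s, c in r.cr_class.items()},
                    "excluded_no_rfd": list(r.excluded_no_rfd),
                    "censored": list(r.censored),
                }
                for label, r in self.risk.items()
            },
            "safe_intakes": {
                label: {
                    "intake_g_per_day": s.intake_g_per_day
                    if math.isfinite(s.intake_g_per_day)
                    else None,
                    "binding_constraint": s.binding_constraint,
                    "hi_limited": s.hi_limited,
                    "cr_limited": s.cr_limited if math.isfinite(s.cr_limited) else None,
                }
                for label, s in self.safe_intakes.items()
            },
            "compliance": [
                {
                    "name": c.name,
                    "measured": c.measured,
                    "sd": c.sd,
                    "units": c.units,
                    "verdict": c.verdict,
                    "margin": c.margin,
                }
                for c in self.compliance
            ],
            "provenance": dict(self.provenance),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _input_hash(
    profile: FattyAcidProfile,
    panel: ElementPanel,
    limits: LimitTable,
    targets: Mapping[str, float],
) -> str:
    payload = {
        "fa": [(sp.shorthand, sp.percent) for sp in profile.species],
        "elements": [(m.symbol, m.concentration, m.lod, m.loq) for m in panel],
        "limits": {
            s: (lim.fao_who, lim.rfd, lim.slope_factor, sorted(lim.dri_ai.items()))
            for s, lim in sorted(limits.elements.items())
        },
        "targets": sorted(targets.items()),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_full_analysis(
    fa_profile: FattyAcidProfile | None = None,
    element_panel: ElementPanel | None = None,
    limits: LimitTable | None = None,
    scenarios: Sequence | None = None,
    rules: Mapping[str, ParameterRule] | None = None,
    quality_params: pd.DataFrame | None = None,
    hi_target: float | None = None,
    cr_target: float | None = None,
    unit_mode: UnitMode = UnitMode.PAPER_FAITHFUL,
) -> AnalysisReport:
    """Run every stage on the given (or bundled) inputs.

    Any argument left ``None`` falls back to the bundled reference dataset,
    so ``run_full_analysis()`` with no arguments is the complete desk-scale
    reproduction.  A failure in any stage raises :class:`StageError` naming
    the stage.
    """
    fa_profile = fa_profile if fa_profile is not None else load_reference_fa_profile()
    element_panel = (
        element_panel if element_panel is not None else load_reference_element_panel()
    )
    limits = limits if limits is not None else load_default_limits()
    scenarios = (
        list(scenarios) if scenarios is not None else load_reference_scenarios(unit_mode)
    )
    rules = rules if rules is not None else load_codex_rules()
    quality_params = (
        quality_params if quality_params is not None else load_reference_quality_params()
    )
    targets = load_default_targets()
    if hi_target is not None:
        targets["hi"] = hi_target
    if cr_target is not None:
        targets["cancer_risk"] = cr_target

    try:
        cs = class_sums(fa_profile)
        indices = {
            "ai": atherogenicity_index(fa_profile),
            "ti": thrombogenicity_index(fa_profile),
            "hh": hh_ratio(fa_profile),
        }
        sums = {
            "sfa": cs.sfa,
            "mufa": cs.mufa,
            "pufa": cs.pufa,
            "ufa": cs.ufa,
            "omega3": cs.omega3,
            "omega6": cs.omega6,
        }
    except OleosafeError as exc:
        raise StageError("nutritional_indices", exc) from exc

    try:
        exceed = exceedance_report(element_panel, limits)
    except OleosafeError as exc:
        raise StageError("exceedance", exc) from exc

    risk_results: dict[str, RiskResult] = {}
    intakes: dict[str, SafeIntakeResult] = {}
    try:
        for scenario in scenarios:
            risk_results[scenario.cohort.label] = hazard_index(
                element_panel, limits, scenario
            )
            intakes[scenario.cohort.label] = safe_intake(
                element_panel,
                limits,
                scenario.cohort,
                hi_target=targets["hi"],
                cr_target=targets["cancer_risk"],
                unit_mode=scenario.unit_mode,
            )
    except OleosafeError as exc:
        raise StageError("risk", exc) from exc

    try:
        compliance = tuple(evaluate_panel(quality_params, rules))
    except OleosafeError as exc:
        raise StageError("compliance", exc) from exc

    provenance = {
        "package_version": _version,
        "input_sha256": _input_hash(fa_profile, element_panel, limits, targets),
        "unit_mode": unit_mode.value,
        "hi_target": targets["hi"],
        "cr_target": targets["cancer_risk"],
    }
    return AnalysisReport(
        class_sums=sums,
        indices=indices,
        exceedances=exceed,
        risk=risk_results,
        safe_intakes=intakes,
        compliance=compliance,
        provenance=provenance,
    )
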