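"""Ingestion exposure chain: CDI → hazard quotient → hazard index → cancer risk.

The chronic daily intake of an element through oil consumption is

    CDI = C · IR · EF · ED / (BW · AT)

with C the concentration in oil (mg/kg), IR the oil ingestion rate (g/day),
EF the exposure frequency (days/year), ED the exposure duration (years),
BW body weight (kg) and AT the averaging time in days (ED · 365 by default,
so the EF·ED/AT prefactor cancels and CDI = C·IR/BW).

Unit modes
----------
``paper_faithful`` (default) keeps IR numerically in g/day with no g→kg
conversion, matching the convention used throughout the food-risk HQ/HI
literature this model follows; ``si_strict`` converts IR to kg/day, making
every CDI, HQ, HI and CR value exactly 1000-fold smaller.  The choice is a
reporting convention, not a model change — pick one and read RfD-relative
ratios consistently.

Downstream quantities:

* hazard quotient ``HQ = CDI / RfD`` per element (RfD: oral reference dose);
* hazard index ``HI = Σ HQ`` over the panel; HI < 1 is interpreted as safe
  consumption;
* cancer risk ``CR = CDI · SF`` per carcinogen (SF: slope factor), with the
  usual classification: CR < 1e-6 below the range of concern, 1e-6–1e-4
  acceptable, above 1e-4 inadmissible.

Because every quantity is linear in IR, the maximum safe intake for a target
HI (or target total CR) has the closed form IR* = target / (value at IR = 1);
:func:`safe_intake` takes the binding minimum of the two.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .elements import ElementPanel, LimitTable, MeasurementStatus
from .errors import DomainError, ValidationError

__all__ = [
    "UnitMode",
    "CensoredMode",
    "Cohort",
    "ExposureScenario",
    "CancerRiskClass",
    "RiskResult",
    "cdi",
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "classify_cancer_risk",
    "max_intake_for_hi",
    "max_intake_for_cr",
    "SafeIntakeResult",
    "safe_intake",
    "risk_grid",
]

DAYS_PER_YEAR = 365.0


class UnitMode(str, enum.Enum):
    PAPER_FAITHFUL = "paper"
    SI_STRICT = "si"


class CensoredMode(str, enum.Enum):
    """How below-LOD elements enter HI/CR: excluded, or substituted at LOD/2."""

    EXCLUDE = "exclude"
    HALF_LOD = "half_lod"


@dataclass(frozen=True)
class Cohort:
    """Exposed population stratum.

    ``averaging_time`` defaults to ED · 365 days, which cancels the
    EF·ED/AT prefactor of the CDI when EF is the full year.
    """

    label: str
    age_years: float
    body_weight: float
    exposure_duration: float = 70.0       # years
    exposure_frequency: float = DAYS_PER_YEAR  # days/year
    averaging_time: float | None = None   # days

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError(f"{self.label}: body weight must be positive")
        if not 0 < self.exposure_frequency <= DAYS_PER_YEAR:
            raise ValidationError(f"{self.label}: exposure frequency outside (0, 365]")
        if self.exposure_duration <= 0:
            raise ValidationError(f"{self.label}: exposure duration must be positive")
        if self.averaging_time is None:
            object.__setattr__(
                self, "averaging_time", self.exposure_duration * DAYS_PER_YEAR
            )
        elif self.averaging_time <= 0:
            raise ValidationError(f"{self.label}: averaging time must be positive")


@dataclass(frozen=True)
class ExposureScenario:
    """A cohort consuming oil at a given ingestion rate (g/day)."""

    cohort: Cohort
    ingestion_rate: float
    unit_mode: UnitMode = UnitMode.PAPER_FAITHFUL

    def __post_init__(self) -> None:
        if self.ingestion_rate < 0:
            raise ValidationError("ingestion rate must be non-negative")


class CancerRiskClass(str, enum.Enum):
    BELOW_RANGE = "below_range"
    ACCEPTABLE = "acceptable"
    INADMISSIBLE = "inadmissible"


def cdi(concentration: float, scenario: ExposureScenario) -> float:
    """Chronic daily intake, mg per kg body weight per day.

    ``concentration`` is mg element per kg oil.  In ``paper_faithful`` mode
    the ingestion rate enters numerically in g/day; ``si_strict`` converts
    it to kg/day first.
    """
    if concentration < 0:
        raise ValidationError("concentration must be non-negative")
    c = scenario.cohort
    if c.body_weight <= 0:
        raise DomainError("body weight must be positive")
    ir = scenario.ingestion_rate
    if scenario.unit_mode is UnitMode.SI_STRICT:
        ir = ir / 1000.0
    return (
        concentration
        * ir
        * c.exposure_frequency
        * c.exposure_duration
        / (c.body_weight * c.averaging_time)
    )


def hazard_quotient(cdi_value: float, rfd: float) -> float:
    """HQ = CDI / RfD."""
    if rfd <= 0:
        raise DomainError(f"reference dose must be positive, got {rfd}")
    return cdi_value / rfd


def cancer_risk(cdi_value: float, slope_factor: float) -> float:
    """CR = CDI · SF."""
    if slope_factor <= 0:
        raise DomainError(f"slope factor must be positive, got {slope_factor}")
    return cdi_value * slope_factor


def classify_cancer_risk(cr: float) -> CancerRiskClass:
    """Classify against the conventional acceptable range 1e-6–1e-4."""
    if cr < 1e-6:
        return CancerRiskClass.BELOW_RANGE
    if cr <= 1e-4:
        return CancerRiskClass.ACCEPTABLE
    return CancerRiskClass.INADMISSIBLE


@dataclass(frozen=True)
class RiskResult:
    """Full exposure-chain output for one scenario.

    ``excluded_no_rfd`` lists quantified elements skipped from HI because no
    RfD is available; ``censored`` lists elements skipped (or substituted)
    because they were never quantified.
    """

    scenario: ExposureScenario
    cdi: Mapping[str, float]
    hq: Mapping[str, float]
    hi: float
    hi_safe: bool
    cancer_risk: Mapping[str, float]
    cr_class: Mapping[str, CancerRiskClass]
    excluded_no_rfd: tuple[str, ...] = ()
    censored: tuple[str, ...] = ()


def _effective_concentrations(
    panel: ElementPanel, censored_mode: CensoredMode
) -> tuple[dict[str, float], tuple[str, ...]]:
    """Concentrations entering the chain, plus the censored symbols."""
    conc: dict[str, float] = {}
    censored: list[str] = []
    for m in panel:
        if m.quantified:
            conc[m.symbol] = m.concentration
        else:
            censored.append(m.symbol)
            if censored_mode is CensoredMode.HALF_LOD:
                conc[m.symbol] = m.lod / 2.0
    return conc, tuple(censored)


def hazard_index(
    panel: ElementPanel,
    limits: LimitTable,
    scenario: ExposureScenario,
    censored_mode: CensoredMode = CensoredMode.EXCLUDE,
) -> RiskResult:
    """Run the full CDI → HQ → HI (and CR) chain over a panel.

    HI sums HQ over every element with an RfD; elements lacking an RfD are
    recorded in ``excluded_no_rfd`` rather than silently dropped.  Censored
    elements contribute zero unless ``censored_mode`` substitutes LOD/2.
    """
    if len(panel) == 0:
        raise DomainError("empty element panel")
    conc, censored = _effective_concentrations(panel, censored_mode)
    if not conc:
        raise DomainError("no evaluable (quantified or substituted) elements in panel")

    cdi_map: dict[str, float] = {s: cdi(c, scenario) for s, c in conc.items()}
    hq_map: dict[str, float] = {}
    excluded: list[str] = []
    for symbol, d in cdi_map.items():
        rfd = limits.get(symbol).rfd
        if rfd is None:
            excluded.append(symbol)
        else:
            hq_map[symbol] = hazard_quotient(d, rfd)
    if not hq_map:
        raise DomainError("no element in panel has a reference dose")
    hi = sum(hq_map.values())

    cr_map: dict[str, float] = {}
    cr_cls: dict[str, CancerRiskClass] = {}
    for symbol, d in cdi_map.items():
        sf = limits.get(symbol).slope_factor
        if sf is not None:
            cr = cancer_risk(d, sf)
            cr_map[symbol] = cr
            cr_cls[symbol] = classify_cancer_risk(cr)

    return RiskResult(
        scenario=scenario,
        cdi=cdi_map,
        hq=hq_map,
        hi=hi,
        hi_safe=hi < 1.0,
        cancer_risk=cr_map,
        cr_class=cr_cls,
        excluded_no_rfd=tuple(excluded),
        censored=censored,
    )


def max_intake_for_hi(
    panel: ElementPanel,
    limits: LimitTable,
    cohort: Cohort,
    hi_target: float,
    unit_mode: UnitMode = UnitMode.PAPER_FAITHFUL,
    censored_mode: CensoredMode = CensoredMode.EXCLUDE,
) -> float:
    """Largest ingestion rate (g/day) whose hazard index equals ``hi_target``.

    HI is exactly linear in IR, so IR* = hi_target / HI(IR=1); with default
    EF/AT this is the closed form hi_target · BW / Σᵢ(Cᵢ/RfDᵢ).
    """
    if hi_target < 0:
        raise ValidationError("hi_target must be non-negative")
    if hi_target == 0:
        return 0.0
    unit = hazard_index(
        panel, limits, ExposureScenario(cohort, 1.0, unit_mode), censored_mode
    ).hi
    if unit <= 0:
        raise DomainError("hazard index is zero at unit intake; no finite solution")
    return hi_target / unit


def max_intake_for_cr(
    panel: ElementPanel,
    limits: LimitTable,
    cohort: Cohort,
    cr_target: float,
    unit_mode: UnitMode = UnitMode.PAPER_FAITHFUL,
    censored_mode: CensoredMode = CensoredMode.EXCLUDE,
) -> float:
    """Largest ingestion rate (g/day) with total cancer risk ``cr_target``.

    Total CR sums CDI·SF over carcinogens; IR* = cr_target / CR(IR=1).
    Returns ``inf`` when the panel contains no carcinogen (the constraint
    never binds).
    """
    if cr_target < 0:
        raise ValidationError("cr_target must be non-negative")
    if cr_target == 0:
        return 0.0
    conc, _ = _effective_concentrations(panel, censored_mode)
    scenario = ExposureScenario(cohort, 1.0, unit_mode)
    total = 0.0
    any_sf = False
    for symbol, c in conc.items():
        sf = limits.get(symbol).slope_factor
        if sf is not None:
            any_sf = True
            total += cancer_risk(cdi(c, scenario), sf)
    if not any_sf or total == 0.0:
        return math.inf
    return cr_target / total


@dataclass(frozen=True)
class SafeIntakeResult:
    """Combined safe intake with the constraint that binds."""

    intake_g_per_day: float
    binding_constraint: str          # "HI" or "CR"
    hi_limited: float
    cr_limited: float                # inf when no carcinogen present


def safe_intake(
    panel: ElementPanel,
    limits: LimitTable,
    cohort: Cohort,
    hi_target: float,
    cr_target: float,
    unit_mode: UnitMode = UnitMode.PAPER_FAITHFUL,
    censored_mode: CensoredMode = CensoredMode.EXCLUDE,
) -> SafeIntakeResult:
    """Minimum of the HI- and CR-constrained maximum intakes."""
    hi_ir = max_intake_for_hi(panel, limits, cohort, hi_target, unit_mode, censored_mode)
    cr_ir = max_intake_for_cr(panel, limits, cohort, cr_target, unit_mode, censored_mode)
    if cr_ir < hi_ir:
        return SafeIntakeResult(cr_ir, "CR", hi_ir, cr_ir)
    return SafeIntakeResult(hi_ir, "HI", hi_ir, cr_ir)


def risk_grid(
    results: Sequence[RiskResult],
    elements: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble results into a cohort × {CR, HQ} grid with a final HI column.

    Rows are (cohort label, index kind); columns are element symbols plus
    ``HI``.  Cells without a value (no slope factor, censored element) hold
    NaN, rendered as ``-`` by the CLI writer.
    """
    if elements is None:
        seen: list[str] = []
        for r in results:
            for s in list(r.hq) + list(r.cancer_risk):
                if s not in seen:
                    seen.append(s)
        elements = seen
    rows = []
    index = []
    for r in results:
        index.append((r.scenario.cohort.label, "CR"))
        rows.append([r.cancer_risk.get(s, math.nan) for s in elements] + [math.nan])
        index.append((r.scenario.cohort.label, "HQ"))
        rows.append([r.hq.get(s, math.nan) for s in elements] + [r.hi])
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["cohort", "index"]),
        columns=list(elements) + ["HI"],
    )
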