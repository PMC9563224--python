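"""Trace-element panels with detection-limit censoring and limit comparison.

An element panel holds per-element concentrations in mg per kg of oil, as
quantified by ICP OES, together with the instrument's limit of detection
(LOD) and limit of quantification (LOQ).  Raw readings are censored into
three states:

* ``below_lod`` — raw value under the LOD: the element was not detected;
* ``detected_below_loq`` — between LOD and LOQ: detected but not reliably
  quantifiable;
* ``quantified`` — at or above the LOQ.

Both boundaries are deterministic: the LOD interval is closed below
(raw == lod counts as detected) and the LOQ boundary is closed
(raw == loq counts as quantified).

Quantified concentrations are compared against regulatory concentration
limits (FAO/WHO, mg/kg) and — given an assumed daily oil intake — against
dietary reference intakes (DRI) / adequate intakes (AI, mg/day).  A spike
recovery check (acceptance window 80–110%, closed) covers the extraction QC.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .errors import DomainError, ValidationError

__all__ = [
    "MeasurementStatus",
    "ElementMeasurement",
    "ElementPanel",
    "ElementLimits",
    "LimitTable",
    "ExceedanceEntry",
    "RecoveryResult",
    "censor",
    "exceedance",
    "exceedance_report",
    "dri_intake_report",
    "recovery_check",
    "read_element_csv",
    "write_element_csv",
]


class MeasurementStatus(str, enum.Enum):
    QUANTIFIED = "quantified"
    DETECTED_BELOW_LOQ = "detected_below_loq"
    BELOW_LOD = "below_lod"


def censor(raw_value: float, lod: float, loq: float) -> MeasurementStatus:
    """Censoring status of a raw reading against the LOD/LOQ pair."""
    if raw_value < 0:
        raise ValidationError(f"negative raw value {raw_value}")
    if lod > loq:
        raise ValidationError(f"lod {lod} > loq {loq}")
    if raw_value < lod:
        return MeasurementStatus.BELOW_LOD
    if raw_value < loq:
        return MeasurementStatus.DETECTED_BELOW_LOQ
    return MeasurementStatus.QUANTIFIED


@dataclass(frozen=True)
class ElementMeasurement:
    """One element's concentration (mg/kg oil) with its censoring state.

    ``concentration`` is ``None`` for elements never observed above the LOD
    (reported as absent).
    """

    symbol: str
    concentration: float | None
    lod: float
    loq: float
    sd: float | None = None
    status: MeasurementStatus = MeasurementStatus.QUANTIFIED

    def __post_init__(self) -> None:
        if self.lod > self.loq:
            raise ValidationError(f"{self.symbol}: lod {self.lod} > loq {self.loq}")
        if self.concentration is not None:
            if self.concentration < 0:
                raise ValidationError(f"{self.symbol}: negative concentration")
            expected = censor(self.concentration, self.lod, self.loq)
            if expected is not self.status:
                raise ValidationError(
                    f"{self.symbol}: status {self.status.value} inconsistent with "
                    f"concentration {self.concentration} vs lod/loq"
                )
        elif self.status is MeasurementStatus.QUANTIFIED:
            raise ValidationError(f"{self.symbol}: quantified but no concentration")

    @classmethod
    def from_raw(
        cls,
        symbol: str,
        raw_value: float,
        lod: float,
        loq: float,
        sd: float | None = None,
    ) -> "ElementMeasurement":
        """Build a measurement, deriving the status from the raw reading."""
        return cls(
            symbol=symbol,
            concentration=raw_value,
            lod=lod,
            loq=loq,
            sd=sd,
            status=censor(raw_value, lod, loq),
        )

    @property
    def quantified(self) -> bool:
        return self.status is MeasurementStatus.QUANTIFIED


@dataclass(frozen=True)
class ElementPanel:
    """Collection of element measurements, indexable by symbol."""

    measurements: tuple[ElementMeasurement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        symbols = [m.symbol for m in self.measurements]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("duplicate element symbols in panel")

    def __iter__(self) -> Iterator[ElementMeasurement]:
        return iter(self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)

    def __getitem__(self, symbol: str) -> ElementMeasurement:
        for m in self.measurements:
            if m.symbol == symbol:
                return m
        raise KeyError(symbol)

    def quantified(self) -> tuple[ElementMeasurement, ...]:
        return tuple(m for m in self.measurements if m.quantified)


@dataclass(frozen=True)
class ElementLimits:
    """Reference values for one element; any field may be absent."""

    fao_who: float | None = None          # mg per kg oil
    dri_ai: Mapping[str, float] = field(default_factory=dict)  # mg/day by cohort
    rfd: float | None = None              # oral reference dose, mg/kg bw/day
    slope_factor: float | None = None     # cancer slope factor, (mg/kg/day)^-1
    provenance: str | None = None

    def __post_init__(self) -> None:
        for name in ("fao_who", "rfd", "slope_factor"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        for cohort, v in self.dri_ai.items():
            if v <= 0:
                raise ValidationError(f"dri_ai[{cohort}] must be positive, got {v}")


@dataclass(frozen=True)
class LimitTable:
    """Per-element regulatory/reference values."""

    elements: Mapping[str, ElementLimits]

    def __getitem__(self, symbol: str) -> ElementLimits:
        return self.elements[symbol]

    def get(self, symbol: str) -> ElementLimits:
        return self.elements.get(symbol, ElementLimits())

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping]) -> "LimitTable":
        elements = {}
        for symbol, entry in data.items():
            elements[symbol] = ElementLimits(
                fao_who=entry.get("fao_who"),
                dri_ai=dict(entry.get("dri_ai") or {}),
                rfd=entry.get("rfd"),
                slope_factor=entry.get("slope_factor"),
                provenance=entry.get("provenance"),
            )
        return cls(elements=elements)

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "LimitTable":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data.get("elements", data))


@dataclass(frozen=True)
class ExceedanceEntry:
    """Concentration expressed as percent of a limit."""

    symbol: str
    limit_source: str                 # "FAO/WHO" or "DRI/AI"
    evaluable: bool
    ratio_percent: float | None = None
    exceeds: bool | None = None
    limit: float | None = None


def exceedance(meas: ElementMeasurement, limit: float, limit_source: str = "FAO/WHO") -> ExceedanceEntry:
    """Percent-of-limit entry for one quantified measurement.

    Non-quantified measurements yield ``evaluable=False`` rather than a
    silent zero.  A concentration exactly at the limit is 100% and does not
    exceed.
    """
    if limit <= 0:
        raise ValidationError(f"{meas.symbol}: limit must be positive, got {limit}")
    if not meas.quantified:
        return ExceedanceEntry(meas.symbol, limit_source, evaluable=False, limit=limit)
    ratio = 100.0 * meas.concentration / limit
    return ExceedanceEntry(
        symbol=meas.symbol,
        limit_source=limit_source,
        evaluable=True,
        ratio_percent=ratio,
        exceeds=meas.concentration > limit,
        limit=limit,
    )


def exceedance_report(panel: ElementPanel, limits: LimitTable) -> dict[str, ExceedanceEntry]:
    """FAO/WHO exceedance entries for every panel element that has a limit."""
    report = {}
    for m in panel:
        lim = limits.get(m.symbol).fao_who
        if lim is not None:
            report[m.symbol] = exceedance(m, lim, "FAO/WHO")
    return report


def dri_intake_report(
    panel: ElementPanel,
    limits: LimitTable,
    dri_cohort: str,
    intake_g_per_day: float,
    si_units: bool = False,
) -> dict[str, ExceedanceEntry]:
    """Element intake at an assumed oil consumption vs DRI/AI (mg/day).

    A concentration (mg/kg) is commensurable with a DRI (mg/day) only through
    an intake assumption: element intake = C × IR.  By default IR enters
    numerically in g/day (the convention of the exposure model, see
    :mod:`oleosafe.risk`); with ``si_units=True`` it is converted to kg/day
    and intakes are 1000-fold smaller.
    """
    if intake_g_per_day < 0:
        raise ValidationError("intake must be non-negative")
    ir = intake_g_per_day / 1000.0 if si_units else intake_g_per_day
    report = {}
    for m in panel:
        dri = limits.get(m.symbol).dri_ai.get(dri_cohort)
        if dri is None:
            continue
        if not m.quantified:
            report[m.symbol] = ExceedanceEntry(m.symbol, "DRI/AI", evaluable=False, limit=dri)
            continue
        intake = m.concentration * ir
        report[m.symbol] = ExceedanceEntry(
            symbol=m.symbol,
            limit_source="DRI/AI",
            evaluable=True,
            ratio_percent=100.0 * intake / dri,
            exceeds=intake > dri,
            limit=dri,
        )
    return report


@dataclass(frozen=True)
class RecoveryResult:
    percent: float
    passed: bool


def recovery_check(
    spiked_found: float,
    spiked_added: float,
    low: float = 80.0,
    high: float = 110.0,
) -> RecoveryResult:
    """Spike recovery QC: pass iff found/added lies in [low, high] percent (closed).

    Boundaries tolerate floating-point rounding of the division (an exact
    110% recovery must not fail by one ulp).
    """
    if spiked_added <= 0:
        raise ValidationError("spiked_added must be positive")
    percent = 100.0 * spiked_found / spiked_added
    ok_low = percent >= low or math.isclose(percent, low, rel_tol=1e-12)
    ok_high = percent <= high or math.isclose(percent, high, rel_tol=1e-12)
    return RecoveryResult(percent=percent, passed=ok_low and ok_high)


# ---------------------------------------------------------------------------
# CSV I/O — columns: symbol, concentration, sd, lod, loq (header required);
# an empty concentration cell marks an element reported absent (below LOD).
# ---------------------------------------------------------------------------

def read_element_csv(source: str | IO[str]) -> ElementPanel:
    df = pd.read_csv(source)
    required = {"symbol", "concentration", "lod", "loq"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"element CSV missing columns: {sorted(missing)}")
    measurements = []
    for row in df.itertuples(index=False):
        sd = getattr(row, "sd", None)
        sd = None if sd is None or pd.isna(sd) else float(sd)
        lod, loq = float(row.lod), float(row.loq)
        if pd.isna(row.concentration):
            m = ElementMeasurement(
                symbol=str(row.symbol),
                concentration=None,
                lod=lod,
                loq=loq,
                sd=sd,
                status=MeasurementStatus.BELOW_LOD,
            )
        else:
            m = ElementMeasurement.from_raw(
                str(row.symbol), float(row.concentration), lod, loq, sd=sd
            )
        measurements.append(m)
    return ElementPanel(tuple(measurements))


def write_element_csv(panel: ElementPanel, target: str | IO[str]) -> None:
    df = pd.DataFrame(
        {
            "symbol": [m.symbol for m in panel],
            "concentration": [m.concentration for m in panel],
            "sd": [m.sd for m in panel],
            "lod": [m.lod for m in panel],
            "loq": [m.loq for m in panel],
            "status": [m.status.value for m in panel],
        }
    )
    df.to_csv(target, index=False)
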