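"""Codex-style compliance checks for oil identity/quality parameters.

Each rule is either a maximum (pass iff measured ≤ max) or a closed range
(pass iff low ≤ measured ≤ high).  Boundary values pass, matching how the
limits are printed ("≤ 20", "118–141").  The reported margin is the signed
distance to the nearest violated-able bound: positive inside the allowed
region, negative outside.

The measurement SD is carried for reporting; by default it does not change
the verdict (point-value comparison).  ``strict=True`` additionally fails a
parameter whose measured ± sd interval straddles a bound.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import UnitMismatchError, ValidationError

__all__ = [
    "RuleKind",
    "ParameterRule",
    "ComplianceEntry",
    "check_parameter",
    "evaluate_panel",
    "read_rules_yaml",
    "read_parameters_csv",
]


class RuleKind(str, enum.Enum):
    MAXIMUM = "maximum"
    RANGE = "range"


@dataclass(frozen=True)
class ParameterRule:
    name: str
    kind: RuleKind
    units: str
    max_value: float | None = None
    low: float | None = None
    high: float | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.kind is RuleKind.MAXIMUM:
            if self.max_value is None or self.max_value <= 0:
                raise ValidationError(f"{self.name}: maximum rule needs max_value > 0")
        else:
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValidationError(f"{self.name}: range rule needs low < high")


@dataclass(frozen=True)
class ComplianceEntry:
    name: str
    measured: float
    sd: float | None
    units: str
    verdict: str                  # "pass" or "fail"
    margin: float                 # signed distance to the nearest bound

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def check_parameter(
    measured: float,
    rule: ParameterRule,
    sd: float | None = None,
    units: str | None = None,
    strict: bool = False,
) -> ComplianceEntry:
    """Evaluate one measured parameter against its rule.

    ``units``, when given, must equal the rule's unit string exactly.
    """
    if units is not None and units != rule.units:
        raise UnitMismatchError(
            f"{rule.name}: measured in {units!r} but rule in {rule.units!r}"
        )
    if rule.kind is RuleKind.MAXIMUM:
        margin = rule.max_value - measured
        ok = measured <= rule.max_value
        if strict and sd:
            ok = ok and measured + sd <= rule.max_value
    else:
        margin = min(measured - rule.low, rule.high - measured)
        ok = rule.low <= measured <= rule.high
        if strict and sd:
            ok = ok and (rule.low <= measured - sd) and (measured + sd <= rule.high)
    return ComplianceEntry(
        name=rule.name,
        measured=measured,
        sd=sd,
        units=rule.units,
        verdict="pass" if ok else "fail",
        margin=margin,
    )


def evaluate_panel(
    measured: pd.DataFrame,
    rules: Mapping[str, ParameterRule],
    strict: bool = False,
) -> list[ComplianceEntry]:
    """Evaluate a table of measured parameters (columns: name, value, sd, units)."""
    entries = []
    for row in measured.itertuples(index=False):
        name = str(row.name)
        if name not in rules:
            raise ValidationError(f"no rule for parameter {name!r}")
        sd = getattr(row, "sd", None)
        sd = None if sd is None or pd.isna(sd) else float(sd)
        units = getattr(row, "units", None)
        units = None if units is None or pd.isna(units) else str(units)
        entries.append(
            check_parameter(float(row.value), rules[name], sd=sd, units=units, strict=strict)
        )
    return entries


def read_rules_yaml(source: str | IO[str]) -> dict[str, ParameterRule]:
    """Load rules from structured config.

    Each entry: ``{kind: maximum|range, units: ..., max: ...}`` or
    ``{kind: range, low: ..., high: ...}``; optional ``provenance``.
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    data = data.get("parameters", data)
    rules = {}
    for name, entry in data.items():
        kind = RuleKind(entry["kind"])
        rules[name] = ParameterRule(
            name=name,
            kind=kind,
            units=str(entry.get("units", "")),
            max_value=entry.get("max"),
            low=entry.get("low"),
            high=entry.get("high"),
            provenance=entry.get("provenance"),
        )
    return rules


def read_parameters_csv(source: str | IO[str]) -> pd.DataFrame:
    df = pd.read_csv(source)
    missing = {"name", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"parameter CSV missing columns: {sorted(missing)}")
    return df
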