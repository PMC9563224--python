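"""Fatty-acid profiles and nutritional-quality indices.

A fatty-acid profile is the percent composition of an oil as reported by
GC-FID of the methyl esters, with each species named by the common shorthand
``C<chain>:<double bonds>[n<omega family>][c|t]`` (``n`` and the Greek ``ω``
are interchangeable; the trailing ``c``/``t`` marks cis/trans geometry).
From a profile this module computes the saturation-class sums (SFA, MUFA,
PUFA, total unsaturated, ω3, ω6) and the three standard lipid-quality
indices:

* atherogenicity index ``AI = (C12:0 + 4·C14:0 + C16:0) / (ΣMUFA + ΣPUFA)``
* thrombogenicity index
  ``TI = (C14:0 + C16:0 + C18:0) / (0.5·ΣMUFA + 0.5·Σω6 + 3·Σω3)``
* hypocholesterolemic/hypercholesterolemic ratio
  ``HH = (C18:1ω9 + C18:2ω6 + C20:4ω6 + C18:3ω3 + C20:5ω3 + C22:5ω3 + C22:6ω3)
  / (C14:0 + C16:0)``

Species absent from a profile contribute zero to every index, so the indices
are always computable from whatever subset of species an instrument reports.
Lower AI/TI and higher HH indicate a nutritionally more favourable oil.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import (
    DomainError,
    MissingSpeciesError,
    ShorthandParseError,
    ValidationError,
)

__all__ = [
    "SaturationClass",
    "Shorthand",
    "FattyAcidSpecies",
    "FattyAcidProfile",
    "ClassSums",
    "DEFAULT_FAMILY_OVERRIDES",
    "parse_fa_shorthand",
    "format_fa_shorthand",
    "classify_species",
    "class_sums",
    "atherogenicity_index",
    "thrombogenicity_index",
    "hh_ratio",
    "species_ratio",
    "read_fa_csv",
    "write_fa_csv",
]

_SHORTHAND_RE = re.compile(r"^[Cc]\s*(\d+):(\d+)(?:[nNω](\d))?([cCtT])?$")

#: ω-family assignments for species whose printed shorthand carries no family
#: tag.  Only n3/n6 membership enters the thrombogenicity denominator; the
#: docosadienoic→n6 assignment shifts TI by well under 0.001 on typical seed
#: oils.  Callers may override any entry via the ``family_overrides`` argument
#: of :func:`class_sums` and the index functions.
DEFAULT_FAMILY_OVERRIDES: Mapping[str, str] = {
    "C16:1": "n7",   # palmitoleic
    "C20:1": "n9",   # gondoic
    "C22:2": "n6",   # docosadienoic
}


class SaturationClass(str, enum.Enum):
    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"


class Shorthand(NamedTuple):
    """Structural content of a shorthand token."""

    chain_length: int
    double_bonds: int
    omega_family: str | None
    geometry: str | None


def parse_fa_shorthand(token: str) -> Shorthand:
    """Parse ``C<chain>:<db>[n<family>][c|t]`` into its structural fields.

    Case-insensitive; accepts ``ω`` in place of ``n``.  Saturated species
    (zero double bonds) may not carry a family tag or geometry suffix.

    Raises
    ------
    ShorthandParseError
        If the token does not match the grammar.
    ValidationError
        If the fields are structurally impossible (chain < 4,
        double bonds ≥ chain, family/geometry on a saturated species).
    """
    m = _SHORTHAND_RE.match(token.strip())
    if m is None:
        raise ShorthandParseError(f"malformed fatty-acid shorthand: {token!r}")
    chain = int(m.group(1))
    db = int(m.group(2))
    family = f"n{m.group(3)}" if m.group(3) else None
    geometry = {"c": "cis", "t": "trans"}[m.group(4).lower()] if m.group(4) else None
    if chain < 4:
        raise ValidationError(f"{token!r}: chain length {chain} < 4")
    if db >= chain:
        raise ValidationError(f"{token!r}: {db} double bonds on a C{chain} chain")
    if db == 0 and (family is not None or geometry is not None):
        raise ValidationError(f"{token!r}: saturated species cannot carry a family or geometry tag")
    return Shorthand(chain, db, family, geometry)


def format_fa_shorthand(
    chain_length: int,
    double_bonds: int,
    omega_family: str | None = None,
    geometry: str | None = None,
) -> str:
    """Canonical shorthand; inverse of :func:`parse_fa_shorthand`."""
    suffix = {"cis": "c", "trans": "t", None: ""}[geometry]
    return f"C{chain_length}:{double_bonds}{omega_family or ''}{suffix}"


@dataclass(frozen=True)
class FattyAcidSpecies:
    """One fatty acid: identity plus its percent of total fatty acids."""

    common_name: str
    shorthand: str
    chain_length: int
    double_bonds: int
    omega_family: str | None
    geometry: str | None
    percent: float
    percent_sd: float | None = None

    def __post_init__(self) -> None:
        if self.chain_length < 4:
            raise ValidationError(f"{self.shorthand}: chain length {self.chain_length} < 4")
        if not 0 <= self.double_bonds < self.chain_length:
            raise ValidationError(
                f"{self.shorthand}: double bonds {self.double_bonds} out of range"
            )
        if self.percent < 0:
            raise ValidationError(f"{self.shorthand}: negative percent {self.percent}")

    @classmethod
    def from_shorthand(
        cls,
        shorthand: str,
        percent: float,
        common_name: str | None = None,
        percent_sd: float | None = None,
    ) -> "FattyAcidSpecies":
        s = parse_fa_shorthand(shorthand)
        return cls(
            common_name=common_name or shorthand,
            shorthand=format_fa_shorthand(*s),
            chain_length=s.chain_length,
            double_bonds=s.double_bonds,
            omega_family=s.omega_family,
            geometry=s.geometry,
            percent=percent,
            percent_sd=percent_sd,
        )


@dataclass(frozen=True)
class FattyAcidProfile:
    """Ordered, uniquely named fatty-acid composition of one oil.

    ``check_total`` enforces that the percents sum to 100 within
    ``total_tolerance`` (printed tables round each row, so exactly 100 is
    unattainable).  Disable it for partial or rescaled profiles.
    """

    species: tuple[FattyAcidSpecies, ...]
    total_tolerance: float = 0.5
    check_total: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        seen = [sp.shorthand for sp in self.species]
        if len(set(seen)) != len(seen):
            dupes = sorted({s for s in seen if seen.count(s) > 1})
            raise ValidationError(f"duplicate species shorthands: {dupes}")
        if self.check_total and self.species:
            total = self.total_percent
            if abs(total - 100.0) > self.total_tolerance:
                raise ValidationError(
                    f"profile total {total:.3f}% outside 100 ± {self.total_tolerance}"
                )

    @property
    def total_percent(self) -> float:
        return sum(sp.percent for sp in self.species)

    def get(self, shorthand: str) -> FattyAcidSpecies:
        """Look up a species by shorthand (normalised through the parser)."""
        key = format_fa_shorthand(*parse_fa_shorthand(shorthand))
        for sp in self.species:
            if sp.shorthand == key:
                return sp
        raise MissingSpeciesError(f"species {key!r} not in profile")

    def scaled(self, k: float) -> "FattyAcidProfile":
        """Every percent multiplied by ``k`` (total check disabled)."""
        return FattyAcidProfile(
            tuple(replace(sp, percent=sp.percent * k) for sp in self.species),
            check_total=False,
        )


@dataclass(frozen=True)
class ClassSums:
    """Percent sums by saturation class and ω family.

    ``ufa = mufa + pufa`` holds exactly by construction.
    """

    sfa: float
    mufa: float
    pufa: float
    omega3: float
    omega6: float

    @property
    def ufa(self) -> float:
        return self.mufa + self.pufa


def classify_species(sp: FattyAcidSpecies) -> SaturationClass:
    """Saturation class from the double-bond count (0 → SFA, 1 → MUFA, ≥2 → PUFA)."""
    if sp.double_bonds == 0:
        return SaturationClass.SFA
    if sp.double_bonds == 1:
        return SaturationClass.MUFA
    return SaturationClass.PUFA


def _effective_family(
    sp: FattyAcidSpecies, overrides: Mapping[str, str]
) -> str | None:
    if sp.omega_family is not None:
        return sp.omega_family
    # overrides are keyed by the bare shorthand (no geometry suffix)
    bare = format_fa_shorthand(sp.chain_length, sp.double_bonds)
    return overrides.get(sp.shorthand, overrides.get(bare))


def class_sums(
    profile: FattyAcidProfile,
    family_overrides: Mapping[str, str] = DEFAULT_FAMILY_OVERRIDES,
) -> ClassSums:
    """Sum percents by saturation class and by ω3/ω6 membership.

    ``family_overrides`` assigns ω families to species whose shorthand lacks
    a tag (see :data:`DEFAULT_FAMILY_OVERRIDES`).
    """
    sfa = mufa = pufa = omega3 = omega6 = 0.0
    for sp in profile.species:
        cls = classify_species(sp)
        if cls is SaturationClass.SFA:
            sfa += sp.percent
        elif cls is SaturationClass.MUFA:
            mufa += sp.percent
        else:
            pufa += sp.percent
        fam = _effective_family(sp, family_overrides)
        if fam == "n3":
            omega3 += sp.percent
        elif fam == "n6":
            omega6 += sp.percent
    return ClassSums(sfa=sfa, mufa=mufa, pufa=pufa, omega3=omega3, omega6=omega6)


def _percent_sum(
    profile: FattyAcidProfile,
    chain: int,
    db: int,
    family: str | None = None,
    overrides: Mapping[str, str] = DEFAULT_FAMILY_OVERRIDES,
) -> float:
    """Summed percent of species matching chain/db (and family, if given)."""
    total = 0.0
    for sp in profile.species:
        if sp.chain_length != chain or sp.double_bonds != db:
            continue
        if family is not None and _effective_family(sp, overrides) != family:
            continue
        total += sp.percent
    return total


def atherogenicity_index(
    profile: FattyAcidProfile,
    family_overrides: Mapping[str, str] = DEFAULT_FAMILY_OVERRIDES,
) -> float:
    """AI = (C12:0 + 4·C14:0 + C16:0) / (ΣMUFA + ΣPUFA); absent species count 0."""
    cs = class_sums(profile, family_overrides)
    den = cs.mufa + cs.pufa
    if den <= 0:
        raise DomainError("atherogenicity index undefined: ΣMUFA + ΣPUFA is zero")
    num = (
        _percent_sum(profile, 12, 0)
        + 4.0 * _percent_sum(profile, 14, 0)
        + _percent_sum(profile, 16, 0)
    )
    return num / den


def thrombogenicity_index(
    profile: FattyAcidProfile,
    family_overrides: Mapping[str, str] = DEFAULT_FAMILY_OVERRIDES,
) -> float:
    """TI = (C14:0 + C16:0 + C18:0) / (0.5·ΣMUFA + 0.5·Σω6 + 3·Σω3)."""
    cs = class_sums(profile, family_overrides)
    den = 0.5 * cs.mufa + 0.5 * cs.omega6 + 3.0 * cs.omega3
    if den <= 0:
        raise DomainError("thrombogenicity index undefined: denominator is zero")
    num = (
        _percent_sum(profile, 14, 0)
        + _percent_sum(profile, 16, 0)
        + _percent_sum(profile, 18, 0)
    )
    return num / den


_HH_NUMERATOR = (
    (18, 1, "n9"),
    (18, 2, "n6"),
    (20, 4, "n6"),
    (18, 3, "n3"),
    (20, 5, "n3"),
    (22, 5, "n3"),
    (22, 6, "n3"),
)


def hh_ratio(
    profile: FattyAcidProfile,
    family_overrides: Mapping[str, str] = DEFAULT_FAMILY_OVERRIDES,
) -> float:
    """Hypocholesterolemic/hypercholesterolemic ratio.

    Seven named unsaturated species (oleic, linoleic, arachidonic,
    α-linolenic, EPA, DPA, DHA) over C14:0 + C16:0.
    """
    den = _percent_sum(profile, 14, 0) + _percent_sum(profile, 16, 0)
    if den <= 0:
        raise DomainError("HH ratio undefined: C14:0 + C16:0 is zero")
    num = sum(
        _percent_sum(profile, c, d, fam, family_overrides) for c, d, fam in _HH_NUMERATOR
    )
    return num / den


def species_ratio(profile: FattyAcidProfile, a: str, b: str) -> float:
    """percent(a) / percent(b), both looked up by shorthand."""
    pa = profile.get(a).percent
    pb = profile.get(b).percent
    if pb <= 0:
        raise DomainError(f"species_ratio: percent of {b!r} is not positive")
    return pa / pb


# ---------------------------------------------------------------------------
# CSV I/O — columns: name, shorthand, percent, percent_sd (header required)
# ---------------------------------------------------------------------------

def read_fa_csv(
    source: str | IO[str],
    total_tolerance: float = 0.5,
    check_total: bool = True,
) -> FattyAcidProfile:
    """Read a fatty-acid composition table.

    Expected UTF-8 CSV columns: ``name, shorthand, percent`` and optionally
    ``percent_sd``.  Shorthands may use ``n`` or ``ω`` for the family marker.
    """
    df = pd.read_csv(source)
    required = {"name", "shorthand", "percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"fatty-acid CSV missing columns: {sorted(missing)}")
    species = []
    for row in df.itertuples(index=False):
        sd = getattr(row, "percent_sd", None)
        sd = None if sd is None or pd.isna(sd) else float(sd)
        species.append(
            FattyAcidSpecies.from_shorthand(
                str(row.shorthand),
                float(row.percent),
                common_name=str(row.name),
                percent_sd=sd,
            )
        )
    return FattyAcidProfile(
        tuple(species), total_tolerance=total_tolerance, check_total=check_total
    )


def write_fa_csv(profile: FattyAcidProfile, target: str | IO[str]) -> None:
    df = pd.DataFrame(
        {
            "name": [sp.common_name for sp in profile.species],
            "shorthand": [sp.shorthand for sp in profile.species],
            "percent": [sp.percent for sp in profile.species],
            "percent_sd": [sp.percent_sd for sp in profile.species],
        }
    )
    df.to_csv(target, index=False)
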