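"""Seeded synthetic data with the statistical structure the analysis assumes.

Fatty-acid profiles are compositional: percents are non-negative and sum to
100.  The generator draws them from a gamma-simplex (Dirichlet-type)
distribution centred on a template profile — independent gammas with shape
``mean_i / dispersion`` renormalised to 100 — so ``fa_dispersion → 0``
degenerates to the template exactly.  The default dispersion (0.01) gives
per-species spreads of the same order as replicate GC-FID standard
deviations (a few tenths of a percent absolute for the major species).

Element concentrations are drawn from a normal truncated at zero around the
template mean ± SD (printed SDs are small relative to means, so truncation
is negligible); with probability ``censor_fraction`` an element is instead
pushed below its LOD to exercise the censoring path.

Everything is driven by one integer seed through ``numpy.random.default_rng``;
equal seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datasets import (
    load_reference_cohorts,
    load_reference_element_panel,
    load_reference_fa_profile,
)
from .elements import ElementMeasurement, ElementPanel, MeasurementStatus
from .errors import ValidationError
from .fatty_acids import FattyAcidProfile
from .risk import Cohort, ExposureScenario, UnitMode

__all__ = [
    "GeneratorConfig",
    "gen_fa_profile",
    "gen_fa_profiles",
    "gen_element_panel",
    "gen_element_panels",
    "gen_scenario_grid",
]

DEFAULT_INTAKES: tuple[float, ...] = (0.61, 1.46, 1.65)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic generator; defaults emulate the bundled dataset."""

    seed: int = 0
    n_samples: int = 1
    fa_template: FattyAcidProfile = field(default_factory=load_reference_fa_profile)
    fa_dispersion: float = 0.01
    element_template: ElementPanel = field(default_factory=load_reference_element_panel)
    element_sd_scale: float = 1.0
    censor_fraction: float = 0.0
    cohorts: tuple[Cohort, ...] = field(
        default_factory=lambda: tuple(load_reference_cohorts())
    )
    intakes: tuple[float, ...] = DEFAULT_INTAKES
    unit_mode: UnitMode = UnitMode.PAPER_FAITHFUL

    def __post_init__(self) -> None:
        if self.fa_dispersion < 0:
            raise ValidationError("fa_dispersion must be non-negative")
        if self.element_sd_scale < 0:
            raise ValidationError("element_sd_scale must be non-negative")
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ValidationError("censor_fraction must lie in [0, 1]")
        if self.n_samples < 0:
            raise ValidationError("n_samples must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_fa_profile(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> FattyAcidProfile:
    """One compositional draw centred on the template percents."""
    rng = config.rng() if rng is None else rng
    template = config.fa_template
    means = np.array([sp.percent for sp in template.species], dtype=float)
    if config.fa_dispersion == 0.0:
        percents = means / means.sum() * 100.0
    else:
        shape = means / config.fa_dispersion
        draws = rng.gamma(shape)
        percents = draws / draws.sum() * 100.0
    species = tuple(
        replace(sp, percent=float(p), percent_sd=None)
        for sp, p in zip(template.species, percents)
    )
    return FattyAcidProfile(species, check_total=True)


def gen_fa_profiles(config: GeneratorConfig) -> list[FattyAcidProfile]:
    """``n_samples`` profiles from one seeded stream."""
    rng = config.rng()
    return [gen_fa_profile(config, rng) for _ in range(config.n_samples)]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) conditioned on ≥ 0 by rejection (sd ≪ mean in practice)."""
    if sd == 0.0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return float(x)
    return 0.0  # pathological sd/mean ratio; mass at the truncation point


def gen_element_panel(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> ElementPanel:
    """One noisy panel; template non-detects stay censored.

    With probability ``censor_fraction`` a quantified element is replaced by
    a uniform sub-LOD value and flagged ``below_lod``.
    """
    rng = config.rng() if rng is None else rng
    measurements = []
    for m in config.element_template:
        if not m.quantified:
            measurements.append(m)
            continue
        if rng.uniform() < config.censor_fraction:
            raw = float(rng.uniform(0.0, m.lod)) if m.lod > 0 else 0.0
            measurements.append(
                ElementMeasurement(
                    symbol=m.symbol,
                    concentration=raw,
                    lod=m.lod,
                    loq=m.loq,
                    sd=None,
                    status=MeasurementStatus.BELOW_LOD,
                )
            )
        else:
            raw = _truncated_normal(
                rng, m.concentration, (m.sd or 0.0) * config.element_sd_scale
            )
            measurements.append(
                ElementMeasurement.from_raw(m.symbol, raw, m.lod, m.loq)
            )
    return ElementPanel(tuple(measurements))


def gen_element_panels(config: GeneratorConfig) -> list[ElementPanel]:
    rng = config.rng()
    return [gen_element_panel(config, rng) for _ in range(config.n_samples)]


def gen_scenario_grid(config: GeneratorConfig) -> list[ExposureScenario]:
    """Cross product of cohorts × ingestion rates, cohort order preserved."""
    return [
        ExposureScenario(cohort, float(ir), config.unit_mode)
        for cohort in config.cohorts
        for ir in config.intakes
    ]
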