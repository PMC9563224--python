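from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from oleosafe.datasets import (
    load_default_limits,
    load_reference_cohorts,
    load_reference_element_panel,
    load_reference_fa_profile,
    load_reference_scenarios,
)
from oleosafe.elements import ElementLimits, ElementMeasurement, ElementPanel, LimitTable
from oleosafe.fatty_acids import FattyAcidProfile, FattyAcidSpecies, format_fa_shorthand

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=75,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_profile() -> FattyAcidProfile:
    return load_reference_fa_profile()


@pytest.fixture(scope="session")
def reference_panel():
    return load_reference_element_panel()


@pytest.fixture(scope="session")
def limits():
    return load_default_limits()


@pytest.fixture(scope="session")
def cohorts():
    return load_reference_cohorts()


@pytest.fixture(scope="session")
def scenarios():
    return load_reference_scenarios()


# ---------------------------------------------------------------------------
# hypothesis strategies
# ---------------------------------------------------------------------------

@st.composite
def shorthands(draw) -> str:
    """Valid shorthand tokens covering the whole grammar."""
    chain = draw(st.integers(min_value=4, max_value=26))
    db = draw(st.integers(min_value=0, max_value=min(6, chain - 1)))
    family = None
    geometry = None
    if db > 0:
        family = draw(st.sampled_from([None, "n3", "n6", "n7", "n9"]))
        geometry = draw(st.sampled_from([None, "cis", "trans"]))
    return format_fa_shorthand(chain, db, family, geometry)


@st.composite
def fa_profiles(draw, min_species: int = 1, max_species: int = 8) -> FattyAcidProfile:
    """Random partial profiles (total-percent check disabled)."""
    tokens = draw(
        st.lists(shorthands(), min_size=min_species, max_size=max_species, unique=True)
    )
    species = []
    for tok in tokens:
        pct = draw(
            st.floats(min_value=0.0, max_value=60.0, allow_nan=False, allow_subnormal=False)
        )
        species.append(FattyAcidSpecies.from_shorthand(tok, pct))
    return FattyAcidProfile(tuple(species), check_total=False)


_SYMBOLS = ["Al", "Cr", "Cu", "Fe", "Mn", "Zn", "Ni", "Pb"]


@st.composite
def element_panels(draw, min_elements: int = 1, max_elements: int = 6):
    symbols = draw(
        st.lists(st.sampled_from(_SYMBOLS), min_size=min_elements, max_size=max_elements, unique=True)
    )
    measurements = []
    for s in symbols:
        conc = draw(st.floats(min_value=0.01, max_value=50.0, allow_nan=False))
        measurements.append(ElementMeasurement.from_raw(s, conc, lod=0.001, loq=0.005))
    return ElementPanel(tuple(measurements))


@st.composite
def limit_tables(draw, panel: ElementPanel | None = None, symbols=None):
    symbols = symbols if symbols is not None else _SYMBOLS
    elements = {}
    for s in symbols:
        rfd = draw(st.floats(min_value=1e-3, max_value=2.0, allow_nan=False))
        sf = draw(st.sampled_from([None, 0.5, 1.5]))
        elements[s] = ElementLimits(rfd=rfd, slope_factor=sf)
    return LimitTable(elements=elements)
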