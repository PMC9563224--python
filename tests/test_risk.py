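"""Exposure chain (CDI/HQ/HI/CR), unit modes and inverse safe-intake solvers."""

from __future__ import annotations

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oleosafe.elements import ElementLimits, ElementMeasurement, ElementPanel, LimitTable
from oleosafe.errors import DomainError, ValidationError
from oleosafe.risk import (
    CancerRiskClass,
    CensoredMode,
    Cohort,
    ExposureScenario,
    UnitMode,
    cancer_risk,
    cdi,
    classify_cancer_risk,
    hazard_index,
    hazard_quotient,
    max_intake_for_cr,
    max_intake_for_hi,
    risk_grid,
    safe_intake,
)
from oleosafe.rounding import round_dp, round_sig

from conftest import element_panels, limit_tables


def _scenario(bw: float, ir: float, mode=UnitMode.PAPER_FAITHFUL) -> ExposureScenario:
    return ExposureScenario(Cohort(label=f"bw{bw}", age_years=30, body_weight=bw), ir, mode)


# ---------------------------------------------------------------------------
# CDI
# ---------------------------------------------------------------------------

def test_cdi_reference_value():
    assert cdi(0.0242, _scenario(26, 0.61)) == pytest.approx(0.0242 * 0.61 / 26, rel=1e-12)


def test_cdi_zero_intake():
    assert cdi(5.0, _scenario(26, 0.0)) == 0.0


def test_cdi_si_strict_is_thousandth():
    paper = cdi(0.0242, _scenario(26, 0.61))
    si = cdi(0.0242, _scenario(26, 0.61, UnitMode.SI_STRICT))
    assert si == pytest.approx(paper / 1000.0, rel=1e-15)


def test_cdi_prefactor_cancels_with_defaults():
    """With EF = 365 and AT = ED·365 the CDI reduces to C·IR/BW for any ED."""
    short = ExposureScenario(Cohort("a", 8, 26, exposure_duration=6), 0.61)
    long = ExposureScenario(Cohort("b", 8, 26, exposure_duration=70), 0.61)
    assert cdi(1.0, short) == pytest.approx(cdi(1.0, long), rel=1e-15)


def test_cohort_validation():
    with pytest.raises(ValidationError):
        Cohort("bad", 8, body_weight=0)
    with pytest.raises(ValidationError):
        Cohort("bad", 8, 26, exposure_frequency=400)


# ---------------------------------------------------------------------------
# forward chain against the printed reproduction grid
# ---------------------------------------------------------------------------

# (cohort label, element) -> HQ as printed, 4-5 decimals
PRINTED_HQ = {
    ("8y", "Cr"): 0.18926,
    ("8y", "Cu"): 0.1637,
    ("8y", "Fe"): 0.05576,
    ("8y", "Mn"): 0.03975,
    ("8y", "Zn"): 0.51794,
    ("8y", "Al"): 0.0244,
    ("18y", "Cr"): 0.18996,
    ("18y", "Cu"): 0.16431,
    ("18y", "Fe"): 0.05597,
    ("18y", "Mn"): 0.0399,
    ("18y", "Zn"): 0.51985,
    ("18y", "Al"): 0.02449,
    ("30y", "Cr"): 0.19014,
    ("30y", "Cu"): 0.16447,
    ("30y", "Fe"): 0.05602,
    ("30y", "Mn"): 0.03994,
    ("30y", "Zn"): 0.52036,
    ("30y", "Al"): 0.02452,
}


@pytest.fixture(scope="module")
def reference_results(reference_panel, limits, scenarios):
    return {s.cohort.label: hazard_index(reference_panel, limits, s) for s in scenarios}


@pytest.mark.parametrize("key", sorted(PRINTED_HQ), ids=lambda k: f"{k[0]}-{k[1]}")
def test_hq_cells_match_printed_grid(reference_results, key):
    """Each of the eighteen HQ cells matches the reference grid at its
    printed precision (4-5 decimals)."""
    label, symbol = key
    printed = PRINTED_HQ[key]
    dp = len(str(printed).split(".")[1])
    assert round_dp(reference_results[label].hq[symbol], dp) == pytest.approx(printed)


def test_hi_at_8y(reference_results):
    r = reference_results["8y"]
    assert round_dp(r.hi, 2) == 0.99
    assert r.hi == pytest.approx(sum(r.hq.values()), rel=1e-15)
    assert r.hi_safe


def test_hi_all_cohorts_safe_and_truncate_to_099(reference_results):
    """Every cohort's HI is below 1; the first two decimals are 0.99 (the
    reference grid's HI column truncates rather than rounds: the 30-y sum of
    its own HQ cells is 0.99545)."""
    for r in reference_results.values():
        assert r.hi_safe
        assert math.floor(r.hi * 100) / 100 == 0.99


def test_cancer_risk_cells(reference_results):
    """Cr is the only carcinogen; the 8-y and 30-y cells match at 2 s.f., the
    18-y computed value (2.849e-4) sits within one ulp of the printed grid."""
    assert round_sig(reference_results["8y"].cancer_risk["Cr"], 2) == pytest.approx(2.8e-4)
    assert round_sig(reference_results["30y"].cancer_risk["Cr"], 2) == pytest.approx(2.9e-4)
    assert reference_results["18y"].cancer_risk["Cr"] == pytest.approx(2.9e-4, abs=0.1e-4)
    for r in reference_results.values():
        assert set(r.cancer_risk) == {"Cr"}
        assert r.cr_class["Cr"] is CancerRiskClass.INADMISSIBLE


def test_censored_elements_recorded_not_summed(reference_results):
    r = reference_results["8y"]
    assert set(r.censored) == {"As", "Cd", "Co", "Ni", "Pb", "Se", "Mg"}
    assert set(r.hq) == {"Al", "Cr", "Cu", "Fe", "Mn", "Zn"}


def test_half_lod_substitution_raises_hi(reference_panel, limits, scenarios):
    base = hazard_index(reference_panel, limits, scenarios[0])
    # give the censored elements an RfD so substitution has something to add
    elements = dict(limits.elements)
    elements["Pb"] = ElementLimits(rfd=0.004)
    sub = hazard_index(
        reference_panel, LimitTable(elements), scenarios[0], CensoredMode.HALF_LOD
    )
    assert sub.hi > base.hi
    assert sub.hq["Pb"] == pytest.approx((0.007 / 2) * 0.61 / 26 / 0.004, rel=1e-12)


def test_hazard_quotient_and_exclusions():
    assert hazard_quotient(0.3, 0.1) == pytest.approx(3.0)
    with pytest.raises(DomainError):
        hazard_quotient(0.3, 0.0)


def test_missing_rfd_is_excluded_not_zero(limits):
    panel = ElementPanel(
        (
            ElementMeasurement.from_raw("Zn", 1.0, 0.0018, 0.006),
            ElementMeasurement.from_raw("Pb", 1.0, 0.007, 0.0233),  # no RfD in table
        )
    )
    r = hazard_index(panel, limits, _scenario(26, 1.0))
    assert r.excluded_no_rfd == ("Pb",)
    assert "Pb" not in r.hq


def test_single_element_panel_hi_is_hq(limits):
    panel = ElementPanel((ElementMeasurement.from_raw("Zn", 6.6228, 0.0018, 0.006),))
    r = hazard_index(panel, limits, _scenario(26, 0.61))
    assert r.hi == r.hq["Zn"]


def test_empty_panel_raises(limits):
    with pytest.raises(DomainError):
        hazard_index(ElementPanel(()), limits, _scenario(26, 0.61))


def test_cancer_risk_classification():
    assert classify_cancer_risk(0.0) is CancerRiskClass.BELOW_RANGE
    assert classify_cancer_risk(5e-7) is CancerRiskClass.BELOW_RANGE
    assert classify_cancer_risk(1e-6) is CancerRiskClass.ACCEPTABLE
    assert classify_cancer_risk(1e-4) is CancerRiskClass.ACCEPTABLE
    assert classify_cancer_risk(2e-4) is CancerRiskClass.INADMISSIBLE
    assert cancer_risk(0.0, 0.5) == 0.0


# ---------------------------------------------------------------------------
# linearity properties
# ---------------------------------------------------------------------------

@given(element_panels(), st.data())
def test_chain_linear_in_ingestion_rate(panel, data):
    limits = data.draw(limit_tables())
    base = hazard_index(panel, limits, _scenario(60, 1.0))
    doubled = hazard_index(panel, limits, _scenario(60, 2.0))
    assert doubled.hi == pytest.approx(2 * base.hi, rel=1e-12)
    for s in base.hq:
        assert doubled.hq[s] == pytest.approx(2 * base.hq[s], rel=1e-12)
    for s in base.cancer_risk:
        assert doubled.cancer_risk[s] == pytest.approx(2 * base.cancer_risk[s], rel=1e-12)


@given(element_panels())
def test_chain_linear_in_concentration(panel):
    limits = LimitTable({m.symbol: ElementLimits(rfd=0.1, slope_factor=0.5) for m in panel})
    scaled = ElementPanel(
        tuple(
            ElementMeasurement.from_raw(m.symbol, m.concentration * 3, m.lod, m.loq)
            for m in panel
        )
    )
    base = hazard_index(panel, limits, _scenario(60, 1.0))
    tripled = hazard_index(scaled, limits, _scenario(60, 1.0))
    assert tripled.hi == pytest.approx(3 * base.hi, rel=1e-12)


@given(element_panels(), st.data())
def test_si_strict_is_paper_over_1000(panel, data):
    limits = data.draw(limit_tables())
    paper = hazard_index(panel, limits, _scenario(60, 1.3))
    si = hazard_index(panel, limits, _scenario(60, 1.3, UnitMode.SI_STRICT))
    assert si.hi == pytest.approx(paper.hi / 1000, rel=1e-12)
    for s in paper.cancer_risk:
        assert si.cancer_risk[s] == pytest.approx(paper.cancer_risk[s] / 1000, rel=1e-12)


# ---------------------------------------------------------------------------
# inverse solvers
# ---------------------------------------------------------------------------

def test_max_intake_for_hi_reference(reference_panel, limits, cohorts):
    """Closed-form inverse at the 26-kg cohort: 0.99·26/Σ(C/RfD) ≈ 0.6095 → 0.61."""
    ir = max_intake_for_hi(reference_panel, limits, cohorts[0], 0.99)
    sum_c_over_rfd = 1.0401 / 1.0 + 0.0242 / 0.003 + 0.2791 / 0.04 + 1.6637 / 0.7 + 0.2372 / 0.14 + 6.6228 / 0.3
    assert ir == pytest.approx(0.99 * 26 / sum_c_over_rfd, rel=1e-12)
    assert round_dp(ir, 2) == 0.61


def test_max_intake_for_hi_zero_target(reference_panel, limits, cohorts):
    assert max_intake_for_hi(reference_panel, limits, cohorts[0], 0.0) == 0.0


def test_max_intake_for_cr_reference(reference_panel, limits, cohorts):
    ir = max_intake_for_cr(reference_panel, limits, cohorts[0], 1e-4)
    assert ir == pytest.approx(1e-4 * 26 / (0.0242 * 0.5), rel=1e-12)


def test_max_intake_for_cr_unbounded_without_carcinogen(limits, cohorts):
    panel = ElementPanel((ElementMeasurement.from_raw("Zn", 6.6228, 0.0018, 0.006),))
    assert max_intake_for_cr(panel, limits, cohorts[0], 1e-4) == math.inf


def test_max_intake_for_cr_inverse_proportional(reference_panel, limits, cohorts):
    doubled = ElementPanel(
        tuple(
            ElementMeasurement.from_raw(
                m.symbol, m.concentration * 2 if m.symbol == "Cr" else m.concentration,
                m.lod, m.loq,
            )
            if m.quantified
            else m
            for m in reference_panel
        )
    )
    base = max_intake_for_cr(reference_panel, limits, cohorts[0], 1e-4)
    assert max_intake_for_cr(doubled, limits, cohorts[0], 1e-4) == pytest.approx(
        base / 2, rel=1e-12
    )


@given(element_panels(), st.data(), st.floats(min_value=0.01, max_value=5.0))
def test_hi_inverse_forward_round_trip(panel, data, target):
    """hazard_index at the solved intake recovers the target to 1e-12 relative."""
    limits = data.draw(limit_tables())
    cohort = Cohort("rt", 30, body_weight=60.0)
    ir = max_intake_for_hi(panel, limits, cohort, target)
    forward = hazard_index(panel, limits, ExposureScenario(cohort, ir)).hi
    assert forward == pytest.approx(target, rel=1e-12)


def test_safe_intake_binding_constraint(reference_panel, limits, cohorts):
    res = safe_intake(reference_panel, limits, cohorts[0], hi_target=0.99, cr_target=1e-4)
    assert res.binding_constraint == "CR"
    assert res.intake_g_per_day == pytest.approx(0.2149, abs=5e-5)
    relaxed = safe_intake(reference_panel, limits, cohorts[0], hi_target=0.99, cr_target=1e-3)
    assert relaxed.binding_constraint == "HI"
    assert relaxed.intake_g_per_day == pytest.approx(0.6095, abs=5e-5)


def test_safe_intake_scales_with_targets(reference_panel, limits, cohorts):
    base = safe_intake(reference_panel, limits, cohorts[0], 0.5, 1e-5)
    scaled = safe_intake(reference_panel, limits, cohorts[0], 1.0, 2e-5)
    assert scaled.binding_constraint == base.binding_constraint
    assert scaled.intake_g_per_day == pytest.approx(2 * base.intake_g_per_day, rel=1e-12)


# ---------------------------------------------------------------------------
# grid assembly
# ---------------------------------------------------------------------------

def test_risk_grid_shape(reference_panel, limits, scenarios):
    results = [hazard_index(reference_panel, limits, s) for s in scenarios]
    grid = risk_grid(results)
    assert list(grid.columns)[-1] == "HI"
    assert grid.shape == (6, 7)  # 3 cohorts x {CR, HQ}; 6 elements + HI
    assert grid.loc[("8y", "HQ"), "Zn"] == pytest.approx(0.51794, abs=5e-6)
    assert math.isnan(grid.loc[("8y", "CR"), "Zn"])
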