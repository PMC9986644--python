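import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilrisk import (
    assess_health_risk,
    cancer_risk,
    cdi_dermal,
    cdi_ingestion,
    cdi_inhalation,
    hazard_index,
    hazard_quotient,
    lifetime_cancer_risk,
)
from soilrisk.health_risk import (
    ADULT,
    CHILD,
    ExposureProfile,
    ToxicityTable,
    cancer_risk_flag,
    chronic_daily_intake,
)

cs_values = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


def test_profile_defaults_match_exposure_tables():
    assert (CHILD.body_weight, CHILD.ingestion_rate, CHILD.skin_area) == (15, 200, 2100)
    assert (ADULT.body_weight, ADULT.ingestion_rate, ADULT.skin_area) == (70, 100, 5800)
    assert CHILD.averaging_time(carcinogenic=True) == 365 * 70
    assert CHILD.averaging_time(carcinogenic=False) == 365 * 6
    assert ADULT.averaging_time(carcinogenic=False) == 365 * 30


@pytest.mark.parametrize(
    "func,expected",
    [
        (cdi_ingestion, 1.2785e-5),  # 1*200*350*6/(15*2190) * 1e-6
        (cdi_dermal, 2.6849e-6),  # 1*2100*0.2*0.1*350*6/(15*2190) * 1e-6
        (cdi_inhalation, 4.918e-10),  # 1*10*350*6/(1.3e9*15*2190)
    ],
)
def test_child_unit_cdi_hand_values(func, expected):
    assert func(1.0, CHILD) == pytest.approx(expected, rel=1e-3)


def test_zero_concentration_gives_zero_dose():
    for route in ("ingestion", "dermal", "inhalation"):
        assert chronic_daily_intake(0.0, CHILD, route) == 0.0


def test_child_adult_ratios_follow_parameters():
    assert cdi_ingestion(5.0, CHILD) / cdi_ingestion(5.0, ADULT) == pytest.approx(
        (200 / 15) / (100 / 70)
    )  # 9.333
    assert cdi_inhalation(5.0, CHILD) / cdi_inhalation(5.0, ADULT) == pytest.approx(
        (10 / 15) / (20 / 70)
    )  # 2.333, the element-independent inhalation ratio


def test_dermal_linear_in_adherence_factor():
    import dataclasses

    doubled = dataclasses.replace(CHILD, adherence_factor=2 * CHILD.adherence_factor)
    assert cdi_dermal(3.0, doubled) == pytest.approx(2 * cdi_dermal(3.0, CHILD))


def test_dermal_exposure_ratio_off_by_default():
    base = cdi_dermal(3.0, CHILD)
    with_fe = cdi_dermal(3.0, CHILD, use_dermal_exposure_ratio=True)
    assert with_fe == pytest.approx(base * 0.61)


@settings(deadline=None, max_examples=50)
@given(cs=cs_values, ed=st.floats(min_value=1, max_value=60))
def test_noncarcinogenic_cdi_independent_of_exposure_duration(cs, ed):
    """AT = 365*ED cancels ED for non-carcinogens."""
    import dataclasses

    profile = dataclasses.replace(CHILD, exposure_duration=ed)
    assert cdi_ingestion(cs, profile) == pytest.approx(
        cdi_ingestion(cs, CHILD), rel=1e-9
    )


@settings(deadline=None, max_examples=50)
@given(cs=cs_values, factor=st.floats(0.1, 10))
def test_doses_homogeneous_of_degree_one(cs, factor):
    for route in ("ingestion", "dermal", "inhalation"):
        assert chronic_daily_intake(factor * cs, CHILD, route) == pytest.approx(
            factor * chronic_daily_intake(cs, CHILD, route), rel=1e-9
        )


def test_hazard_quotient_threshold_semantics():
    assert hazard_quotient(2e-4, 2e-4) == 1.0
    assert hazard_quotient(0.0, 3e-4) == 0.0
    with pytest.raises(ValueError):
        hazard_quotient(1e-4, 0.0)


def test_hazard_index_sums_defined_routes():
    assert hazard_index([0.1, 0.02, 0.003]) == pytest.approx(0.123)
    assert hazard_index([0.4, None, None]) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        hazard_index([None, None])


def test_cancer_risk_chain_and_window():
    assert cancer_risk(0.0, 1.5) == 0.0
    assert lifetime_cancer_risk([1e-5, 2e-6, 3e-8]) == pytest.approx(1.203e-5)
    assert cancer_risk_flag(2e-4) == "exceeds"
    assert cancer_risk_flag(5e-5) == "acceptable"
    assert cancer_risk_flag(1e-7) == "negligible"


def test_toxicity_fallback_and_not_assessed():
    tox = ToxicityTable.default()
    rfd, fallback = tox.rfd_for("As", "dermal")
    assert fallback and rfd == pytest.approx(3.0e-4)
    assert tox.rfd_for("As", "ingestion") == (pytest.approx(3.0e-4), False)
    assert tox.csf_for("Cr", "ingestion") is None  # no slope factor: not assessed
    gi = ToxicityTable(
        rfd={"As": {"ingestion": 3.0e-4}}, csf={}, gi_absorption={"As": 0.5}
    )
    assert gi.rfd_for("As", "dermal")[0] == pytest.approx(1.5e-4)


def test_site_report_structure_and_aggregation(refs, survey_summaries):
    report = assess_health_risk(survey_summaries)
    det = report.detail
    assert set(det.receptor) == {"child", "adult"}
    assert len(det) == 2 * 11 * 6 * 3  # receptors x sites x elements x routes
    # brute-force double sum equals the reported site HI
    block = det[(det.receptor == "child") & (det.land_use == "MW")]
    brute = sum(v for v in block.hq if v is not None)
    assert report.hi("child", "MW") == pytest.approx(brute)
    # carcinogen-only LTCR: Cr/Ni/Cu have no CSF and stay out
    assert {e for e in block[block.cr.notna()].element} == {"As", "Cd", "Pb"}
    assert all(det.cdi >= 0)
    hqs = det.hq.dropna()
    assert (hqs >= 0).all()


def test_children_exceed_adults_everywhere(refs, survey_summaries):
    report = assess_health_risk(survey_summaries)
    summary = report.summary().pivot(index="land_use", columns="receptor")
    assert (
        summary[("hi_total", "child")] > summary[("hi_total", "adult")]
    ).all()
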