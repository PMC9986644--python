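import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilrisk import (
    classify_index,
    contamination_factor,
    degree_of_contamination,
    enrichment_factor,
    geoaccumulation_index,
    pollution_load_index,
    site_indices,
)
from soilrisk.indices import index_frame, load_schemes

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    "conc,background,expected",
    [
        (0.85, 0.30, 2.8333),  # park-area Cd
        (5.87, 41.0, 0.1432),  # residential-area Cr
        (7.77, 7.77, 1.0),  # identity at background
    ],
)
def test_contamination_factor_values(conc, background, expected):
    assert contamination_factor(conc, background) == pytest.approx(expected, abs=1e-4)


def test_contamination_factor_rejects_bad_background():
    with pytest.raises(ValueError):
        contamination_factor(1.0, 0.0)
    with pytest.raises(ValueError):
        contamination_factor(-1.0, 2.0)


def test_degree_of_contamination_park_area():
    cfs = [1.7469, 2.8333, 0.339, 0.9476, 0.5905, 0.5793]
    assert degree_of_contamination(cfs) == pytest.approx(7.037, abs=1e-3)
    assert degree_of_contamination([0, 0, 0]) == 0.0
    with pytest.raises(ValueError):
        degree_of_contamination([])


def test_degree_of_contamination_metal_workshop(refs, survey_summaries):
    mw = next(s for s in survey_summaries if s.land_use == "MW")
    cfs = [contamination_factor(mw.mean[e], refs.background[e]) for e in mw.mean]
    assert degree_of_contamination(cfs) == pytest.approx(20.16, abs=0.02)


class TestEnrichmentFactor:
    def test_background_ratio_gives_unity(self):
        assert enrichment_factor(4.9, 20000, 4.9, 20000) == pytest.approx(1.0)

    def test_iron_cancels_at_equal_levels(self):
        assert enrichment_factor(10, 20000, 5, 20000) == pytest.approx(2.0)

    def test_doubling_sample_iron_halves_ef(self):
        base = enrichment_factor(10, 20000, 5, 18000)
        assert enrichment_factor(10, 40000, 5, 18000) == pytest.approx(base / 2)

    def test_rejects_nonpositive_normalisers(self):
        with pytest.raises(ValueError):
            enrichment_factor(1, 0, 1, 1)
        with pytest.raises(ValueError):
            enrichment_factor(1, 1, 1, -2)


@pytest.mark.parametrize(
    "conc,background,expected",
    [
        (8.56, 4.90, 0.22),  # park-area As
        (2.05, 0.30, 2.19),  # metal-workshop Cd
        (5.87, 41.00, -3.39),  # residential-area Cr
    ],
)
def test_geoaccumulation_published_cells(conc, background, expected):
    assert geoaccumulation_index(conc, background) == pytest.approx(expected, abs=0.005)


def test_geoaccumulation_zero_point():
    assert geoaccumulation_index(1.5 * 7.0, 7.0) == 0.0


def test_geoaccumulation_zero_concentration_policy():
    with pytest.raises(ValueError):
        geoaccumulation_index(0.0, 5.0)
    assert geoaccumulation_index(0.0, 5.0, zero_conc="neginf") == -math.inf


def test_pollution_load_index_values(refs, survey_summaries):
    assert pollution_load_index([1.0, 1.0, 1.0]) == pytest.approx(1.0)
    assert pollution_load_index([2.0, 8.0]) == pytest.approx(4.0)
    mw = next(s for s in survey_summaries if s.land_use == "MW")
    cfs = [contamination_factor(mw.mean[e], refs.background[e]) for e in mw.mean]
    # recomputed from site means; the survey chart peaks at 2.82
    assert pollution_load_index(cfs) == pytest.approx(2.769, abs=0.005)
    with pytest.raises(ValueError):
        pollution_load_index([1.0, 0.0])


# -- properties -------------------------------------------------------------


@settings(deadline=None, max_examples=50)
@given(conc=positive, background=positive, factor=st.floats(0.1, 10))
def test_contamination_factor_linear_in_concentration(conc, background, factor):
    assert contamination_factor(factor * conc, background) == pytest.approx(
        factor * contamination_factor(conc, background), rel=1e-9
    )


@settings(deadline=None, max_examples=50)
@given(conc=positive, background=positive)
def test_igeo_doubling_adds_one(conc, background):
    assert geoaccumulation_index(2 * conc, background) == pytest.approx(
        geoaccumulation_index(conc, background) + 1.0, abs=1e-9
    )


@settings(deadline=None, max_examples=50)
@given(st.lists(positive, min_size=1, max_size=8), st.randoms(use_true_random=False))
def test_aggregates_permutation_invariant(cfs, rnd):
    shuffled = list(cfs)
    rnd.shuffle(shuffled)
    assert degree_of_contamination(shuffled) == pytest.approx(
        degree_of_contamination(cfs), rel=1e-12
    )
    assert pollution_load_index(shuffled) == pytest.approx(
        pollution_load_index(cfs), rel=1e-9
    )


def test_pli_collapses_as_one_cf_vanishes():
    assert pollution_load_index([1.0, 1.0, 1e-6]) < 0.011


# -- classification ---------------------------------------------------------


def test_classify_degree_of_contamination_study_scheme():
    assert classify_index(4.42, "cd_study") == "Low"
    assert classify_index(7.03, "cd_study") == "Moderate"
    assert classify_index(10.29, "cd_study") == "Considerable"
    assert classify_index(20.16, "cd_study") == "High"


def test_classify_boundary_is_lower_inclusive():
    assert classify_index(6.0, "cd_study") == "Moderate"
    assert classify_index(5.999, "cd_study") == "Low"


def test_classify_rejects_out_of_domain():
    with pytest.raises(ValueError):
        classify_index(-0.5, "cd_study")
    with pytest.raises(KeyError):
        classify_index(1.0, "no_such_scheme")


def test_schemes_cover_negative_igeo():
    assert classify_index(-3.39, "igeo_muller") == "Unpolluted"
    assert classify_index(2.19, "igeo_muller") == "Moderately to heavily polluted"


def test_hakanson_scheme_differs_from_study_scheme():
    schemes = load_schemes()
    # 20.16 is "High" under the survey labels but Considerable classically
    assert schemes["cd_hakanson"].classify(20.16) == "Considerable"


# -- site-level -------------------------------------------------------------


def test_site_indices_invariants(refs, survey_summaries):
    reports = site_indices(survey_summaries, refs)
    frame = index_frame(reports)
    assert len(frame) == 11
    for r in reports:
        assert r.c_d == pytest.approx(sum(r.cf.values()))
        assert r.pli == pytest.approx(
            np.exp(np.mean(np.log(list(r.cf.values()))))
        )


def test_per_sample_pli_option(refs, study_table):
    site_mean = site_indices(study_table, refs)
    per_sample = site_indices(study_table, refs, pli_basis="per_sample")
    by_site = {r.land_use: r.pli for r in site_mean}
    for r in per_sample:
        # both are valid PLI summaries; they differ but stay comparable
        assert r.pli == pytest.approx(by_site[r.land_use], rel=0.35)
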