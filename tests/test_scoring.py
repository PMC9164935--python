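"""IQR-band classification and case scoring."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dilicat.datasets import (
    SUBSET1_EXPECTED_POINTS,
    SUBSET1_EXPECTED_TOTALS,
    sportif3_subset1_cases,
)
from dilicat.phenotype import PARAMETERS, CaseFeatures, PercentileProfile
from dilicat.scoring import Band, WeightScheme, classify, score_case, score_cohort

RATIO_WEIGHTED = WeightScheme("ast_alt_ratio")


class TestClassify:
    def test_out_of_range_and_beyond_fence_scores_minus_50(self, phenotype_v1):
        cls = classify(43, phenotype_v1.profile("latency_days"))  # range min 56, fence low 45.25
        assert cls.band is Band.OUT_AND_OUTLIER and cls.percentage == -50

    def test_out_of_range_within_fences_scores_minus_25(self, phenotype_v1):
        cls = classify(92, phenotype_v1.profile("latency_days"))  # range max 83, fence high 100.5
        assert cls.band is Band.OUT_OF_RANGE and cls.percentage == -25

    def test_iqr_membership_scores_100(self, phenotype_v1):
        cls = classify(0.64, phenotype_v1.profile("ast_alt_ratio"))
        assert cls.band is Band.IQR and cls.percentage == 100

    def test_in_range_tail_beyond_p90_scores_0(self, phenotype_v1):
        cls = classify(0.68, phenotype_v1.profile("ast_alt_ratio"))  # q90 0.674, range max 0.69
        assert cls.band is Band.TAIL_IN_RANGE and cls.percentage == 0

    def test_median_always_in_iqr(self, phenotype_v1):
        for p in PARAMETERS:
            prof = phenotype_v1.profile(p)
            assert classify(prof.median, prof).band is Band.IQR

    def test_iqr_endpoints_score_100(self, phenotype_v1):
        prof = phenotype_v1.profile("ast_alt_ratio")
        for v in (prof.q25, prof.q75):
            assert classify(v, prof).band is Band.IQR

    def test_in_range_outlier_scores_minus_25(self):
        # fence_high (18) inside the observed range (max 100)
        prof = PercentileProfile(
            median=10, q10=6, q15=7, q25=8, q75=12, q85=13, q90=90,
            range_min=5, range_max=100, fence_low=5, fence_high=18,
            n_cases=9, quantile_dialect="inclusive",
        )
        cls = classify(50, prof)
        assert cls.band is Band.OUTLIER and cls.percentage == -25

    def test_band_percentage_non_increasing_away_from_median(self, phenotype_v1):
        prof = phenotype_v1.profile("latency_days")
        upward = [classify(v, prof).percentage for v in (69, 74, 77, 79, 80.5)]
        assert upward == sorted(upward, reverse=True)

    def test_non_finite_value_rejected(self, phenotype_v1):
        with pytest.raises(ValueError):
            classify(float("nan"), phenotype_v1.profile("latency_days"))


class TestGoldenScores:
    def test_all_validation_points_and_totals(self, phenotype_v1):
        scores = score_cohort(sportif3_subset1_cases(), phenotype_v1, RATIO_WEIGHTED)
        for s in scores:
            for param, pts in SUBSET1_EXPECTED_POINTS[s.case_id].items():
                assert s.parameters[param].points == pts, (s.case_id, param)
        assert tuple(s.total for s in scores) == SUBSET1_EXPECTED_TOTALS

    @pytest.mark.parametrize(
        "case_id,lat,r,ratio,expected",
        [
            ("d1", 43, 3.32, 0.64, 25),
            ("c3", 266, 0.67, 1.09, -40),
            ("d4", 427, 9.41, 0.47, -10),
        ],
    )
    def test_single_case_totals(self, phenotype_v1, case_id, lat, r, ratio, expected):
        case = CaseFeatures(case_id, "x", lat, r, ratio)
        assert score_case(case, phenotype_v1, RATIO_WEIGHTED).total == expected

    def test_case_at_the_three_medians_attains_maximum_80(self, phenotype_v1):
        case = CaseFeatures(
            "m", "x",
            phenotype_v1.profile("latency_days").median,
            phenotype_v1.profile("r_value").median,
            phenotype_v1.profile("ast_alt_ratio").median,
        )
        assert score_case(case, phenotype_v1, RATIO_WEIGHTED).total == 80

    def test_minimum_minus_40_attained(self, phenotype_v1):
        # the third comparator case attains the floor
        case = CaseFeatures("w3", "x", 266, 0.67, 1.09)
        assert score_case(case, phenotype_v1, RATIO_WEIGHTED).total == -40


class TestWeighting:
    def test_doubling_property(self, phenotype_v1):
        case = CaseFeatures("c", "x", 60, 7.0, 0.63)
        for param in PARAMETERS:
            std = score_case(case, phenotype_v1, WeightScheme("latency_days" if param != "latency_days" else "r_value"))
            wtd = score_case(case, phenotype_v1, WeightScheme(param))
            assert wtd.parameters[param].points == 2 * std.parameters[param].points

    def test_exactly_one_weighted_parameter(self, phenotype_v1):
        s = score_case(CaseFeatures("c", "x", 60, 7.0, 0.63), phenotype_v1, RATIO_WEIGHTED)
        assert sum(p.weighted for p in s.parameters.values()) == 1

    def test_unknown_weighted_parameter_rejected(self):
        with pytest.raises(ValueError):
            WeightScheme("alp")


class TestCohort:
    def test_empty_cohort(self, phenotype_v1):
        assert score_cohort([], phenotype_v1, RATIO_WEIGHTED) == []

    def test_incomplete_case_error_names_case(self, phenotype_v1):
        bad = CaseFeatures("incomplete", "x", 50.0, None, 0.6)
        with pytest.raises(ValueError, match="incomplete"):
            score_cohort([bad], phenotype_v1, RATIO_WEIGHTED)

    def test_input_order_preserved(self, phenotype_v1):
        cases = sportif3_subset1_cases()[::-1]
        scores = score_cohort(cases, phenotype_v1, RATIO_WEIGHTED)
        assert [s.case_id for s in scores] == [c.case_id for c in cases]


class TestCompatibilityFlag:
    def test_table_outlier_compat_fixes_in_range_outlier_at_minus_10(self):
        prof = PercentileProfile(
            median=10, q10=6, q15=7, q25=8, q75=12, q85=13, q90=90,
            range_min=5, range_max=100, fence_low=5, fence_high=18,
            n_cases=9, quantile_dialect="inclusive",
        )
        from dilicat.phenotype import DiliPhenotype

        ph = DiliPhenotype("x", "v1", prof, prof, prof, "inclusive", ("a", "b", "c", "d", "e"))
        case = CaseFeatures("c", "x", 50, 50, 50)  # in-range outliers everywhere
        default = score_case(case, ph, WeightScheme("latency_days"))
        compat = score_case(case, ph, WeightScheme("latency_days"), table_outlier_compat=True)
        assert default.parameters["latency_days"].points == -10  # -25% of 40
        assert default.parameters["r_value"].points == -5  # -25% of 20
        assert compat.parameters["latency_days"].points == -10
        assert compat.parameters["r_value"].points == -10


@given(
    lat=st.floats(0.1, 1000),
    r=st.floats(0.1, 50),
    ratio=st.floats(0.1, 5),
    weighted=st.sampled_from(list(PARAMETERS)),
)
def test_total_always_bounded(phenotype_v1, lat, r, ratio, weighted):
    s = score_case(CaseFeatures("c", "x", lat, r, ratio), phenotype_v1, WeightScheme(weighted))
    assert -40 <= s.total <= 80
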