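"""Rank, trend and contingency tests, and the weighting rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from dilicat.phenotype import CaseFeatures
from dilicat.stats import (
    StatisticalError,
    chi_square_2x2,
    iqr_distance,
    mann_whitney,
    mantel_haenszel_trend,
    select_weighted_parameter,
)

DRUG_RATIOS = [0.64, 0.68, 0.59, 0.47, 0.65]
COMP_RATIOS = [1.11, 0.97, 1.09]
DRUG_LAT = [43, 46, 92, 427, 45]
COMP_LAT = [43, 187, 266]
DRUG_R = [3.32, 6.63, 7.26, 9.41, 0.56]
COMP_R = [2.07, 2.82, 0.67]


def pair_count_u(a, b):
    """Brute-force U of group a: wins + half-ties over all pairs."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


class TestMannWhitney:
    def test_disjoint_samples_give_u_zero(self):
        res = mann_whitney(DRUG_RATIOS, COMP_RATIOS)
        assert res.u == 0.0
        assert res.p_two_sided == pytest.approx(0.025, abs=5e-4)

    def test_tie_corrected_latency_comparison(self):
        res = mann_whitney(DRUG_LAT, COMP_LAT)
        assert res.u == 6.5
        assert res.tie_correction_applied
        assert res.p_two_sided == pytest.approx(0.764, abs=5e-4)

    def test_r_value_comparison(self):
        res = mann_whitney(DRUG_R, COMP_R)
        assert res.u == 3.0
        assert res.p_two_sided == pytest.approx(0.18, abs=5e-3)

    def test_symmetric_case(self):
        res = mann_whitney([1, 2], [1, 2])
        assert res.u == 2.0 and res.z == 0.0 and res.p_two_sided == 1.0

    def test_u_pair_identity(self):
        res = mann_whitney(DRUG_LAT, COMP_LAT)
        assert res.u + res.u_other == len(DRUG_LAT) * len(COMP_LAT)

    def test_empty_group_rejected(self):
        with pytest.raises(StatisticalError):
            mann_whitney([], [1.0])

    def test_all_identical_guarded(self):
        with pytest.warns(UserWarning, match="identical"):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_two_sided == 1.0

    @given(
        a=st.lists(st.integers(0, 8), min_size=1, max_size=10),
        b=st.lists(st.integers(0, 8), min_size=1, max_size=10),
    )
    def test_rank_formula_matches_pair_count_oracle(self, a, b):
        res = mann_whitney(a, b)
        u_a = pair_count_u(a, b)
        assert min(u_a, len(a) * len(b) - u_a) == pytest.approx(res.u)

    @given(
        a=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
        b=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
    )
    def test_group_reversal_preserves_u_and_p(self, a, b):
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r1.u == pytest.approx(r2.u)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_matches_scipy_asymptotic_no_continuity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 20, rng.integers(2, 10)).astype(float)
            b = rng.integers(0, 20, rng.integers(2, 10)).astype(float)
            ours = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, use_continuity=False, alternative="two-sided", method="asymptotic")
            assert ours.p_two_sided == pytest.approx(float(ref.pvalue), rel=1e-10)


class TestTrend:
    def test_published_validation_totals(self):
        labels = ["drug"] * 5 + ["comparator"] * 3
        totals = [25, 15, 35, -10, 20, -35, -35, -40]
        res = mantel_haenszel_trend(labels, totals)
        assert res.p == pytest.approx(0.016, abs=5e-4)

    def test_hand_computed_chi_square(self):
        res = mantel_haenszel_trend([0, 0, 1, 1], [1, 2, 3, 4])
        assert res.chi_square == pytest.approx(2.4)

    def test_mirrored_design_gives_zero_chi_square(self):
        res = mantel_haenszel_trend([0, 0, 1, 1], [-1, 1, -1, 1])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_constant_scores_rejected(self):
        with pytest.raises(StatisticalError):
            mantel_haenszel_trend([0, 0, 1, 1], [5, 5, 5, 5])

    def test_single_label_rejected(self):
        with pytest.raises(StatisticalError):
            mantel_haenszel_trend([1, 1, 1], [1, 2, 3])

    @given(
        scores=st.lists(st.floats(-40, 80), min_size=4, max_size=20),
        labels=st.lists(st.booleans(), min_size=4, max_size=20),
    )
    def test_equals_n_minus_1_r_squared_via_independent_pearson(self, scores, labels):
        n = min(len(scores), len(labels))
        scores, labels = scores[:n], labels[:n]
        x = [1.0 if l else 0.0 for l in labels]
        if len(set(scores)) < 2 or len(set(labels)) < 2:
            return
        res = mantel_haenszel_trend(labels, scores)
        r, _ = sps.pearsonr(x, scores)
        assert res.chi_square == pytest.approx((n - 1) * r**2, abs=1e-12, rel=1e-12)

    def test_type_one_error_under_label_permutation(self):
        # Monte-Carlo: permuting labels of fixed scores at n = 24 keeps
        # the rejection rate at alpha within binomial noise.
        rng = np.random.default_rng(11)
        scores = rng.normal(size=24)
        labels = np.array([1] * 12 + [0] * 12)
        reps = 2000
        rej = 0
        for _ in range(reps):
            perm = rng.permutation(labels)
            if mantel_haenszel_trend(perm.tolist(), scores.tolist()).p < 0.05:
                rej += 1
        rate = rej / reps
        assert 0.03 <= rate <= 0.07


class TestChiSquare:
    def test_phase2_incidence_not_significant(self):
        res = chi_square_2x2(5, 86, 3, 105)
        assert res.p == pytest.approx(0.31, abs=5e-3)

    def test_phase3_incidence_highly_significant(self):
        res = chi_square_2x2(53, 1343, 22, 1333)
        assert res.p < 0.001

    def test_equal_proportions_give_zero(self):
        res = chi_square_2x2(4, 50, 4, 50)
        assert res.chi_square == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatisticalError):
            chi_square_2x2(0, 50, 0, 60)

    def test_events_exceeding_n_rejected(self):
        with pytest.raises(StatisticalError):
            chi_square_2x2(10, 5, 1, 5)


class TestIqrDistance:
    @pytest.mark.parametrize("v,expected", [(5, 0.0), (3, 0.0), (7, 0.0), (1, 2.0), (10, 3.0)])
    def test_distance(self, v, expected):
        assert iqr_distance(v, 3, 7) == expected


def _cases(drug, lats, rs, ratios, arm):
    return [
        CaseFeatures(f"{arm}{i}", drug, l, r, q, arm=arm)
        for i, (l, r, q) in enumerate(zip(lats, rs, ratios))
    ]


class TestWeightSelection:
    def test_validation_batch_selects_ast_alt_ratio(self):
        drug = _cases("x", DRUG_LAT, DRUG_R, DRUG_RATIOS, "drug")
        comp = _cases("w", COMP_LAT, COMP_R, COMP_RATIOS, "comparator")
        scheme = select_weighted_parameter(drug, comp)
        assert scheme.weighted_parameter == "ast_alt_ratio"

    def test_no_comparator_defaults_to_latency(self):
        drug = _cases("x", DRUG_LAT, DRUG_R, DRUG_RATIOS, "drug")
        scheme = select_weighted_parameter(drug, [])
        assert scheme.weighted_parameter == "latency_days"
        assert "default" in scheme.reason

    def test_nothing_significant_defaults_to_latency(self):
        drug = _cases("x", [10, 20, 30], [1, 2, 3], [0.5, 0.6, 0.7], "drug")
        comp = _cases("w", [12, 22, 28], [1.1, 2.1, 2.9], [0.52, 0.61, 0.69], "comparator")
        scheme = select_weighted_parameter(drug, comp)
        assert scheme.weighted_parameter == "latency_days"
        assert "default" in scheme.reason

    def test_p_value_tie_broken_by_smaller_u(self, monkeypatch):
        # two parameters tie at p = 0.020 (3 dp); the one with U = 2
        # must win over the one with U = 5.
        import dilicat.stats as dstats
        from dilicat.stats import RankTestResult

        fixed = {
            "latency_days": RankTestResult(5.0, 20.0, -2.33, 0.0198, False, 5, 5),
            "r_value": RankTestResult(2.0, 23.0, -2.33, 0.0201, False, 5, 5),
            "ast_alt_ratio": RankTestResult(9.0, 16.0, -1.0, 0.3173, False, 5, 5),
        }
        params = iter(["latency_days", "r_value", "ast_alt_ratio"])
        monkeypatch.setattr(dstats, "mann_whitney", lambda a, b: fixed[next(params)])
        drug = _cases("x", [1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0], [0.5, 0.6, 0.7, 0.8], "drug")
        comp = _cases("w", [5, 6, 7], [5.0, 6.0, 7.0], [0.9, 1.0, 1.1], "comparator")
        scheme = select_weighted_parameter(drug, comp)
        assert scheme.weighted_parameter == "r_value"
        assert "U=2" in scheme.reason
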