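"""Categorization, weights, and equal-interval binning."""

import pytest
from hypothesis import given, settings, strategies as st

from karstprior import (
    Category,
    StudyConfig,
    cave_attribute_scores,
    categorize_end,
    categorize_nts,
    categorize_tbs,
    categorize_vul,
    equal_interval_cutpoints,
    weight_of,
)


class TestEqualIntervals:
    @pytest.mark.parametrize("vmin,vmax,k,expected", [
        (17, 93, 4, (36, 55, 74, 93)),
        (0, 100, 4, (25, 50, 75, 100)),
        (1, 2, 2, (1, 2)),
    ])
    def test_cutpoint_examples(self, vmin, vmax, k, expected):
        assert equal_interval_cutpoints(vmin, vmax, k).uppers == expected

    def test_too_many_classes_rejected(self):
        with pytest.raises(ValueError):
            equal_interval_cutpoints(1, 3, 4)

    def test_classes_partition_integer_range_exhaustively(self):
        """For every range width <= 200 and k <= 6: gap-free, overlap-free."""
        for vmin in (0, 17):
            for span in range(1, 201):
                vmax = vmin + span
                for k in range(1, 7):
                    if span < k - 1:
                        continue
                    iv = equal_interval_cutpoints(vmin, vmax, k)
                    assert iv.uppers[-1] == vmax
                    assert list(iv.uppers) == sorted(set(iv.uppers))
                    classes = [iv.class_of(v) for v in range(vmin, vmax + 1)]
                    # contiguous ascending class labels covering 1..k
                    assert classes[0] == 1 and classes[-1] == k
                    assert all(b - a in (0, 1) for a, b in zip(classes, classes[1:]))
                    assert set(classes) == set(range(1, k + 1))

    def test_value_outside_range_requires_rebuild(self):
        iv = equal_interval_cutpoints(17, 93, 4)
        with pytest.raises(ValueError, match="rebuild"):
            iv.class_of(94)


class TestCategorizers:
    @pytest.mark.parametrize("value,expected", [
        (49, Category.AVERAGE), (93, Category.EXTREME), (17, Category.LOW),
        (36, Category.LOW), (37, Category.AVERAGE), (75, Category.EXTREME),
    ])
    def test_nts_on_printed_range(self, value, expected):
        iv = equal_interval_cutpoints(17, 93, 4)
        assert categorize_nts(value, iv) is expected

    @pytest.mark.parametrize("tbs,expected", [
        (14, Category.EXTREME), (7, Category.EXTREME), (0, Category.NONE),
        (5, Category.HIGH), (6, Category.HIGH), (1, Category.LOW),
        (3, Category.AVERAGE),
    ])
    def test_tbs_bins(self, tbs, expected):
        assert categorize_tbs(tbs) is expected

    @pytest.mark.parametrize("end,policy,expected", [
        (2, "table_literal", Category.HIGH),
        (3, "table_literal", Category.EXTREME),
        (0, "table_literal", Category.LOW),
        (0, "zero", Category.NONE),
        (1, "zero", Category.AVERAGE),
    ])
    def test_end_bins_and_zero_policy(self, end, policy, expected):
        assert categorize_end(end, policy) is expected

    @pytest.mark.parametrize("vul,expected", [
        (4, Category.EXTREME), (5, Category.EXTREME), (1, Category.LOW),
        (0, Category.NONE), (2, Category.AVERAGE), (3, Category.HIGH),
    ])
    def test_vul_bins(self, vul, expected):
        assert categorize_vul(vul) is expected

    def test_vul_out_of_range(self):
        with pytest.raises(ValueError):
            categorize_vul(6)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.integers(0, 20), b=st.integers(0, 20))
    def test_categorization_is_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert categorize_tbs(lo) <= categorize_tbs(hi)
        assert categorize_end(lo) <= categorize_end(hi)
        assert categorize_vul(min(lo, 5)) <= categorize_vul(min(hi, 5))


class TestWeights:
    @pytest.mark.parametrize("category,score", [
        (Category.NONE, 0), (Category.LOW, 100), (Category.AVERAGE, 250),
        (Category.HIGH, 500), (Category.EXTREME, 1000),
    ])
    def test_default_weights(self, category, score):
        assert weight_of(category) == score

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            weight_of(99)


class TestCaveScores:
    def test_maximal_cave_totals_3500(self):
        iv = equal_interval_cutpoints(17, 93, 4)
        out = cave_attribute_scores(
            {"nTS": 93, "TbS": 14, "EnD": 2, "VuL": 4}, iv
        )
        assert (out["nTS_score"], out["TbS_score"], out["EnD_score"],
                out["VuL_score"]) == (1000, 1000, 500, 1000)
        assert out["total"] == 3500

    def test_minimal_cave_totals_300(self):
        iv = equal_interval_cutpoints(17, 93, 4)
        out = cave_attribute_scores(
            {"nTS": 17, "TbS": 0, "EnD": 0, "VuL": 1}, iv
        )
        assert (out["nTS_score"], out["TbS_score"], out["EnD_score"],
                out["VuL_score"]) == (100, 0, 100, 100)
        assert out["total"] == 300

    def test_nts_below_observed_minimum_is_a_contract_error(self):
        iv = equal_interval_cutpoints(17, 93, 4)
        with pytest.raises(ValueError):
            cave_attribute_scores({"nTS": 0, "TbS": 0, "EnD": 0, "VuL": 0}, iv)

    @settings(max_examples=100, derandomize=True)
    @given(
        nts=st.integers(17, 93), tbs=st.integers(0, 14),
        end=st.integers(0, 5), vul=st.integers(0, 5),
    )
    def test_scores_stay_in_weight_set_and_bounds(self, nts, tbs, end, vul):
        iv = equal_interval_cutpoints(17, 93, 4)
        out = cave_attribute_scores(
            {"nTS": nts, "TbS": tbs, "EnD": min(end, tbs), "VuL": vul}, iv
        )
        for name in ("nTS", "TbS", "EnD", "VuL"):
            assert out[f"{name}_score"] in {0, 100, 250, 500, 1000}
        assert 0 <= out["total"] <= 4000
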