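import numpy as np
import pandas as pd
import pytest

from conftest import make_intakes
from dietscreen.coverage import (
    FfqItemMap,
    MomTable,
    candidate_additions,
    compute_mom_table,
    coverage_decision,
    mom1,
    mom2,
    recompute_with_additions,
    sum_scores,
)
from dietscreen.errors import (
    DegenerateVarianceError,
    MappingGapError,
    RecordValidationError,
    UndefinedStatisticError,
)

# two persons; f1 contributes 40 and 40, f2 contributes 60 and 160
TWO_PERSON = {"p1": {"f1": 40.0, "f2": 60.0}, "p2": {"f1": 40.0, "f2": 160.0}}


class TestMom1:
    def test_hand_example(self):
        m1 = mom1(make_intakes(TWO_PERSON), "iron_mg")
        assert m1["f1"] == pytest.approx(100 * 80 / 300)
        assert m1["f2"] == pytest.approx(100 * 220 / 300)

    def test_single_person_single_food_is_100(self):
        m1 = mom1(make_intakes({"p1": {"f": 3.0}}), "iron_mg")
        assert m1["f"] == pytest.approx(100.0)

    def test_duplicating_cohort_leaves_mom1_unchanged(self):
        base = mom1(make_intakes(TWO_PERSON), "iron_mg")
        doubled_data = {**TWO_PERSON, "p3": TWO_PERSON["p1"], "p4": TWO_PERSON["p2"]}
        doubled = mom1(make_intakes(doubled_data), "iron_mg")
        assert np.allclose(base.values, doubled.values)

    def test_zero_total_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mom1(make_intakes({"p1": {"f": 0.0}}), "iron_mg")


class TestMom2:
    def test_constant_food_carries_no_variance(self):
        m2 = mom2(make_intakes(TWO_PERSON), "iron_mg")
        assert m2["f1"] == pytest.approx(0.0)
        assert m2["f2"] == pytest.approx(100.0)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateVarianceError):
            mom2(make_intakes({"p1": {"f": 1.0}, "p2": {"f": 1.0}}), "iron_mg")

    def test_sums_to_100_on_random_data(self):
        rng = np.random.default_rng(3)
        data = {
            f"p{i}": {f"f{j}": float(rng.uniform(0, 50)) for j in range(5)} for i in range(20)
        }
        m2 = mom2(make_intakes(data), "iron_mg")
        assert m2.sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_bruteforce_covariance_decomposition(self):
        """MOM2 equals explicit covariance sums on small instances."""
        rng = np.random.default_rng(9)
        data = {
            f"p{i}": {f"f{j}": float(rng.uniform(0, 30)) for j in range(4)} for i in range(7)
        }
        m2 = mom2(make_intakes(data), "iron_mg")
        persons = sorted(data)
        foods = sorted(data[persons[0]])
        X = np.array([[data[p][f] for f in foods] for p in persons])
        T = X.sum(axis=1)
        n = len(persons)
        var_t = ((T - T.mean()) ** 2).sum() / (n - 1)
        for j, f in enumerate(foods):
            cov = ((X[:, j] - X[:, j].mean()) * (T - T.mean())).sum() / (n - 1)
            assert m2[f] == pytest.approx(100 * cov / var_t, rel=1e-9)


class TestSumScoresAndDecision:
    def _mom(self):
        return compute_mom_table(make_intakes(TWO_PERSON), ["iron_mg"])

    def test_all_mapped_gives_100(self):
        sums = sum_scores(self._mom(), FfqItemMap({"f1": "a", "f2": "b"}))
        assert sums.loc["iron_mg", "mom1_sum"] == pytest.approx(100.0)

    def test_none_mapped_gives_0(self):
        sums = sum_scores(self._mom(), FfqItemMap({"f1": None, "f2": None}))
        assert sums.loc["iron_mg", "mom1_sum"] == pytest.approx(0.0)

    def test_partial_mapping_hand_values(self):
        sums = sum_scores(self._mom(), FfqItemMap({"f1": None, "f2": "b"}))
        assert sums.loc["iron_mg", "mom1_sum"] == pytest.approx(100 * 220 / 300)
        assert sums.loc["iron_mg", "mom2_sum"] == pytest.approx(100.0)

    def test_mapping_gap_lists_codes(self):
        with pytest.raises(MappingGapError, match="f2"):
            sum_scores(self._mom(), FfqItemMap({"f1": "a"}))

    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(80.0, 80.0, True), (76.2, 39.1, False), (95.0, 79.9, False), (80.0, 100.0, True)],
    )
    def test_decision_is_inclusive_at_threshold(self, m1, m2, expected):
        sums = pd.DataFrame({"mom1_sum": [m1], "mom2_sum": [m2]}, index=["x"])
        assert bool(coverage_decision(sums)["x"]) is expected

    def test_zero_threshold_always_sufficient(self):
        sums = pd.DataFrame({"mom1_sum": [0.0], "mom2_sum": [-5.0]}, index=["x"])
        assert bool(coverage_decision(sums, threshold=-10)["x"])


def _mom_table(values: dict) -> MomTable:
    """values: nutrient -> {food: (mom1, mom2)}"""
    tables = {}
    for nutrient, foods in values.items():
        tables[nutrient] = pd.DataFrame(
            {
                "mom1": {f: v[0] for f, v in foods.items()},
                "mom2": {f: v[1] for f, v in foods.items()},
            }
        )
    return tables and MomTable(tables=tables)


class TestCandidates:
    MOM = {
        "vitb12_ug": {
            "mapped_a": (60.0, 30.0),
            "low_both": (0.5, 0.5),
            "or_rule": (0.2, 3.0),
            "big": (5.0, 2.0),
        }
    }
    MAPPING = FfqItemMap(
        {"mapped_a": "item_a", "low_both": None, "or_rule": None, "big": None}
    )

    def test_or_rule_and_sorting(self):
        cands = candidate_additions(_mom_table(self.MOM), self.MAPPING)
        # below-1% food excluded; OR rule includes or_rule; sorted by max(mom1, mom2) desc
        assert cands["vitb12_ug"] == ["big", "or_rule"]

    def test_sufficient_nutrients_get_no_candidates(self):
        mom = _mom_table({"protein_g": {"mapped_a": (90.0, 95.0), "x": (10.0, 5.0)}})
        mapping = FfqItemMap({"mapped_a": "item_a", "x": None})
        assert candidate_additions(mom, mapping) == {"protein_g": []}

    def test_fully_mapped_gives_empty_list(self):
        mom = _mom_table({"vitb12_ug": {"a": (50.0, 40.0), "b": (50.0, 60.0)}})
        mapping = FfqItemMap({"a": "i1", "b": None})
        cands = candidate_additions(mom, FfqItemMap({"a": "i1", "b": "i2"}))
        assert cands["vitb12_ug"] == []

    def test_lowering_min_pct_never_removes_candidates(self):
        mom = _mom_table(self.MOM)
        strict = set(candidate_additions(mom, self.MAPPING, min_pct=2.0)["vitb12_ug"])
        loose = set(candidate_additions(mom, self.MAPPING, min_pct=0.1)["vitb12_ug"])
        assert strict <= loose


class TestRecompute:
    def test_additivity(self):
        mom = _mom_table({"vitd_ug": {"a": (70.0, 80.0), "b": (5.0, 3.0), "c": (25.0, 17.0)}})
        mapping = FfqItemMap({"a": "i", "b": None, "c": None})
        before = sum_scores(mom, mapping)
        after = recompute_with_additions(mom, mapping, ["b"])
        assert after.loc["vitd_ug", "mom1_sum"] - before.loc["vitd_ug", "mom1_sum"] == pytest.approx(5.0)
        assert after.loc["vitd_ug", "mom2_sum"] - before.loc["vitd_ug", "mom2_sum"] == pytest.approx(3.0)

    def test_completion_reaches_100(self):
        mom = _mom_table({"vitd_ug": {"a": (60.0, 55.0), "b": (40.0, 45.0)}})
        mapping = FfqItemMap({"a": "i", "b": None})
        after = recompute_with_additions(mom, mapping, ["b"])
        assert after.loc["vitd_ug", "mom1_sum"] == pytest.approx(100.0)
        assert after.loc["vitd_ug", "mom2_sum"] == pytest.approx(100.0)

    def test_empty_additions_is_identity(self):
        mom = _mom_table({"vitd_ug": {"a": (60.0, 55.0), "b": (40.0, 45.0)}})
        mapping = FfqItemMap({"a": "i", "b": None})
        pd.testing.assert_frame_equal(
            recompute_with_additions(mom, mapping, []), sum_scores(mom, mapping)
        )

    def test_already_mapped_addition_rejected(self):
        mom = _mom_table({"vitd_ug": {"a": (60.0, 55.0), "b": (40.0, 45.0)}})
        mapping = FfqItemMap({"a": "i", "b": None})
        with pytest.raises(RecordValidationError, match="a"):
            recompute_with_additions(mom, mapping, ["a"])
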