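import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietscreen.dhd import (
    ComponentDefinition,
    FfqResponse,
    derive_component_intakes,
    estimate_nutrient_intakes,
    load_components,
    load_ffq_definition,
    load_rda,
    score_component,
    score_dhd,
    score_nutrients,
)
from dietscreen.errors import ConfigurationError, SchemaError
from dietscreen.simulate import simulate_ffq


@pytest.fixture(scope="module")
def ffq_def():
    return load_ffq_definition()


@pytest.fixture(scope="module")
def components():
    return load_components()


class TestFixtureShape:
    def test_item_and_question_counts(self, ffq_def):
        assert ffq_def.n_items == 55
        assert ffq_def.n_questions == 40

    def test_sixteen_components_configured(self, components):
        assert len(components) == 16

    def test_eggs_not_in_item_set(self, ffq_def):
        assert not any("egg" in item_id for item_id in ffq_def.items)


class TestDeriveComponentIntakes:
    def test_daily_conversion(self, ffq_def):
        resp = FfqResponse("p", {"raw_vegetables": (7.0, 200.0)})
        intakes = derive_component_intakes(resp, ffq_def)
        assert intakes["vegetables"] == pytest.approx(200.0)

    def test_all_zero_response(self, ffq_def):
        resp = FfqResponse("p", {item: (0.0, 0.0) for item in ffq_def.items})
        assert all(v == 0 for v in derive_component_intakes(resp, ffq_def).values())

    def test_half_weights_sum_to_one_full_contribution(self, ffq_def):
        # cheese maps to dairy with weight 0.5; two identical answers = one full one
        resp = FfqResponse("p", {"cheese": (7.0, 30.0), "vegetable_juice": (0, 0)})
        half = derive_component_intakes(resp, ffq_def)["dairy"]
        assert half == pytest.approx(0.5 * 30.0)

    def test_unknown_item_rejected(self, ffq_def):
        with pytest.raises(SchemaError, match="not_an_item"):
            derive_component_intakes(FfqResponse("p", {"not_an_item": (1, 1)}), ffq_def)


ADQ = ComponentDefinition("veg", "adequacy", {"threshold": 200.0})
MOD = ComponentDefinition("meat", "moderation", {"lower": 45.0, "upper": 100.0})
OPT = ComponentDefinition(
    "dairy", "optimum", {"zero_low": 0.0, "opt_low": 300.0, "opt_high": 450.0, "zero_high": 750.0}
)


class TestScoreComponent:
    @pytest.mark.parametrize(
        "intake,expected",
        [(0, 0.0), (100, 5.0), (200, 10.0), (350, 10.0)],
    )
    def test_adequacy_interpolation(self, intake, expected):
        assert score_component(intake, ADQ) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "intake,expected",
        [(0, 10.0), (45, 10.0), (72.5, 5.0), (100, 0.0), (500, 0.0)],
    )
    def test_moderation_interpolation(self, intake, expected):
        assert score_component(intake, MOD) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "intake,expected",
        [(0, 0.0), (150, 5.0), (300, 10.0), (450, 10.0), (600, 5.0), (750, 0.0)],
    )
    def test_optimum_plateau(self, intake, expected):
        assert score_component(intake, OPT) == pytest.approx(expected)

    def test_malformed_moderation_rejected(self):
        bad = ComponentDefinition("x", "moderation", {"lower": 10.0, "upper": 10.0})
        with pytest.raises(ConfigurationError):
            score_component(5, bad)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(min_value=0, max_value=1000), st.floats(min_value=0, max_value=1000))
    def test_adequacy_nondecreasing_moderation_nonincreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert score_component(lo, ADQ) <= score_component(hi, ADQ)
        assert score_component(lo, MOD) >= score_component(hi, MOD)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(min_value=0, max_value=2000))
    def test_scores_stay_in_range(self, intake):
        for d in (ADQ, MOD, OPT):
            assert 0.0 <= score_component(intake, d) <= 10.0


class TestScoreDhd:
    def test_perfect_adherence_scores_160(self, ffq_def, components):
        resp = simulate_ffq(1, adherence=1.0, seed=0)[0]
        assert score_dhd(resp, ffq_def, components).total == pytest.approx(160.0)

    def test_null_response_equals_per_component_hand_sum(self, ffq_def, components):
        """Total at zero intake = sum of each component scored at zero.

        Moderation-type components whose optimum is zero intake (alcohol,
        processed meat, ...) score 10 at zero; adequacy components score 0.
        """
        resp = FfqResponse("p", {})
        total = score_dhd(resp, ffq_def, components).total
        expected = 0.0
        for name, cdef in components.items():
            if cdef.kind == "ratio":
                expected += 10.0  # empty denominator convention
            elif cdef.kind == "binary":
                expected += score_component(0.0, cdef)
            else:
                expected += score_component(0.0, cdef)
        assert total == pytest.approx(expected)

    def test_total_is_exact_component_sum_and_monotone_in_vegetables(self, ffq_def, components):
        lo = score_dhd(FfqResponse("p", {"raw_vegetables": (7, 50)}), ffq_def, components)
        hi = score_dhd(FfqResponse("p", {"raw_vegetables": (7, 180)}), ffq_def, components)
        for s in (lo, hi):
            assert s.total == pytest.approx(sum(s.component_scores.values()))
        assert hi.total >= lo.total

    def test_wrong_component_count_rejected(self, ffq_def, components):
        subset = dict(list(components.items())[:10])
        with pytest.raises(ConfigurationError):
            score_dhd(FfqResponse("p", {}), ffq_def, subset)

    def test_idempotent(self, ffq_def, components):
        resp = simulate_ffq(1, adherence=0.5, seed=3)[0]
        a = score_dhd(resp, ffq_def, components)
        b = score_dhd(resp, ffq_def, components)
        assert a.component_scores == b.component_scores and a.total == b.total


class TestScoreNutrients:
    def test_rda_cap_floor_and_midpoint(self, ffq_def):
        rda = {"vitamin_b12": {"value": 2.8}}
        rda.update({n: {"value": 1.0} for n in ("vitamin_b6", "folate_eq", "vitamin_d", "iron")})
        rda["protein"] = {"value": 1.0}
        # fatty fish has 3.0 ug B12 per 100 g
        for grams, expected in ((0.0, 0.0), (2.8 / 3.0 * 100, 10.0), (2.8 / 6.0 * 100, 5.0)):
            resp = FfqResponse("p", {"fatty_fish": (7.0, grams)})
            scores = score_nutrients(resp, ffq_def, rda)
            assert scores["vitamin_b12"] == pytest.approx(expected)

    def test_per_kg_protein_requires_weight(self, ffq_def):
        with pytest.raises(SchemaError, match="weight"):
            score_nutrients(FfqResponse("p", {}), ffq_def, load_rda(), sex="male")

    def test_sex_specific_iron_rda(self, ffq_def):
        resp = FfqResponse("p", {"legumes_pulses": (7.0, 200.0)})  # 5 mg iron/day
        male = score_nutrients(resp, ffq_def, load_rda(), weight_kg=70, sex="male")
        female = score_nutrients(resp, ffq_def, load_rda(), weight_kg=60, sex="female")
        assert male["iron"] == pytest.approx(10 * 5.0 / 9.0)
        assert female["iron"] == pytest.approx(10 * 5.0 / 16.0)

    def test_intake_estimation_matches_hand_sum(self, ffq_def):
        resp = FfqResponse("p", {"milk": (7.0, 200.0), "cheese": (7.0, 50.0)})
        intakes = estimate_nutrient_intakes(resp, ffq_def)
        assert intakes["protein"] == pytest.approx(200 / 100 * 3.5 + 50 / 100 * 24)
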