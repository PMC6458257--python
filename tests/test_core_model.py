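"""Unit and property tests for the pathway time equations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msureach import (
    MsuParams,
    Scenario,
    UsualParams,
    classify_zone,
    evaluate_scenario,
    msu_ecr_time,
    msu_onscene_total,
    msu_tpa_time,
    usual_ecr_time,
    usual_tpa_time,
)
from msureach.geography import ConfigurationError, MatrixLookupError, TravelMatrix

from conftest import brute_force_evaluate, make_zero_travel_city, random_small_instance

minutes = st.floats(min_value=0, max_value=200, allow_nan=False)


class TestParams:
    def test_defaults_reproduce_base_configuration(self):
        p, u = MsuParams(), UsualParams()
        assert (p.scene_min, p.cta_min, p.ctp_min, p.tele_min, p.hub_proc_min) \
            == (30, 10, 0, 0, 30)
        assert u.fixed_tpa_min == 95
        assert u.fixed_ecr_min == 125

    @pytest.mark.parametrize("field", ["scene_min", "cta_min", "ctp_min",
                                       "tele_min", "hub_proc_min"])
    def test_msu_params_reject_negative_and_nonfinite(self, field):
        with pytest.raises(ValueError):
            MsuParams(**{field: -1.0})
        with pytest.raises(ValueError):
            MsuParams(**{field: float("nan")})

    @pytest.mark.parametrize("field", ["dispatch_min", "scene_min",
                                       "door_to_needle_min", "door_to_groin_min"])
    def test_usual_params_reject_negative(self, field):
        with pytest.raises(ValueError):
            UsualParams(**{field: -0.5})


class TestTimeEquations:
    @pytest.mark.parametrize("p,expected", [
        (MsuParams(), 40.0),
        (MsuParams(0, 0, 0, 0, 0), 0.0),
        (MsuParams(30, 10, 10, 15), 65.0),
    ])
    def test_msu_onscene_total(self, p, expected):
        assert msu_onscene_total(p) == expected

    @pytest.mark.parametrize("b2z,p,expected", [
        (0.0, MsuParams(), 40.0),
        (76.0, MsuParams(), 116.0),   # farthest-zone total under defaults
        (12.5, MsuParams(30, 10, 10, 15), 77.5),
    ])
    def test_msu_tpa_time(self, b2z, p, expected):
        assert msu_tpa_time(b2z, p) == expected

    def test_msu_tpa_rejects_negative_travel(self):
        with pytest.raises(ValueError):
            msu_tpa_time(-1.0, MsuParams())

    @pytest.mark.parametrize("b2z,hubs,expected", [
        (0.0, [0.0], 70.0),
        (20.0, [20.0, 35.0], 110.0),
    ])
    def test_msu_ecr_time(self, b2z, hubs, expected):
        assert msu_ecr_time(b2z, hubs, MsuParams()) == expected

    def test_msu_ecr_dominated_hub_is_irrelevant(self):
        p = MsuParams()
        assert msu_ecr_time(10, [15.0], p) == msu_ecr_time(10, [15.0, 40.0], p)

    def test_msu_ecr_empty_hub_list_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            msu_ecr_time(10, [], MsuParams())

    @pytest.mark.parametrize("travel,expected", [(0.0, 95.0), (21.0, 116.0)])
    def test_usual_tpa_time(self, travel, expected):
        assert usual_tpa_time(travel, UsualParams()) == expected

    def test_usual_tpa_zero_params_zero_travel(self):
        assert usual_tpa_time(0, UsualParams(0, 0, 0, 0)) == 0.0

    @pytest.mark.parametrize("travel,expected", [(0.0, 125.0), (30.0, 155.0)])
    def test_usual_ecr_time(self, travel, expected):
        assert usual_ecr_time(travel, UsualParams()) == expected

    def test_usual_ecr_shifts_uniformly_with_door_to_groin(self):
        u0, u1 = UsualParams(), UsualParams(door_to_groin_min=80)
        for t in [0.0, 7.5, 30.0, 62.0]:
            assert usual_ecr_time(t, u0) - usual_ecr_time(t, u1) == 10.0

    @given(b2z=minutes, hub=minutes)
    @settings(max_examples=50, deadline=None)
    def test_ecr_total_is_tpa_total_plus_hub_leg_and_processing(self, b2z, hub):
        p = MsuParams()
        assert msu_ecr_time(b2z, [hub], p) == \
            msu_tpa_time(b2z, p) + hub + p.hub_proc_min


class TestClassification:
    def test_strictly_faster_msu_is_superior(self):
        r = classify_zone("Z", 90, 130, 95, 120, 10)
        assert r.superior_tpa          # 90 < 95
        assert not r.superior_ecr      # 130 > 120

    @pytest.mark.parametrize("tie,expected", [(True, True), (False, False)])
    def test_tie_rule_is_explicit(self, tie, expected):
        r = classify_zone("Z", 95, 125, 95, 125, 10, tie_msu_superior=tie)
        assert r.superior_tpa is expected
        assert r.superior_ecr is expected

    def test_flags_match_brute_force_on_hand_instance(self, tiny_city,
                                                      tiny_scenario):
        zones, hospitals, matrix = tiny_city
        p, u = MsuParams(), UsualParams()
        results = evaluate_scenario(zones, hospitals, matrix, tiny_scenario, p, u)
        oracle = brute_force_evaluate(zones, hospitals, matrix, tiny_scenario, p, u)
        for r in results:
            exp = oracle[r.zone_id]
            assert (r.msu_tpa_min, r.msu_ecr_min, r.usual_tpa_min,
                    r.usual_ecr_min, r.superior_tpa, r.superior_ecr) == exp


class TestEvaluateScenario:
    def test_zero_travel_limit_all_superior(self):
        zones, hospitals, matrix, scenario = make_zero_travel_city(1)
        (r,) = evaluate_scenario(zones, hospitals, matrix, scenario)
        assert (r.msu_tpa_min, r.usual_tpa_min) == (40.0, 95.0)
        assert (r.msu_ecr_min, r.usual_ecr_min) == (70.0, 125.0)
        assert r.superior_tpa and r.superior_ecr

    def test_matches_brute_force_on_random_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            zones, hospitals, matrix, scenario, p, u = random_small_instance(rng)
            results = evaluate_scenario(zones, hospitals, matrix, scenario, p, u)
            oracle = brute_force_evaluate(zones, hospitals, matrix, scenario, p, u)
            for r in results:
                assert (r.msu_tpa_min, r.msu_ecr_min, r.usual_tpa_min,
                        r.usual_ecr_min, r.superior_tpa, r.superior_ecr) \
                    == oracle[r.zone_id]

    def test_two_hub_msu_ecr_never_slower_than_single_hub(self, tiny_city,
                                                          tiny_scenario):
        zones, hospitals, matrix = tiny_city
        single = dataclasses.replace(tiny_scenario, ecr_hub_ids=("HUB1",),
                                     usual_ecr_site_ids=("HUB1", "HUB2"))
        r2 = evaluate_scenario(zones, hospitals, matrix, tiny_scenario)
        r1 = evaluate_scenario(zones, hospitals, matrix, single)
        for a, b in zip(r2, r1):
            assert a.msu_ecr_min <= b.msu_ecr_min

    def test_missing_matrix_entry_names_the_pair(self, tiny_city, tiny_scenario):
        zones, hospitals, matrix = tiny_city
        holed = TravelMatrix({pair: v for pair, v in matrix.items()
                              if pair != ("Z2", "HUB2")})
        with pytest.raises(MatrixLookupError) as exc:
            evaluate_scenario(zones, hospitals, holed, tiny_scenario)
        assert "Z2" in str(exc.value) and "HUB2" in str(exc.value)

    def test_unknown_or_incapable_sites_rejected(self, tiny_city):
        zones, hospitals, matrix = tiny_city
        with pytest.raises(ConfigurationError):
            evaluate_scenario(zones, hospitals, matrix,
                              Scenario("NOPE", ("HUB1",), ("HUB1",)))
        with pytest.raises(ConfigurationError):
            # TPA1 is not ECR-capable, so it cannot be an MSU hub
            evaluate_scenario(zones, hospitals, matrix,
                              Scenario("HUB1", ("TPA1",), ("TPA1",)))

    def test_usual_travel_excluded_variant_uses_fixed_totals(self, tiny_city,
                                                             tiny_scenario):
        zones, hospitals, matrix = tiny_city
        fixed = dataclasses.replace(tiny_scenario, usual_travel_included=False)
        for r in evaluate_scenario(zones, hospitals, matrix, fixed):
            assert r.usual_tpa_min == 95.0
            assert r.usual_ecr_min == 125.0


class TestScenarioValidation:
    def test_hub_must_be_tpa_site(self):
        with pytest.raises(ConfigurationError):
            Scenario(base_id="A", ecr_hub_ids=("B",), tpa_site_ids=("A",))

    def test_empty_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            Scenario(base_id="A", ecr_hub_ids=(), tpa_site_ids=("A",))
        with pytest.raises(ConfigurationError):
            Scenario(base_id="A", ecr_hub_ids=("A",), tpa_site_ids=())
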