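import numpy as np
import pytest

from msureach import (
    Hospital,
    MsuParams,
    Scenario,
    SyntheticCityConfig,
    TravelMatrix,
    UsualParams,
    Zone,
    generate_synthetic_city,
)


@pytest.fixture(scope="session")
def default_city():
    """The shipped default synthetic city (200 zones, fixed seed)."""
    return generate_synthetic_city(SyntheticCityConfig(seed=7))


@pytest.fixture()
def tiny_city():
    """Hand-built 5-zone, 3-site instance with an explicit matrix."""
    zones = [Zone(f"Z{i}", lat=-37.8 + 0.01 * i, lon=145.0) for i in range(5)]
    hospitals = [
        Hospital("HUB1", "base hub", -37.8, 144.95, tpa_capable=True,
                 ecr_capable=True, is_msu_base=True),
        Hospital("HUB2", "second hub", -37.9, 145.1, tpa_capable=True,
                 ecr_capable=True),
        Hospital("TPA1", "tpa only", -37.7, 145.05, tpa_capable=True),
    ]
    entries = {}
    base_to_zone = [5.0, 18.0, 30.0, 47.0, 62.0]
    zone_to_site = {
        "HUB1": [6.0, 17.0, 31.0, 45.0, 60.0],
        "HUB2": [40.0, 28.0, 12.0, 20.0, 35.0],
        "TPA1": [25.0, 10.0, 8.0, 30.0, 21.0],
    }
    for i, z in enumerate(zones):
        entries[("HUB1", z.zone_id)] = base_to_zone[i]
        for sid, col in zone_to_site.items():
            entries[(z.zone_id, sid)] = col[i]
            entries[(sid, z.zone_id)] = col[i]
    return zones, hospitals, TravelMatrix(entries)


@pytest.fixture()
def tiny_scenario():
    return Scenario(base_id="HUB1", ecr_hub_ids=("HUB1", "HUB2"),
                    tpa_site_ids=("HUB1", "HUB2", "TPA1"))


def make_zero_travel_city(n_zones=1):
    """All-zero matrix: every zone co-located with every site."""
    zones = [Zone(f"Z{i}", lat=0.0, lon=0.0) for i in range(n_zones)]
    hospitals = [
        Hospital("HUB1", "base hub", 0.0, 0.0, tpa_capable=True,
                 ecr_capable=True, is_msu_base=True),
        Hospital("HUB2", "second hub", 0.0, 0.0, tpa_capable=True,
                 ecr_capable=True),
    ]
    entries = {}
    for z in zones:
        for h in hospitals:
            entries[(h.site_id, z.zone_id)] = 0.0
            entries[(z.zone_id, h.site_id)] = 0.0
    scenario = Scenario(base_id="HUB1", ecr_hub_ids=("HUB1", "HUB2"),
                        tpa_site_ids=("HUB1", "HUB2"))
    return zones, hospitals, TravelMatrix(entries), scenario


def random_small_instance(rng: np.random.Generator):
    """Random instance with <= 10 zones and <= 4 sites for oracle checks."""
    n_zones = int(rng.integers(1, 11))
    n_extra = int(rng.integers(0, 3))  # tPA-only sites beyond the two hubs
    zones = [Zone(f"Z{i}", lat=float(rng.uniform(-1, 1)),
                  lon=float(rng.uniform(-1, 1))) for i in range(n_zones)]
    hospitals = [
        Hospital("HUB1", "h1", 0.0, 0.0, tpa_capable=True, ecr_capable=True,
                 is_msu_base=True),
        Hospital("HUB2", "h2", 0.1, 0.1, tpa_capable=True, ecr_capable=True),
    ] + [Hospital(f"TPA{j}", f"t{j}", 0.2, 0.2, tpa_capable=True)
         for j in range(n_extra)]
    entries = {}
    for z in zones:
        for h in hospitals:
            entries[(h.site_id, z.zone_id)] = float(rng.uniform(0, 60))
            entries[(z.zone_id, h.site_id)] = float(rng.uniform(0, 60))
    n_hubs = int(rng.integers(1, 3))
    scenario = Scenario(
        base_id="HUB1",
        ecr_hub_ids=("HUB1", "HUB2")[:n_hubs],
        tpa_site_ids=tuple(h.site_id for h in hospitals),
        usual_ecr_site_ids=("HUB1", "HUB2"),
        tie_msu_superior=bool(rng.integers(0, 2)),
    )
    p = MsuParams(scene_min=float(rng.uniform(10, 40)),
                  cta_min=float(rng.uniform(0, 15)),
                  ctp_min=float(rng.uniform(0, 15)),
                  tele_min=float(rng.uniform(0, 30)),
                  hub_proc_min=float(rng.uniform(10, 40)))
    u = UsualParams(dispatch_min=float(rng.uniform(5, 25)),
                    scene_min=float(rng.uniform(10, 30)),
                    door_to_needle_min=float(rng.uniform(30, 75)),
                    door_to_groin_min=float(rng.uniform(60, 110)))
    return zones, hospitals, TravelMatrix(entries), scenario, p, u


def brute_force_evaluate(zones, hospitals, matrix, scenario, p, u):
    """Independent recomputation enumerating every destination choice.

    Computes each pathway total directly from raw parameters as a min over
    complete itineraries, without any nearest-site shortcut; used as the
    oracle against evaluate_scenario.
    """
    usual_ecr = (scenario.usual_ecr_site_ids
                 if scenario.usual_ecr_site_ids is not None
                 else scenario.ecr_hub_ids)
    out = {}
    for z in zones:
        b2z = matrix.minutes(scenario.base_id, z.zone_id)
        onscene = p.scene_min + p.cta_min + p.ctp_min + p.tele_min
        msu_tpa = b2z + onscene
        msu_ecr = min(b2z + onscene + matrix.minutes(z.zone_id, h) + p.hub_proc_min
                      for h in scenario.ecr_hub_ids)
        usual_tpa = min(u.dispatch_min + u.scene_min
                        + matrix.minutes(z.zone_id, s) + u.door_to_needle_min
                        for s in scenario.tpa_site_ids)
        usual_ecr_t = min(u.dispatch_min + u.scene_min
                          + matrix.minutes(z.zone_id, s) + u.door_to_groin_min
                          for s in usual_ecr)
        if scenario.tie_msu_superior:
            sup_tpa, sup_ecr = msu_tpa <= usual_tpa, msu_ecr <= usual_ecr_t
        else:
            sup_tpa, sup_ecr = msu_tpa < usual_tpa, msu_ecr < usual_ecr_t
        out[z.zone_id] = (msu_tpa, msu_ecr, usual_tpa, usual_ecr_t,
                          sup_tpa, sup_ecr)
    return out
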