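"""Alarm-to-reperfusion time equations and per-zone superiority classification.

Two linear pathways are compared for each zone, in minutes from alarm:

Mobile stroke unit (MSU), based at an ECR hub:
    tPA:  base->zone travel + on-scene total
          (thrombolysis is given at the scene; no hospital leg)
    ECR:  tPA total + min(zone->hub travel over the MSU's hub set)
          + hub processing

Conventional ambulance:
    tPA:  dispatch-to-patient + on-scene + zone->nearest thrombolysis site
          + door-to-needle
    ECR:  dispatch-to-patient + on-scene + zone->nearest ECR destination
          + door-to-groin

Under the defaults the travel-independent conventional components are
95 min (tPA) and 125 min (ECR) and the MSU on-scene total is 40 min.
A zone is "MSU-superior" for a treatment when the MSU total is strictly
smaller (ties counted as superior by default; configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .geography import (
    ConfigurationError,
    Hospital,
    TravelMatrix,
    Zone,
    nearest_site,
)

__all__ = [
    "MsuParams",
    "UsualParams",
    "Scenario",
    "ZoneResult",
    "msu_onscene_total",
    "msu_tpa_time",
    "msu_ecr_time",
    "usual_tpa_time",
    "usual_ecr_time",
    "classify_zone",
    "evaluate_scenario",
]


def _check_minutes(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class MsuParams:
    """On-scene and add-on durations (minutes) for the MSU pathway.

    scene_min covers patient processing at the scene including blood tests;
    cta_min is CT angiography set-up and acquisition; ctp_min and tele_min are
    optional CT perfusion and telemedicine add-ons (0 = absent; 10-15 min are
    typical enabled values); hub_proc_min is processing at the ECR hub on
    arrival (image review and angiography-suite set-up).
    """

    scene_min: float = 30.0
    cta_min: float = 10.0
    ctp_min: float = 0.0
    tele_min: float = 0.0
    hub_proc_min: float = 30.0

    def __post_init__(self) -> None:
        for name in ("scene_min", "cta_min", "ctp_min", "tele_min", "hub_proc_min"):
            object.__setattr__(self, name, _check_minutes(getattr(self, name), name))


@dataclass(frozen=True)
class UsualParams:
    """Fixed durations (minutes) for the conventional ambulance pathway."""

    dispatch_min: float = 15.0
    scene_min: float = 20.0
    door_to_needle_min: float = 60.0
    door_to_groin_min: float = 90.0

    def __post_init__(self) -> None:
        for name in ("dispatch_min", "scene_min", "door_to_needle_min",
                     "door_to_groin_min"):
            object.__setattr__(self, name, _check_minutes(getattr(self, name), name))

    @property
    def fixed_tpa_min(self) -> float:
        """Travel-independent tPA component (95 min under defaults)."""
        return self.dispatch_min + self.scene_min + self.door_to_needle_min

    @property
    def fixed_ecr_min(self) -> float:
        """Travel-independent ECR component (125 min under defaults)."""
        return self.dispatch_min + self.scene_min + self.door_to_groin_min


@dataclass(frozen=True)
class Scenario:
    """Site roles for one evaluation.

    ecr_hub_ids are the hubs the MSU may deliver to for thrombectomy (the
    single-hub scenario is the length-1 tuple). The conventional pathway's
    ECR destinations default to the same set but can be pinned independently
    via usual_ecr_site_ids — needed when comparing MSU hub policies against a
    fixed statewide two-hub protocol. With usual_travel_included=False the
    conventional totals use only the fixed components (a sensitivity variant
    in which the quoted 95/125 min are treated as travel-inclusive).
    """

    base_id: str
    ecr_hub_ids: tuple[str, ...]
    tpa_site_ids: tuple[str, ...]
    tie_msu_superior: bool = True
    usual_ecr_site_ids: tuple[str, ...] | None = None
    usual_travel_included: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "ecr_hub_ids", tuple(self.ecr_hub_ids))
        object.__setattr__(self, "tpa_site_ids", tuple(self.tpa_site_ids))
        if self.usual_ecr_site_ids is not None:
            object.__setattr__(self, "usual_ecr_site_ids",
                               tuple(self.usual_ecr_site_ids))
        if not self.ecr_hub_ids:
            raise ConfigurationError("ecr_hub_ids must be non-empty")
        if not self.tpa_site_ids:
            raise ConfigurationError("tpa_site_ids must be non-empty")
        missing = set(self.ecr_hub_ids) - set(self.tpa_site_ids)
        if missing:
            raise ConfigurationError(
                f"every ECR hub must also be a tPA site; not tPA-capable: {sorted(missing)}"
            )

    @property
    def effective_usual_ecr_site_ids(self) -> tuple[str, ...]:
        return self.usual_ecr_site_ids if self.usual_ecr_site_ids is not None \
            else self.ecr_hub_ids


@dataclass(frozen=True)
class ZoneResult:
    """Pathway totals and superiority flags for one zone."""

    zone_id: str
    msu_tpa_min: float
    msu_ecr_min: float
    usual_tpa_min: float
    usual_ecr_min: float
    superior_tpa: bool
    superior_ecr: bool
    base_to_zone_min: float
    nearest_tpa_site_id: str | None = None
    nearest_ecr_site_id: str | None = None


def msu_onscene_total(p: MsuParams) -> float:
    """Total MSU time at the patient's location (40 min under defaults)."""
    return p.scene_min + p.cta_min + p.ctp_min + p.tele_min


def msu_tpa_time(base_to_zone: float, p: MsuParams) -> float:
    """Alarm-to-needle for the MSU: travel to the scene plus on-scene total."""
    base_to_zone = _check_minutes(base_to_zone, "base_to_zone")
    return base_to_zone + msu_onscene_total(p)


def msu_ecr_time(base_to_zone: float, zone_to_hubs: Sequence[float],
                 p: MsuParams) -> float:
    """Alarm-to-groin for the MSU.

    The MSU treats at the scene then carries the patient to the closest of
    its candidate hubs; no further imaging is needed there, only hub
    processing. The single-hub scenario is the length-1 list.
    """
    if len(zone_to_hubs) == 0:
        raise ConfigurationError("zone_to_hubs must be non-empty")
    hub_leg = min(_check_minutes(t, "zone_to_hub") for t in zone_to_hubs)
    return msu_tpa_time(base_to_zone, p) + hub_leg + p.hub_proc_min


def usual_tpa_time(zone_to_nearest_tpa_site: float, u: UsualParams) -> float:
    """Alarm-to-needle for the conventional pathway."""
    t = _check_minutes(zone_to_nearest_tpa_site, "zone_to_nearest_tpa_site")
    return u.dispatch_min + u.scene_min + t + u.door_to_needle_min


def usual_ecr_time(zone_to_nearest_ecr_site: float, u: UsualParams) -> float:
    """Alarm-to-groin for the conventional pathway."""
    t = _check_minutes(zone_to_nearest_ecr_site, "zone_to_nearest_ecr_site")
    return u.dispatch_min + u.scene_min + t + u.door_to_groin_min


def _superior(msu: float, usual: float, tie_msu_superior: bool) -> bool:
    return msu < usual or (tie_msu_superior and msu == usual)


def classify_zone(zone_id: str, msu_tpa_min: float, msu_ecr_min: float,
                  usual_tpa_min: float, usual_ecr_min: float,
                  base_to_zone_min: float, tie_msu_superior: bool = True,
                  nearest_tpa_site_id: str | None = None,
                  nearest_ecr_site_id: str | None = None) -> ZoneResult:
    """Attach superiority flags to computed pathway totals."""
    return ZoneResult(
        zone_id=zone_id,
        msu_tpa_min=msu_tpa_min,
        msu_ecr_min=msu_ecr_min,
        usual_tpa_min=usual_tpa_min,
        usual_ecr_min=usual_ecr_min,
        superior_tpa=_superior(msu_tpa_min, usual_tpa_min, tie_msu_superior),
        superior_ecr=_superior(msu_ecr_min, usual_ecr_min, tie_msu_superior),
        base_to_zone_min=base_to_zone_min,
        nearest_tpa_site_id=nearest_tpa_site_id,
        nearest_ecr_site_id=nearest_ecr_site_id,
    )


def _validate_scenario_sites(scenario: Scenario,
                             hospitals: Sequence[Hospital]) -> dict[str, Hospital]:
    by_id = {h.site_id: h for h in hospitals}
    if len(by_id) != len(hospitals):
        raise ConfigurationError("duplicate site_id in hospital list")
    if scenario.base_id not in by_id:
        raise ConfigurationError(f"unknown MSU base {scenario.base_id!r}")
    for sid in scenario.ecr_hub_ids + scenario.effective_usual_ecr_site_ids:
        if sid not in by_id:
            raise ConfigurationError(f"unknown ECR site {sid!r}")
        if not by_id[sid].ecr_capable:
            raise ConfigurationError(f"site {sid!r} is not ECR-capable")
    for sid in scenario.tpa_site_ids:
        if sid not in by_id:
            raise ConfigurationError(f"unknown tPA site {sid!r}")
        if not by_id[sid].tpa_capable:
            raise ConfigurationError(f"site {sid!r} is not tPA-capable")
    return by_id


def evaluate_scenario(zones: Sequence[Zone], hospitals: Sequence[Hospital],
                      matrix: TravelMatrix, scenario: Scenario,
                      p: MsuParams | None = None,
                      u: UsualParams | None = None) -> list[ZoneResult]:
    """Evaluate both pathways for every zone and classify superiority.

    Deterministic given inputs; a missing matrix entry raises a
    MatrixLookupError naming the (origin, destination) pair — travel times
    are never imputed.
    """
    p = p if p is not None else MsuParams()
    u = u if u is not None else UsualParams()
    by_id = _validate_scenario_sites(scenario, hospitals)
    tpa_sites = [by_id[s] for s in sorted(set(scenario.tpa_site_ids))]
    usual_ecr_sites = [by_id[s] for s in
                       sorted(set(scenario.effective_usual_ecr_site_ids))]

    results: list[ZoneResult] = []
    for z in zones:
        b2z = matrix.minutes(scenario.base_id, z.zone_id)
        hub_legs = [matrix.minutes(z.zone_id, h) for h in scenario.ecr_hub_ids]
        tpa_site, t_tpa = nearest_site(z.zone_id, tpa_sites, matrix)
        ecr_site, t_ecr = nearest_site(z.zone_id, usual_ecr_sites, matrix)
        if not scenario.usual_travel_included:
            t_tpa = 0.0
            t_ecr = 0.0
        results.append(classify_zone(
            zone_id=z.zone_id,
            msu_tpa_min=msu_tpa_time(b2z, p),
            msu_ecr_min=msu_ecr_time(b2z, hub_legs, p),
            usual_tpa_min=usual_tpa_time(t_tpa, u),
            usual_ecr_min=usual_ecr_time(t_ecr, u),
            base_to_zone_min=b2z,
            tie_msu_superior=scenario.tie_msu_superior,
            nearest_tpa_site_id=tpa_site,
            nearest_ecr_site_id=ecr_site,
        ))
    return results
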