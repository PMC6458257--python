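"""Zones, hospitals, travel-time matrices and a seeded synthetic city.

Coordinates are WGS84 decimal degrees in ``(lat, lon)`` order throughout the
library and its CSV headers (GeoJSON output is the one place that uses the
standard ``[lon, lat]`` axis order).

The synthetic city is a monocentric metropolitan area: zone centroids whose
density decays away from a central business district, a mobile-stroke-unit
(MSU) base co-located with the first thrombectomy (ECR) hub near the centre,
a second ECR hub further out, and a ring of thrombolysis-only hospitals.
Travel times come from a congested-centre speed kernel over great-circle
distance, optionally perturbed by multiplicative log-normal noise, so that
base-to-zone times span roughly 5-80 minutes under the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius
KM_PER_DEG = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0


class ConfigurationError(ValueError):
    """Invalid scenario or generator configuration."""


class MatrixLookupError(KeyError):
    """A travel-time lookup for an absent (origin, destination) pair."""

    def __init__(self, origin: str, destination: str):
        self.origin = origin
        self.destination = destination
        super().__init__(f"no travel time for pair ({origin!r} -> {destination!r})")

    def __str__(self) -> str:  # KeyError would repr-quote the message
        return self.args[0]


def _check_lat_lon(lat: float, lon: float, what: str) -> None:
    if not (math.isfinite(lat) and -90.0 <= lat <= 90.0):
        raise ValueError(f"{what}: latitude {lat!r} outside [-90, 90]")
    if not (math.isfinite(lon) and -180.0 <= lon <= 180.0):
        raise ValueError(f"{what}: longitude {lon!r} outside [-180, 180]")


@dataclass(frozen=True)
class Zone:
    """A demand zone (postcode-like unit) represented by its centroid."""

    zone_id: str
    lat: float
    lon: float
    population: float | None = None

    def __post_init__(self) -> None:
        if not self.zone_id:
            raise ValueError("zone_id must be non-empty")
        _check_lat_lon(self.lat, self.lon, f"zone {self.zone_id!r}")
        if self.population is not None and self.population < 0:
            raise ValueError(f"zone {self.zone_id!r}: negative population")


@dataclass(frozen=True)
class Hospital:
    """A receiving site with capability flags.

    ``ecr_capable`` implies ``tpa_capable`` (a thrombectomy hub can always
    give thrombolysis); at most one site per scenario is the MSU base.
    """

    site_id: str
    name: str
    lat: float
    lon: float
    tpa_capable: bool = True
    ecr_capable: bool = False
    is_msu_base: bool = False

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        _check_lat_lon(self.lat, self.lon, f"site {self.site_id!r}")
        if self.ecr_capable and not self.tpa_capable:
            raise ValueError(
                f"site {self.site_id!r}: ecr_capable requires tpa_capable"
            )


class TravelMatrix:
    """Directed origin-destination travel times in minutes.

    Lookups of absent pairs raise :class:`MatrixLookupError`; nothing is ever
    imputed. Asymmetric inputs are supported (and arise from the noisy
    synthetic kernel); symmetry is neither assumed nor enforced, and neither
    is the triangle inequality.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        data: dict[tuple[str, str], float] = {}
        for (o, d), v in entries.items():
            v = float(v)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(
                    f"travel time {v!r} for ({o!r} -> {d!r}) must be finite and >= 0"
                )
            if o == d and v != 0.0:
                raise ValueError(f"diagonal entry ({o!r}, {o!r}) must be 0, got {v!r}")
            data[(str(o), str(d))] = v
        self._data = data

    def minutes(self, origin: str, destination: str) -> float:
        if origin == destination and (origin, destination) not in self._data:
            return 0.0
        try:
            return self._data[(origin, destination)]
        except KeyError:
            raise MatrixLookupError(origin, destination) from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._data or pair[0] == pair[1]

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TravelMatrix) and self._data == other._data

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self._data.items()))

    def origins(self) -> set[str]:
        return {o for o, _ in self._data}

    def destinations(self) -> set[str]:
        return {d for _, d in self._data}


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between ``(lat, lon)`` points."""
    _check_lat_lon(a[0], a[1], "point a")
    _check_lat_lon(b[0], b[1], "point b")
    lat1, lon1, lat2, lon2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


@dataclass(frozen=True)
class SyntheticCityConfig:
    """Parameters of the synthetic monocentric city.

    Speeds are km/h; the effective speed rises linearly from
    ``speed_center_kmh`` at the centre to ``speed_edge_kmh`` once the trip
    midpoint is ``speed_scale_km`` or further from the centre (congested core,
    free-flowing periphery). ``noise_sigma`` is the sigma of multiplicative
    log-normal noise on each directed travel time; 0 gives the deterministic
    kernel, under which the matrix is symmetric.
    """

    n_zones: int = 200
    city_radius_km: float = 40.0
    base_offset_km: float = 2.0
    second_hub_offset_km: float = 20.0
    n_tpa_only_sites: int = 6
    circuity_factor: float = 1.3
    speed_center_kmh: float = 25.0
    speed_edge_kmh: float = 60.0
    speed_scale_km: float = 20.0
    noise_sigma: float = 0.1
    seed: int = 0
    center_lat: float = -37.81
    center_lon: float = 144.96

    def __post_init__(self) -> None:
        if self.n_zones < 1:
            raise ConfigurationError("n_zones must be >= 1")
        for name in ("city_radius_km", "circuity_factor", "speed_center_kmh",
                     "speed_edge_kmh", "speed_scale_km"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        _check_lat_lon(self.center_lat, self.center_lon, "city centre")

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_lat, self.center_lon)


def _offset_point(cfg: SyntheticCityConfig, dist_km: float, bearing_rad: float
                  ) -> tuple[float, float]:
    """Point ``dist_km`` from the city centre at the given bearing.

    Local equirectangular approximation; adequate at metropolitan scale.
    """
    dlat = dist_km * math.cos(bearing_rad) / KM_PER_DEG
    dlon = dist_km * math.sin(bearing_rad) / (KM_PER_DEG * math.cos(math.radians(cfg.center_lat)))
    return (cfg.center_lat + dlat, cfg.center_lon + dlon)


def travel_minutes(a: tuple[float, float], b: tuple[float, float],
                   cfg: SyntheticCityConfig, noise_z: float = 0.0) -> float:
    """Synthetic travel time in minutes between ``(lat, lon)`` points.

    minutes = 60 * (haversine_km * circuity) / v_eff * exp(noise_sigma * z)
    with v_eff interpolated by the trip midpoint's distance from the centre.
    """
    d = haversine_km(a, b)
    if d == 0.0:
        return 0.0
    mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    d_mid = haversine_km(mid, cfg.center)
    frac = min(d_mid / cfg.speed_scale_km, 1.0)
    v_eff = cfg.speed_center_kmh + (cfg.speed_edge_kmh - cfg.speed_center_kmh) * frac
    noise = math.exp(cfg.noise_sigma * noise_z)
    return 60.0 * (d * cfg.circuity_factor) / v_eff * noise


# fixed site bearings (radians); deterministic layout, not seed-dependent
_BASE_BEARING = 0.35
_SECOND_HUB_BEARING = 2.4


def generate_synthetic_city(cfg: SyntheticCityConfig
                            ) -> tuple[list[Zone], list[Hospital], TravelMatrix]:
    """Generate a reproducible monocentric city.

    Zone radial distances are drawn as |Normal(0, city_radius_km/2)| truncated
    (by rejection) at ``city_radius_km``, with uniform angles, so density
    decays away from the centre. The matrix covers base<->zone and
    zone<->site in both directions for every zone and site.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.city_radius_km / 2.0

    zones: list[Zone] = []
    width = max(3, len(str(cfg.n_zones)))
    for i in range(cfg.n_zones):
        r = abs(rng.normal(0.0, sigma))
        while r > cfg.city_radius_km:
            r = abs(rng.normal(0.0, sigma))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        lat, lon = _offset_point(cfg, r, theta)
        pop = float(np.round(rng.uniform(2000, 30000) * math.exp(-r / cfg.city_radius_km)))
        zones.append(Zone(zone_id=f"Z{i:0{width}d}", lat=lat, lon=lon, population=pop))

    b_lat, b_lon = _offset_point(cfg, cfg.base_offset_km, _BASE_BEARING)
    h2_lat, h2_lon = _offset_point(cfg, cfg.second_hub_offset_km, _SECOND_HUB_BEARING)
    hospitals = [
        Hospital("HUB1", "Central ECR hub (MSU base)", b_lat, b_lon,
                 tpa_capable=True, ecr_capable=True, is_msu_base=True),
        Hospital("HUB2", "Second ECR hub", h2_lat, h2_lon,
                 tpa_capable=True, ecr_capable=True),
    ]
    ring = cfg.city_radius_km / 2.0
    for j in range(cfg.n_tpa_only_sites):
        bearing = 2.0 * math.pi * (j + 0.5) / max(cfg.n_tpa_only_sites, 1)
        s_lat, s_lon = _offset_point(cfg, ring, bearing)
        hospitals.append(Hospital(f"TPA{j + 1}", f"Thrombolysis hospital {j + 1}",
                                  s_lat, s_lon, tpa_capable=True))

    points: dict[str, tuple[float, float]] = {z.zone_id: (z.lat, z.lon) for z in zones}
    points.update({h.site_id: (h.lat, h.lon) for h in hospitals})

    entries: dict[tuple[str, str], float] = {}
    # deterministic pair order => deterministic noise stream
    for z in zones:
        for h in hospitals:
            for o, d in ((h.site_id, z.zone_id), (z.zone_id, h.site_id)):
                zdraw = rng.standard_normal() if cfg.noise_sigma > 0 else 0.0
                entries[(o, d)] = travel_minutes(points[o], points[d], cfg, zdraw)
    return zones, hospitals, TravelMatrix(entries)


def nearest_site(zone_id: str, sites: Sequence[Hospital], matrix: TravelMatrix,
                 capability_filter: Callable[[Hospital], bool] | None = None
                 ) -> tuple[str, float]:
    """Nearest site by zone->site minutes among sites passing the filter.

    Ties are broken by lexicographic site_id so the choice is deterministic.
    """
    candidates = [s for s in sites if capability_filter is None or capability_filter(s)]
    if not candidates:
        raise ConfigurationError(
            f"no site passes the capability filter for zone {zone_id!r}"
        )
    best = min(candidates, key=lambda s: (matrix.minutes(zone_id, s.site_id), s.site_id))
    return best.site_id, matrix.minutes(zone_id, best.site_id)


def required_pairs(zones: Iterable[Zone], base_id: str,
                   site_ids: Iterable[str]) -> list[tuple[str, str]]:
    """All (origin, destination) pairs a scenario evaluation will request."""
    site_ids = sorted(set(site_ids))
    pairs: list[tuple[str, str]] = []
    for z in zones:
        pairs.append((base_id, z.zone_id))
        for sid in site_ids:
            pairs.append((z.zone_id, sid))
    return pairs


def missing_pairs(matrix: TravelMatrix, zones: Iterable[Zone], base_id: str,
                  site_ids: Iterable[str]) -> list[tuple[str, str]]:
    """Pairs required by an evaluation but absent from the matrix."""
    return [p for p in required_pairs(zones, base_id, site_ids) if p not in matrix]
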