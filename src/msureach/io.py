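"""File formats and configuration.

CSV schemas (header required, coordinates in WGS84 decimal degrees,
``lat,lon`` column order):

* zones:      ``zone_id,lat,lon[,population]``
* hospitals:  ``site_id,name,lat,lon,tpa_capable,ecr_capable,is_msu_base``
* matrix:     long dialect ``origin,destination,minutes`` (canonical), or
              wide dialect origins x destinations with a header row/column.

GeoJSON output follows RFC 7946: Point features with ``[lon, lat]``
coordinate order. All writes are atomic (temp file then rename) so a failed
run leaves no partial artifact.
"""

from __future__ import annotations

import csv
import json
import math
import os
import tempfile
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterator, Protocol, Sequence

import yaml

from .core_model import MsuParams, Scenario, UsualParams, ZoneResult
from .geography import (
    ConfigurationError,
    Hospital,
    SyntheticCityConfig,
    TravelMatrix,
    Zone,
    travel_minutes,
)
from .sweep import display_class

__all__ = [
    "read_zones", "write_zones", "read_hospitals", "write_hospitals",
    "read_matrix", "write_matrix", "export_geojson", "results_to_frame",
    "RunConfig", "CityFiles", "read_config", "write_config",
    "default_scenario", "MatrixProvider", "SyntheticMatrixProvider",
    "atomic_write",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


@contextmanager
def atomic_write(path: str | os.PathLike) -> Iterator[Path]:
    """Yield a temp path in the target directory; rename into place on
    success, remove on failure."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    tmp = Path(tmp)
    try:
        yield tmp
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise


def _parse_bool(text: str, where: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {text!r}")


def _parse_float(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"{where}: cannot parse number {text!r}") from None


def _read_rows(path: str | os.PathLike, required: Sequence[str]
               ) -> tuple[list[str], list[dict[str, str]]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a CSV header")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        return list(reader.fieldnames), list(reader)


def read_zones(path: str | os.PathLike) -> list[Zone]:
    header, rows = _read_rows(path, ["zone_id", "lat", "lon"])
    zones: list[Zone] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        where = f"{path} row {i}"
        zid = (row["zone_id"] or "").strip()
        if zid in seen:
            raise ValueError(f"{where}: duplicate zone_id {zid!r}")
        seen.add(zid)
        pop_text = (row.get("population") or "").strip()
        try:
            zones.append(Zone(
                zone_id=zid,
                lat=_parse_float(row["lat"], where),
                lon=_parse_float(row["lon"], where),
                population=_parse_float(pop_text, where) if pop_text else None,
            ))
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from None
    return zones


def write_zones(zones: Sequence[Zone], path: str | os.PathLike) -> None:
    with atomic_write(path) as tmp:
        with open(tmp, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["zone_id", "lat", "lon", "population"])
            for z in zones:
                w.writerow([z.zone_id, repr(z.lat), repr(z.lon),
                            "" if z.population is None else repr(z.population)])


_HOSPITAL_COLS = ["site_id", "name", "lat", "lon",
                  "tpa_capable", "ecr_capable", "is_msu_base"]


def read_hospitals(path: str | os.PathLike) -> list[Hospital]:
    header, rows = _read_rows(path, _HOSPITAL_COLS)
    hospitals: list[Hospital] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        where = f"{path} row {i}"
        sid = (row["site_id"] or "").strip()
        if sid in seen:
            raise ValueError(f"{where}: duplicate site_id {sid!r}")
        seen.add(sid)
        try:
            hospitals.append(Hospital(
                site_id=sid,
                name=(row["name"] or "").strip(),
                lat=_parse_float(row["lat"], where),
                lon=_parse_float(row["lon"], where),
                tpa_capable=_parse_bool(row["tpa_capable"], where),
                ecr_capable=_parse_bool(row["ecr_capable"], where),
                is_msu_base=_parse_bool(row["is_msu_base"], where),
            ))
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from None
    return hospitals


def write_hospitals(hospitals: Sequence[Hospital], path: str | os.PathLike) -> None:
    with atomic_write(path) as tmp:
        with open(tmp, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_HOSPITAL_COLS)
            for h in hospitals:
                w.writerow([h.site_id, h.name, repr(h.lat), repr(h.lon),
                            str(h.tpa_capable).lower(),
                            str(h.ecr_capable).lower(),
                            str(h.is_msu_base).lower()])


def read_matrix(path: str | os.PathLike, dialect: str = "long") -> TravelMatrix:
    if dialect == "long":
        header, rows = _read_rows(path, ["origin", "destination", "minutes"])
        entries: dict[tuple[str, str], float] = {}
        for i, row in enumerate(rows, start=2):
            where = f"{path} row {i}"
            v = _parse_float(row["minutes"], where)
            if v < 0:
                raise ValueError(f"{where}: negative minutes {v!r}")
            entries[(row["origin"].strip(), row["destination"].strip())] = v
        return TravelMatrix(entries)
    if dialect == "wide":
        with open(path, newline="") as fh:
            reader = list(csv.reader(fh))
        if not reader:
            raise ValueError(f"{path}: empty file")
        dests = [c.strip() for c in reader[0][1:]]
        entries = {}
        for i, row in enumerate(reader[1:], start=2):
            origin = row[0].strip()
            for j, cell in enumerate(row[1:]):
                if cell.strip() == "":
                    continue  # absent pair
                where = f"{path} cell (row {i}, column {dests[j]!r})"
                v = _parse_float(cell, where)
                if v < 0:
                    raise ValueError(f"{where}: negative minutes {v!r}")
                entries[(origin, dests[j])] = v
        return TravelMatrix(entries)
    raise ValueError(f"unknown matrix dialect {dialect!r} (use 'long' or 'wide')")


def write_matrix(matrix: TravelMatrix, path: str | os.PathLike,
                 dialect: str = "long") -> None:
    if dialect == "long":
        with atomic_write(path) as tmp:
            with open(tmp, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["origin", "destination", "minutes"])
                for (o, d), v in matrix.items():
                    w.writerow([o, d, repr(v)])
        return
    if dialect == "wide":
        origins = sorted(matrix.origins())
        dests = sorted(matrix.destinations())
        with atomic_write(path) as tmp:
            with open(tmp, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["origin"] + dests)
                for o in origins:
                    row: list[str] = [o]
                    for d in dests:
                        row.append(repr(matrix.minutes(o, d)) if (o, d) in matrix else "")
                    w.writerow(row)
        return
    raise ValueError(f"unknown matrix dialect {dialect!r} (use 'long' or 'wide')")


def results_to_frame(single: Sequence[ZoneResult],
                     multi: Sequence[ZoneResult]):
    """Per-zone table combining single- and two-hub MSU evaluations."""
    import pandas as pd

    if [r.zone_id for r in single] != [r.zone_id for r in multi]:
        raise ValueError("single- and multi-hub results cover different zones")
    return pd.DataFrame({
        "zone_id": [r.zone_id for r in single],
        "base_to_zone_min": [r.base_to_zone_min for r in single],
        "msu_tpa_min": [r.msu_tpa_min for r in single],
        "usual_tpa_min": [r.usual_tpa_min for r in single],
        "msu_ecr_single_min": [r.msu_ecr_min for r in single],
        "msu_ecr_multi_min": [r.msu_ecr_min for r in multi],
        "usual_ecr_min": [r.usual_ecr_min for r in single],
        "superior_tpa": [r.superior_tpa for r in single],
        "superior_ecr_single": [r.superior_ecr for r in single],
        "superior_ecr_multi": [r.superior_ecr for r in multi],
        "display_class": [display_class(r) for r in single],
    })


def export_geojson(zones: Sequence[Zone], single: Sequence[ZoneResult],
                   multi: Sequence[ZoneResult], path: str | os.PathLike) -> None:
    """Write per-zone results as an RFC 7946 FeatureCollection of Points.

    Coordinates are ``[lon, lat]``; properties carry both pathway totals and
    the superiority flags for the single- and two-hub MSU scenarios plus a
    ``display_class`` colour (green/yellow/blue).
    """
    by_zone = {z.zone_id: z for z in zones}
    s_by_id = {r.zone_id: r for r in single}
    m_by_id = {r.zone_id: r for r in multi}
    if set(by_zone) != set(s_by_id) or set(by_zone) != set(m_by_id):
        raise ValueError("zones and results must cover the same zone_ids")
    features = []
    for z in zones:
        s, m = s_by_id[z.zone_id], m_by_id[z.zone_id]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [z.lon, z.lat]},
            "properties": {
                "zone_id": z.zone_id,
                "msu_tpa_min": s.msu_tpa_min,
                "usual_tpa_min": s.usual_tpa_min,
                "msu_ecr_min": s.msu_ecr_min,
                "msu_ecr_multi_min": m.msu_ecr_min,
                "usual_ecr_min": s.usual_ecr_min,
                "superior_tpa": s.superior_tpa,
                "superior_ecr_single": s.superior_ecr,
                "superior_ecr_multi": m.superior_ecr,
                "display_class": display_class(s),
            },
        })
    doc = {"type": "FeatureCollection", "features": features}
    with atomic_write(path) as tmp:
        tmp.write_text(json.dumps(doc, indent=2))


# --------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class CityFiles:
    """Paths to an externally supplied city (zones, hospitals, matrix)."""

    zones: str
    hospitals: str
    matrix: str
    matrix_dialect: str = "long"


@dataclass(frozen=True)
class RunConfig:
    """A complete, reproducible run description.

    Exactly one of ``synthetic`` (generator block) or ``files`` (paths) must
    be present. ``scenario`` may be omitted for synthetic cities, in which
    case it is derived from the generated capability flags. The config
    round-trips losslessly through YAML with all defaults made explicit.
    """

    seed: int = 0
    output_dir: str = "out"
    synthetic: SyntheticCityConfig | None = None
    files: CityFiles | None = None
    msu: MsuParams = field(default_factory=MsuParams)
    usual: UsualParams = field(default_factory=UsualParams)
    scenario: Scenario | None = None
    sweep: list[tuple[MsuParams, UsualParams]] | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.files is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' and 'files' must be configured")

    def to_dict(self) -> dict:
        d: dict = {"seed": self.seed, "output_dir": self.output_dir,
                   "msu": asdict(self.msu), "usual": asdict(self.usual)}
        if self.synthetic is not None:
            d["city"] = {"synthetic": asdict(self.synthetic)}
        else:
            d["city"] = {"files": asdict(self.files)}
        if self.scenario is not None:
            s = asdict(self.scenario)
            s["ecr_hub_ids"] = list(s["ecr_hub_ids"])
            s["tpa_site_ids"] = list(s["tpa_site_ids"])
            if s["usual_ecr_site_ids"] is not None:
                s["usual_ecr_site_ids"] = list(s["usual_ecr_site_ids"])
            d["scenario"] = s
        if self.sweep is not None:
            d["sweep"] = [{"msu": asdict(p), "usual": asdict(u)}
                          for p, u in self.sweep]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        city = d.get("city") or {}
        synthetic = files = None
        if "synthetic" in city:
            synthetic = SyntheticCityConfig(**city["synthetic"])
        if "files" in city:
            files = CityFiles(**city["files"])
        scenario = None
        if "scenario" in d and d["scenario"] is not None:
            scenario = Scenario(**d["scenario"])
        sweep = None
        if "sweep" in d and d["sweep"] is not None:
            sweep = [(MsuParams(**(e.get("msu") or {})),
                      UsualParams(**(e.get("usual") or {})))
                     for e in d["sweep"]]
        return cls(seed=int(d.get("seed", 0)),
                   output_dir=str(d.get("output_dir", "out")),
                   synthetic=synthetic, files=files,
                   msu=MsuParams(**(d.get("msu") or {})),
                   usual=UsualParams(**(d.get("usual") or {})),
                   scenario=scenario, sweep=sweep)


def read_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    with atomic_write(path) as tmp:
        tmp.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def default_scenario(hospitals: Sequence[Hospital],
                     tie_msu_superior: bool = True) -> Scenario:
    """Derive a scenario from capability flags: the flagged MSU base, all
    ECR-capable sites as hubs (base first), all tPA-capable sites."""
    bases = [h.site_id for h in hospitals if h.is_msu_base]
    if len(bases) != 1:
        raise ConfigurationError(
            f"expected exactly one is_msu_base site, found {len(bases)}")
    base = bases[0]
    hubs = sorted(h.site_id for h in hospitals if h.ecr_capable)
    if base in hubs:
        hubs = [base] + [h for h in hubs if h != base]
    tpa = tuple(sorted(h.site_id for h in hospitals if h.tpa_capable))
    return Scenario(base_id=base, ecr_hub_ids=tuple(hubs), tpa_site_ids=tpa,
                    tie_msu_superior=tie_msu_superior)


# --------------------------------------------------------------------------
# travel-time provider contract

class MatrixProvider(Protocol):
    """Contract for travel-time backends.

    Implementations resolve batches of coordinate pairs to minutes and must
    be deterministic within a run (or document otherwise). The synthetic
    kernel provider is the only in-repo implementation; adapters for hosted
    distance-matrix services plug in here without touching the model.
    """

    name: str
    max_batch: int

    def travel_minutes(self, pairs: Sequence[tuple[tuple[float, float],
                                                   tuple[float, float]]]
                       ) -> list[float]: ...


class SyntheticMatrixProvider:
    """Deterministic provider backed by the synthetic speed kernel."""

    def __init__(self, cfg: SyntheticCityConfig):
        self.cfg = cfg
        self.name = "synthetic-kernel"
        self.max_batch = 10_000

    def travel_minutes(self, pairs):
        return [travel_minutes(a, b, self.cfg) for a, b in pairs]
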