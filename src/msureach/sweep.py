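"""Coverage statistics, operating range and parameter sweeps.

Coverage counts zones (suburbs), unweighted, where the MSU pathway beats the
conventional one; percentages are reported to one decimal, rounded half-up.
The sweep engine evaluates a grid of (MSU, conventional) parameter settings,
each under both a single-hub and a two-hub MSU thrombectomy destination set
with the conventional pathway pinned to the full hub protocol, producing
rows in the layout of a sensitivity table: fixed conventional components,
MSU add-on minutes, and the three superiority percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import pandas as pd

from .core_model import (
    MsuParams,
    Scenario,
    UsualParams,
    ZoneResult,
    evaluate_scenario,
)
from .geography import Hospital, TravelMatrix, Zone

__all__ = [
    "CoverageResult",
    "SweepRow",
    "coverage",
    "max_operating_range",
    "run_sweep",
    "boundary_partition",
    "display_class",
    "table1_grid",
    "sweep_to_frame",
    "SWEEP_COLUMNS",
]


def round_pct(n_superior: int, n_zones: int) -> float:
    """100 * n_superior / n_zones, rounded half-up to one decimal (exactly)."""
    q = (Decimal(100) * Decimal(n_superior) / Decimal(n_zones))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageResult:
    """Zone-count coverage for one treatment comparison."""

    n_zones: int
    n_superior: int
    pct: float
    max_range_min: float | None = None


def _flag(r: ZoneResult, which: str) -> bool:
    if which == "tpa":
        return r.superior_tpa
    if which == "ecr":
        return r.superior_ecr
    raise ValueError(f"which must be 'tpa' or 'ecr', got {which!r}")


def coverage(results: Sequence[ZoneResult], which: Literal["tpa", "ecr"],
             matrix: TravelMatrix | None = None,
             base_id: str | None = None,
             weights: dict[str, float] | None = None) -> CoverageResult:
    """Fraction of zones where the MSU is superior for the given treatment.

    Zones are weighted equally by default (suburb count, not population);
    pass per-zone ``weights`` for a population-weighted variant, in which
    case pct is the weighted share rounded the same way. When ``matrix`` and
    ``base_id`` are given, max_range_min is the maximum base->zone travel
    time over superior zones (None if none are superior).
    """
    if not results:
        raise ValueError("coverage of an empty result list is undefined")
    flags = [_flag(r, which) for r in results]
    n_sup = sum(flags)
    if weights is None:
        pct = round_pct(n_sup, len(results))
    else:
        total = sum(weights[r.zone_id] for r in results)
        sup = sum(weights[r.zone_id] for r, f in zip(results, flags) if f)
        q = Decimal(100) * Decimal(str(sup)) / Decimal(str(total))
        pct = float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    max_range = None
    if matrix is not None and base_id is not None:
        max_range = max_operating_range(
            [r for r, f in zip(results, flags) if f] or None, matrix, base_id,
            prefiltered=True)
    return CoverageResult(n_zones=len(results), n_superior=n_sup, pct=pct,
                          max_range_min=max_range)


def max_operating_range(results: Sequence[ZoneResult] | None,
                        matrix: TravelMatrix, base_id: str,
                        prefiltered: bool = False) -> float | None:
    """Maximum base->zone travel time over zones MSU-superior for tPA.

    Returns None when no zone qualifies. With ``prefiltered=True`` the input
    is taken as the already-filtered superior set.
    """
    if results is None:
        return None
    pool = results if prefiltered else [r for r in results if r.superior_tpa]
    if not pool:
        return None
    return max(matrix.minutes(base_id, r.zone_id) for r in pool)


@dataclass(frozen=True)
class SweepRow:
    """One sweep setting and its three superiority percentages."""

    usual_fixed_tpa_min: float
    usual_fixed_ecr_min: float
    msu_scene_min: float
    cta_min: float
    ctp_min: float
    tele_min: float
    pct_superior_tpa: float
    pct_superior_ecr_single: float
    pct_superior_ecr_multi: float


SWEEP_COLUMNS = [
    "usual_fixed_tpa_min", "usual_fixed_ecr_min",
    "msu_scene_min", "cta_min", "ctp_min", "tele_min",
    "pct_superior_tpa", "pct_superior_ecr_single", "pct_superior_ecr_multi",
]


def _single_hub_scenario(scenario: Scenario) -> Scenario:
    """Restrict the MSU to its first hub; the conventional pathway keeps the
    full hub protocol."""
    return replace(scenario,
                   ecr_hub_ids=(scenario.ecr_hub_ids[0],),
                   usual_ecr_site_ids=scenario.effective_usual_ecr_site_ids)


def run_sweep(grid: Sequence[tuple[MsuParams, UsualParams]],
              zones: Sequence[Zone], hospitals: Sequence[Hospital],
              matrix: TravelMatrix, scenario: Scenario) -> list[SweepRow]:
    """Evaluate every grid setting under single- and multi-hub MSU scenarios.

    Rows are independent and deterministic; the grid is an explicit list (not
    a cross-product) so irregular sensitivity tables can be reproduced
    verbatim from a config file.
    """
    single = _single_hub_scenario(scenario)
    rows: list[SweepRow] = []
    for i, entry in enumerate(grid):
        try:
            p, u = entry
            if not isinstance(p, MsuParams) or not isinstance(u, UsualParams):
                raise TypeError("expected (MsuParams, UsualParams)")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid sweep grid entry at row {i}: {exc}") from exc
        multi_res = evaluate_scenario(zones, hospitals, matrix, scenario, p, u)
        single_res = evaluate_scenario(zones, hospitals, matrix, single, p, u)
        rows.append(SweepRow(
            usual_fixed_tpa_min=u.fixed_tpa_min,
            usual_fixed_ecr_min=u.fixed_ecr_min,
            msu_scene_min=p.scene_min,
            cta_min=p.cta_min,
            ctp_min=p.ctp_min,
            tele_min=p.tele_min,
            pct_superior_tpa=coverage(multi_res, "tpa").pct,
            pct_superior_ecr_single=coverage(single_res, "ecr").pct,
            pct_superior_ecr_multi=coverage(multi_res, "ecr").pct,
        ))
    return rows


def sweep_to_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    """Sweep rows as a DataFrame in the canonical column order."""
    return pd.DataFrame([vars(r) for r in rows], columns=SWEEP_COLUMNS)


def display_class(single_result: ZoneResult) -> str:
    """Map display colour: blue = MSU superior for ECR back at base,
    green = superior for tPA only, yellow = inferior."""
    if single_result.superior_ecr:
        return "blue"
    if single_result.superior_tpa:
        return "green"
    return "yellow"


def boundary_partition(single_results: Sequence[ZoneResult],
                       multi_results: Sequence[ZoneResult] | None = None
                       ) -> dict[str, list[str]]:
    """Group zones into map display classes.

    The tPA layer partitions all zones into superior/inferior; the ECR
    classes are overlays (single-hub, and two-hub when given), mirroring a
    layer-toggle display.
    """
    if not single_results:
        raise ValueError("boundary_partition of empty results is undefined")
    groups: dict[str, list[str]] = {
        "superior_tpa": [r.zone_id for r in single_results if r.superior_tpa],
        "inferior_tpa": [r.zone_id for r in single_results if not r.superior_tpa],
        "superior_ecr_single": [r.zone_id for r in single_results if r.superior_ecr],
    }
    if multi_results is not None:
        groups["superior_ecr_multi"] = [r.zone_id for r in multi_results
                                        if r.superior_ecr]
    return groups


def table1_grid() -> list[tuple[MsuParams, UsualParams]]:
    """The canonical sensitivity grid: three conventional-pathway blocks
    (fixed tPA/ECR components 95/125, 85/115, 75/105 min) crossed with an
    irregular set of CT-perfusion and telemedicine add-ons."""
    def usual(fixed_tpa: float) -> UsualParams:
        delta = 95.0 - fixed_tpa
        return UsualParams(door_to_needle_min=60.0 - delta,
                           door_to_groin_min=90.0 - delta)

    def msu(ctp: float = 0.0, tele: float = 0.0) -> MsuParams:
        return MsuParams(ctp_min=ctp, tele_min=tele)

    return [
        (msu(), usual(95)),
        (msu(ctp=10), usual(95)),
        (msu(tele=10), usual(95)),
        (msu(ctp=10, tele=10), usual(95)),
        (msu(tele=20), usual(95)),
        (msu(tele=30), usual(95)),
        (msu(), usual(85)),
        (msu(tele=10), usual(85)),
        (msu(tele=20), usual(85)),
        (msu(), usual(75)),
        (msu(tele=10), usual(75)),
        (msu(tele=20), usual(75)),
    ]
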