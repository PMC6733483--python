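"""Multi-method track fusion and dispersal-behavior classification.

Satellite (Argos) positions are filtered (drop class Z, drop on-land
fixes, greedy forward speed filter), then merged with "known" positions
derived from the other two methods: each acoustic detection-day becomes
a class-2 pseudo-position at the centroid of the stations that heard
the shark that day, and each visual encounter becomes a class-3
pseudo-position at the survey site.  The fused track supports a simple
rule-based classification of dispersal behavior — local-only, same-year
excursion and return, interannual return, multi-year return, permanent
emigrant, or emigrant that left the basin entirely.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .types import ARGOS_ACCURACY_RANK, ArgosPosition, PositionSource, ValidationError

EARTH_RADIUS_KM = 6371.0

BEHAVIORS = (
    "local_only",
    "excursion_return_same_year",
    "interannual_return",
    "multi_year_return",
    "emigrant",
    "emigrant_left_basin",
)


def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points."""
    lat1, lon1, lat2, lon2 = map(np.radians, (*p1, *p2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def filter_argos(
    positions: Sequence[ArgosPosition],
    land: Optional[Polygon] = None,
    vmax_ms: float = 4.0,
) -> list[ArgosPosition]:
    """Filter one shark's time-sorted Argos series.

    Three passes in order: (1) drop error class Z; (2) drop fixes inside
    the land polygon, if one is supplied; (3) greedy forward speed
    filter — walk the series keeping a point only if the implied speed
    from the last kept point is <= ``vmax_ms`` (the first surviving
    point is always kept).  Idempotent and order-preserving.
    """
    step = [p for p in positions if p.error_class != "Z"]
    if land is not None:
        step = [p for p in step if not land.contains(Point(p.lon, p.lat))]
    out: list[ArgosPosition] = []
    for p in step:
        if not out:
            out.append(p)
            continue
        prev = out[-1]
        dt_s = (p.timestamp - prev.timestamp).total_seconds()
        dist_m = haversine_km((prev.lat, prev.lon), (p.lat, p.lon)) * 1000.0
        if dt_s <= 0:
            if dist_m == 0.0:
                out.append(p)  # duplicate instant at same place is compliant
            continue
        if dist_m / dt_s <= vmax_ms:
            out.append(p)
    return out


@dataclass
class FusedTrack:
    shark_id: str
    positions: list[ArgosPosition] = field(default_factory=list)
    home: tuple[float, float] = (0.0, 0.0)
    behavior: Optional[str] = None
    max_displacement_km: Optional[float] = None


def merge_known_positions(
    shark_id: str,
    argos_filtered: Sequence[ArgosPosition],
    detection_days: dict[dt.date, list[tuple[float, float]]],
    encounter_days: dict[dt.date, tuple[float, float]],
    timezone_offset_hours: int = 3,
) -> list[ArgosPosition]:
    """Merge Argos fixes with acoustic/visual pseudo-positions.

    ``detection_days`` maps a detection day to the coordinates of the
    stations that heard the shark that day (centroid used);
    ``encounter_days`` maps an encounter day to the survey-site
    coordinates.  Pseudo-positions are timestamped local noon and carry
    class C2 (acoustic, ~500 m) or C3 (visual, ~250 m).  Duplicate
    same-instant points collapse to the most accurate class.
    """
    positions: list[ArgosPosition] = list(argos_filtered)
    warnings: list[str] = []
    for day, coords in sorted(detection_days.items()):
        coords = [c for c in coords if c is not None]
        if not coords:
            warnings.append(f"{shark_id} {day}: acoustic day with no station coordinates")
            continue
        lat = float(np.mean([c[0] for c in coords]))
        lon = float(np.mean([c[1] for c in coords]))
        ts = dt.datetime.combine(day, dt.time(12)) - dt.timedelta(hours=timezone_offset_hours)
        positions.append(
            ArgosPosition(shark_id, ts, lat, lon, "C2", PositionSource.ACOUSTIC_PSEUDO)
        )
    for day, (lat, lon) in sorted(encounter_days.items()):
        ts = dt.datetime.combine(day, dt.time(12)) - dt.timedelta(hours=timezone_offset_hours)
        positions.append(
            ArgosPosition(shark_id, ts, lat, lon, "C3", PositionSource.VISUAL_PSEUDO)
        )
    positions.sort(key=lambda p: (p.timestamp, -ARGOS_ACCURACY_RANK[p.error_class]))
    deduped: list[ArgosPosition] = []
    for p in positions:
        if deduped and deduped[-1].timestamp == p.timestamp:
            continue  # first entry at this instant has the better class
        deduped.append(p)
    return deduped


def classify_behavior(
    track: FusedTrack,
    home: tuple[float, float],
    return_days_by_year: dict[int, bool],
    local_km: float = 100.0,
    basin: Optional[Polygon] = None,
) -> str:
    """Rule-based dispersal-behavior label.

    ``return_days_by_year`` records, per calendar year, whether the
    shark produced any evidence of presence at the aggregation site
    (acoustic detection, visual encounter, or filtered position within
    ``local_km`` of home).

    Rules, in order: never displaced beyond ``local_km`` → local_only;
    left the basin polygon and never re-detected at home afterwards →
    emigrant_left_basin; otherwise, by return evidence after the first
    departure year: >= 2 later years → multi_year_return, exactly >= 1
    later year → interannual_return, same-year only →
    excursion_return_same_year, none → emigrant.
    """
    if not track.positions:
        raise ValidationError(f"shark {track.shark_id}: empty track")
    displacements = [haversine_km(home, (p.lat, p.lon)) for p in track.positions]
    track.max_displacement_km = float(max(displacements))
    track.home = home
    if track.max_displacement_km < local_km:
        track.behavior = "local_only"
        return track.behavior
    departures = [
        p for p, d in zip(track.positions, displacements) if d >= local_km
    ]
    first_departure = min(departures, key=lambda p: p.timestamp)
    first_departure_year = first_departure.timestamp.year
    later_return_years = sorted(
        y for y, present in return_days_by_year.items()
        if present and y > first_departure_year
    )
    # home evidence after the first departure but within the same year
    same_year_return = any(
        d < local_km
        and p.timestamp > first_departure.timestamp
        and p.timestamp.year == first_departure_year
        for p, d in zip(track.positions, displacements)
    )
    if basin is not None:
        left_basin = any(
            not basin.contains(Point(p.lon, p.lat)) for p in track.positions
        )
        if left_basin and not later_return_years and not same_year_return:
            track.behavior = "emigrant_left_basin"
            return track.behavior
    if len(later_return_years) >= 2:
        track.behavior = "multi_year_return"
    elif len(later_return_years) == 1:
        track.behavior = "interannual_return"
    elif same_year_return:
        track.behavior = "excursion_return_same_year"
    else:
        track.behavior = "emigrant"
    return track.behavior


def monthly_latitude_summary(
    tracks: Iterable[FusedTrack],
) -> dict[int, tuple[list[float], int]]:
    """Pooled per-calendar-month latitude samples and shark counts.

    Returns month (1–12) → (list of position latitudes across years,
    number of distinct sharks contributing that month).
    """
    lats: dict[int, list[float]] = {m: [] for m in range(1, 13)}
    sharks: dict[int, set[str]] = {m: set() for m in range(1, 13)}
    for tr in tracks:
        for p in tr.positions:
            m = p.timestamp.month
            lats[m].append(p.lat)
            sharks[m].add(tr.shark_id)
    return {m: (lats[m], len(sharks[m])) for m in range(1, 13)}
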