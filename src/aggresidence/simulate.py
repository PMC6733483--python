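"""Synthetic telemetry scenario generator with known ground truth.

The generator emulates the data structure of a multi-year passive
acoustic study of a seasonal reef aggregation monitored by a ~63-station
receiver array in seven geographic regions, with sparse spring boat
surveys and Argos satellite tracking of a subset of animals:

* seasonal presence following a von-Mises-shaped annual cycle (peak
  week and concentration are parameters), peaking in boreal spring;
* range-dependent detection with a logistic distance curve calibrated
  so that detection probability is 0.5 at a station's nominal range
  (defaults 540 m for inshore-side stations, 230 m offshore);
* transmitters pinging at Uniform(60, 180) s random intervals;
* receiver outages, linear receiver clock drift, tag loss with a daily
  hazard, and Argos positional noise by error class (plus a fraction of
  unusable class-Z fixes);
* scripted per-shark dispersal behaviors (local residents, same-year
  excursions, interannual and multi-year returners, emigrants, and
  emigrants leaving the basin) with mostly-southward off-season drift.

Everything is driven by one global seed with independent per-stream
substreams, so the emitted files are byte-identical across runs and
each component can be regenerated independently.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import core_io
from .types import (
    ArgosPosition,
    ClockRecord,
    Detection,
    EndReason,
    PositionSource,
    Shark,
    Station,
    StudyWindow,
    TagDeployment,
)

KM_PER_DEG_LAT = 111.19


@dataclass
class SimConfig:
    """Scenario parameters; defaults describe the emulated multi-year study design."""

    seed: int = 0
    n_sharks: int = 85
    #: fractions of the tagged population by sex (remainder undetermined)
    female_fraction: float = 0.42
    male_fraction: float = 0.44
    length_mean_m: float = 4.0
    length_sd_m: float = 0.8
    #: stations per geographic region (63 total)
    region_counts: dict[str, int] = field(
        default_factory=lambda: {
            "exposed": 6,
            "sheltered": 6,
            "inshore": 3,
            "north_shelf": 4,
            "south_shelf": 7,
            "abu_latt": 3,
            "offshore": 34,
        }
    )
    inshore_range_m: float = 540.0
    offshore_range_m: float = 230.0
    #: logistic steepness of the detection-range curve (per meter)
    range_curve_scale_m: float = 150.0
    home_lat: float = 20.1
    home_lon: float = 40.0
    #: seasonal presence cycle: P(at site) = peak_prob * exp(kappa*(cos-1))
    peak_week: float = 14.0
    kappa: float = 4.0
    peak_prob: float = 0.8
    start: dt.date = dt.date(2010, 4, 1)
    years: int = 6
    transmission_interval_s: tuple[float, float] = (60.0, 180.0)
    #: hours per present day a shark actually spends at its daily
    #: position inside the array (it roams beyond range the rest)
    station_visit_hours: float = 2.0
    outage_rate: float = 0.01  # per station-day
    tag_loss_hazard: float = 0.002  # per day
    clock_offset_sd_s: float = 45.0
    download_interval_days: int = 180
    #: fraction of sharks carrying a satellite transmitter
    satellite_fraction: float = 0.45
    argos_rate_per_day: float = 0.8
    argos_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Z": 0.08, "B": 0.22, "A": 0.18, "C0": 0.16,
            "C1": 0.14, "C2": 0.12, "C3": 0.10,
        }
    )
    #: 1-sigma positional noise per class, km
    argos_class_sd_km: dict[str, float] = field(
        default_factory=lambda: {
            "Z": 50.0, "B": 10.0, "A": 5.0, "C0": 2.5,
            "C1": 1.0, "C2": 0.5, "C3": 0.25,
        }
    )
    #: scripted behavior mix (must sum to <= 1; remainder local_only)
    behavior_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "excursion_return_same_year": 0.05,
            "interannual_return": 0.25,
            "multi_year_return": 0.10,
            "emigrant": 0.20,
            "emigrant_left_basin": 0.07,
        }
    )
    offseason_lat_drift_deg: float = 4.5  # southward drift of dispersers
    #: km scatter of a present shark's daily position around the site core
    site_scatter_km: float = 2.2
    survey_sighting_prob: float = 0.35
    basin_south_lat: float = 12.5

    @property
    def window(self) -> StudyWindow:
        end = dt.date(self.start.year + self.years, self.start.month, self.start.day)
        return StudyWindow(self.start, end)

    def streams(self) -> dict[str, np.random.Generator]:
        names = ("array", "sharks", "presence", "detection", "outage",
                 "argos", "survey", "clock", "tagloss")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


@dataclass
class GroundTruth:
    presence_days: dict[str, list[str]] = field(default_factory=dict)
    tag_loss_day: dict[str, Optional[str]] = field(default_factory=dict)
    behavior: dict[str, str] = field(default_factory=dict)
    outage_days: dict[str, list[str]] = field(default_factory=dict)
    daily_position: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "presence_days": self.presence_days,
                "tag_loss_day": self.tag_loss_day,
                "behavior": self.behavior,
                "outage_days": self.outage_days,
                "daily_position": self.daily_position,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class Scenario:
    config: SimConfig
    stations: list[Station]
    sharks: list[Shark]
    deployments: list[TagDeployment]
    detections: list[Detection]  # timestamp_raw carries clock drift
    encounters: list
    argos: list[ArgosPosition]
    clocks: list[ClockRecord]
    survey_days: list[tuple[dt.date, float]]
    loss_evidence: list[tuple[str, dt.date, str]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# array

def build_array(config: SimConfig, rng: np.random.Generator) -> tuple[list[Station], GroundTruth]:
    """Lay out stations around the site and assign outage days.

    Inshore-side regions sit within ~15 km of the aggregation core;
    offshore reefs scatter 20–60 km out.  Active intervals cover the
    whole window minus sampled outage days.
    """
    window = config.window
    truth = GroundTruth()
    stations = []
    offsets_km = {
        "exposed": (0.0, 2.0), "sheltered": (2.5, 2.0), "inshore": (6.0, 3.0),
        "north_shelf": (12.0, 4.0), "south_shelf": (-12.0, 4.0),
        "abu_latt": (18.0, 5.0),
    }
    all_days = window.dates()
    for region, count in config.region_counts.items():
        for i in range(count):
            if region == "offshore":
                bearing = rng.uniform(0, 2 * math.pi)
                dist = rng.uniform(20.0, 60.0)
                dy, dx = dist * math.cos(bearing), dist * math.sin(bearing)
                rng_m = config.offshore_range_m
            else:
                base, spread = offsets_km[region]
                dy = base + rng.normal(0, spread / 2)
                dx = rng.normal(0, spread / 2)
                rng_m = config.inshore_range_m
            lat = config.home_lat + dy / KM_PER_DEG_LAT
            lon = config.home_lon + dx / (KM_PER_DEG_LAT * math.cos(math.radians(config.home_lat)))
            sid = f"{region[:2].upper()}{i + 1:02d}"
            outages = sorted(
                d for d in all_days[1:-1] if rng.random() < config.outage_rate
            )
            intervals = _intervals_excluding(window, outages)
            stations.append(
                Station(sid, region, lat, lon, intervals, rng_m)
            )
            truth.outage_days[sid] = [d.isoformat() for d in outages]
    return stations, truth


def _intervals_excluding(
    window: StudyWindow, excluded: list[dt.date]
) -> list[tuple[dt.datetime, dt.datetime]]:
    intervals = []
    start: Optional[dt.date] = None
    excluded_set = set(excluded)
    for d in window.dates():
        if d in excluded_set:
            if start is not None:
                intervals.append(_day_interval(start, d))
                start = None
        elif start is None:
            start = d
    if start is not None:
        intervals.append(_day_interval(start, window.end + dt.timedelta(days=1)))
    return intervals


def _day_interval(start: dt.date, end_exclusive: dt.date):
    return (
        dt.datetime.combine(start, dt.time.min),
        dt.datetime.combine(end_exclusive, dt.time.min),
    )


# ---------------------------------------------------------------------------
# sharks

def simulate_sharks(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[Shark], list[TagDeployment], dict[str, str]]:
    """Tagged population with sizes, sexes and scripted behaviors.

    Tagging dates fall in the spring aggregation season of the first
    ``years - 1`` study years (a shark tagged on the last day could
    never show a return).
    """
    sharks, deployments = [], []
    labels = _assign_behaviors(config, rng)
    for i in range(config.n_sharks):
        sid = f"WS{i + 1:03d}"
        u = rng.random()
        sex = "F" if u < config.female_fraction else (
            "M" if u < config.female_fraction + config.male_fraction else "U"
        )
        length = float(np.clip(rng.normal(config.length_mean_m, config.length_sd_m), 3.0, 7.0))
        year = config.start.year + int(rng.integers(0, max(1, config.years - 1)))
        doy = int(rng.integers(60, 150))  # spring tagging trips
        tag_date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
        if tag_date < config.start:
            tag_date = config.start + dt.timedelta(days=int(rng.integers(0, 60)))
        t0 = dt.datetime.combine(tag_date, dt.time(10, 0))
        dep = TagDeployment(tag_id=f"T{i + 1:04d}", shark_id=sid, start=t0, end=None)
        shark = Shark(sid, sex, length, [dep])
        sharks.append(shark)
        deployments.append(dep)
    return sharks, deployments, labels


def _assign_behaviors(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    labels = {}
    kinds = list(config.behavior_fractions)
    probs = np.array([config.behavior_fractions[k] for k in kinds])
    for i in range(config.n_sharks):
        u = rng.random()
        acc = 0.0
        label = "local_only"
        for k, p in zip(kinds, probs):
            acc += p
            if u < acc:
                label = k
                break
        labels[f"WS{i + 1:03d}"] = label
    return labels


# ---------------------------------------------------------------------------
# presence

def seasonal_presence_prob(week: float, config: SimConfig) -> float:
    """Von-Mises-shaped annual presence probability, peak at peak_week."""
    theta = 2 * math.pi * (week - config.peak_week) / 52.0
    return config.peak_prob * math.exp(config.kappa * (math.cos(theta) - 1.0))


#: latitude-drift amplitude (degrees south of home) by scripted behavior
def _drift_amplitude(config: SimConfig, label: str) -> float:
    if label == "local_only":
        return 0.3  # stays well inside the local radius
    if label == "emigrant_left_basin":
        return config.home_lat - config.basin_south_lat + 2.5
    if label == "emigrant":
        return config.home_lat - config.basin_south_lat - 0.5
    return config.offseason_lat_drift_deg  # returners


def simulate_presence(
    config: SimConfig,
    sharks: list[Shark],
    labels: dict[str, str],
    rng: np.random.Generator,
) -> GroundTruth:
    """Daily true state per shark: at the site, or dispersed along a
    latitude trajectory determined by its scripted behavior.

    Behaviors script which calendar years a shark frequents the site:
    residents every year; same-year-excursion sharks only their tagging
    year (with a mid-season excursion to ~300 km); interannual
    returners their tagging year plus one later year; multi-year
    returners three consecutive years; emigrants only until their first
    off-season departure.  Outside its site years a shark stays at
    least several hundred km away, so it can generate no spurious
    return evidence.
    """
    from .occupancy import week_of_year  # pure helper, no circularity

    window = config.window
    truth = GroundTruth(behavior=dict(labels))
    for shark in sharks:
        sid = shark.shark_id
        tag_date = window.local_date(shark.first_tagged)
        label = labels[sid]
        site_years = _site_years(label, tag_date.year, window)
        amplitude = _drift_amplitude(config, label)
        presence: list[str] = []
        daily: dict[str, tuple[float, float]] = {}
        for d in window.dates():
            if d < tag_date:
                continue
            w = week_of_year(d)
            phase = 0.5 * (1 - math.cos(2 * math.pi * (w - config.peak_week) / 52.0))
            excursion = _excursion_phase(config, label, d, tag_date.year)
            at_site = False
            if d.year in site_years and excursion is None:
                at_site = rng.random() < seasonal_presence_prob(w, config)
            if at_site:
                jitter = rng.normal(0, config.site_scatter_km, 2)
                lat = config.home_lat + jitter[0] / KM_PER_DEG_LAT
                lon = config.home_lon + jitter[1] / (
                    KM_PER_DEG_LAT * math.cos(math.radians(config.home_lat))
                )
                presence.append(d.isoformat())
            else:
                if excursion is not None:
                    lat_off = 2.7 * excursion
                elif d.year in site_years or any(y > d.year for y in site_years):
                    lat_off = amplitude * phase  # drifts out and back
                else:
                    # no future site year: stay far away for good
                    lat_off = amplitude * max(phase, 0.7)
                lat = config.home_lat - lat_off + rng.normal(0, 0.15)
                lon = config.home_lon + rng.normal(0, 0.25)
            daily[d.isoformat()] = (float(lat), float(lon))
        truth.presence_days[sid] = presence
        truth.daily_position[sid] = daily
    return truth


def _site_years(label: str, first_year: int, window: StudyWindow) -> set[int]:
    years = list(range(first_year, window.end.year + 1))
    if label == "local_only":
        return set(years)
    if label == "excursion_return_same_year":
        return {first_year}
    if label == "interannual_return":
        return set(years[:2])
    if label == "multi_year_return":
        return set(years[:3])
    return {first_year}  # emigrants: present only until first departure


def _excursion_phase(
    config: SimConfig, label: str, d: dt.date, first_year: int
) -> Optional[float]:
    """Triangular 0→1→0 profile of the scripted same-year excursion
    (weeks peak+2 .. peak+8 of the tagging year); None outside it."""
    if label != "excursion_return_same_year" or d.year != first_year:
        return None
    from .occupancy import week_of_year

    w = week_of_year(d)
    lo, hi = config.peak_week + 2, config.peak_week + 8
    if not (lo <= w <= hi):
        return None
    half = (hi - lo) / 2
    return 1.0 - abs(w - (lo + half)) / half


# ---------------------------------------------------------------------------
# detections

def detection_probability(distance_m: float, nominal_range_m: float, scale_m: float) -> float:
    """Logistic range curve with P = 0.5 exactly at the nominal range."""
    return 1.0 / (1.0 + math.exp((distance_m - nominal_range_m) / scale_m))


def _station_distance_m(lat1, lon1, lat2, lon2) -> float:
    dy = (lat2 - lat1) * KM_PER_DEG_LAT
    dx = (lon2 - lon1) * KM_PER_DEG_LAT * math.cos(math.radians(lat1))
    return math.hypot(dy, dx) * 1000.0


def n_transmissions_in(seconds: float, config: SimConfig, rng: np.random.Generator) -> int:
    """Renewal count for Uniform(lo, hi) inter-transmission gaps."""
    lo, hi = config.transmission_interval_s
    mean = (lo + hi) / 2.0
    n_guess = int(seconds / lo) + 2
    gaps = rng.uniform(lo, hi, size=n_guess)
    total = np.cumsum(gaps)
    return int(np.searchsorted(total, seconds))


def simulate_detections(
    config: SimConfig,
    stations: list[Station],
    sharks: list[Shark],
    truth: GroundTruth,
    tag_loss_day: dict[str, Optional[str]],
    rng: np.random.Generator,
) -> list[Detection]:
    """Per present shark-day, binomially thinned per-transmission
    detections at every in-range active station.

    For each present day the number of transmissions is drawn from the
    Uniform(60, 180) s renewal process; each active station within
    acoustic range logs each transmission independently with the
    logistic range probability.  Detection timestamps are uniform over
    the day.  Days after tag loss emit nothing.
    """
    tag_of = {s.shark_id: s.tagging_events[0].tag_id for s in sharks}
    detections: list[Detection] = []
    day_seconds = 86400.0
    visit_seconds = config.station_visit_hours * 3600.0
    for shark in sharks:
        sid = shark.shark_id
        loss = tag_loss_day.get(sid)
        loss_date = dt.date.fromisoformat(loss) if loss else None
        for day_iso in truth.presence_days.get(sid, []):
            day = dt.date.fromisoformat(day_iso)
            if loss_date is not None and day > loss_date:
                continue
            lat, lon = truth.daily_position[sid][day_iso]
            n_trans = n_transmissions_in(visit_seconds, config, rng)
            if n_trans == 0:
                continue
            day_start = dt.datetime.combine(day, dt.time.min)
            for st in stations:
                dist = _station_distance_m(lat, lon, st.lat, st.lon)
                if dist > st.nominal_range_m + 8 * config.range_curve_scale_m:
                    continue
                p = detection_probability(dist, st.nominal_range_m, config.range_curve_scale_m)
                k = int(rng.binomial(n_trans, p))
                if k == 0:
                    continue
                offsets = np.sort(rng.uniform(0, day_seconds, size=k))
                for off in offsets:
                    t_true = day_start + dt.timedelta(seconds=float(off))
                    if not st.is_active_at(t_true):
                        continue
                    detections.append(Detection(tag_of[sid], st.station_id, t_true))
    detections.sort(key=lambda d: (d.timestamp_raw, d.tag_id, d.station_id))
    return detections


def apply_clock_drift(
    detections: list[Detection],
    stations: list[Station],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[Detection], list[ClockRecord]]:
    """Shift true timestamps by linear receiver drift; emit clock records.

    Each station is 'downloaded' every ``download_interval_days``; the
    clock reads true time at each initialization and drifts linearly to
    a Normal(0, clock_offset_sd_s) offset at the next download.
    """
    window = config.window
    clocks: list[ClockRecord] = []
    per_station: dict[str, list[ClockRecord]] = {}
    t0 = dt.datetime.combine(window.start, dt.time.min)
    t_end = dt.datetime.combine(window.end + dt.timedelta(days=1), dt.time.min)
    for st in stations:
        t = t0
        recs = []
        while t < t_end:
            t_next = min(t + dt.timedelta(days=config.download_interval_days), t_end)
            recs.append(
                ClockRecord(st.station_id, t, t_next, float(rng.normal(0, config.clock_offset_sd_s)))
            )
            t = t_next
        clocks.extend(recs)
        per_station[st.station_id] = recs
    drifted = []
    for d in detections:
        rec = next(
            (c for c in per_station[d.station_id] if c.init_time <= d.timestamp_raw < c.download_time),
            None,
        )
        if rec is None:
            drifted.append(d)
            continue
        span = (rec.download_time - rec.init_time).total_seconds()
        frac = (d.timestamp_raw - rec.init_time).total_seconds() / span
        raw = d.timestamp_raw + dt.timedelta(seconds=rec.offset_at_download_s * frac)
        drifted.append(Detection(d.tag_id, d.station_id, raw))
    return drifted, clocks


# ---------------------------------------------------------------------------
# tag loss, surveys, Argos

def simulate_tag_loss(
    config: SimConfig,
    sharks: list[Shark],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[dict[str, Optional[str]], list[tuple[str, dt.date, str]]]:
    """Geometric(hazard) tag-retention; lost tags may yield resighting
    evidence (an untagged resighting some weeks later)."""
    window = config.window
    loss_day: dict[str, Optional[str]] = {}
    evidence: list[tuple[str, dt.date, str]] = []
    for shark in sharks:
        sid = shark.shark_id
        tag_date = window.local_date(shark.first_tagged)
        days_at_liberty = (window.end - tag_date).days
        if config.tag_loss_hazard <= 0:
            loss_day[sid] = None
            continue
        k = int(rng.geometric(config.tag_loss_hazard))
        if k >= days_at_liberty:
            loss_day[sid] = None
            continue
        d = tag_date + dt.timedelta(days=k)
        loss_day[sid] = d.isoformat()
        ev = d + dt.timedelta(days=int(rng.integers(20, 120)))
        if ev <= window.end and rng.random() < 0.6:
            evidence.append((sid, ev, "resighted_untagged"))
    truth.tag_loss_day = loss_day
    return loss_day, evidence


def simulate_surveys(
    config: SimConfig,
    sharks: list[Shark],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[list, list[tuple[dt.date, float]]]:
    """Weekly spring boat surveys; present sharks sighted independently."""
    window = config.window
    survey_days: list[tuple[dt.date, float]] = []
    d = window.start
    while d <= window.end:
        if 3 <= d.month <= 5 and d.weekday() == 2:  # weekly spring trips
            survey_days.append((d, 1.0))
        d += dt.timedelta(days=1)
    encounters = []
    from .types import VisualEncounter

    for day, units in survey_days:
        iso = day.isoformat()
        for shark in sharks:
            if iso in set(truth.presence_days.get(shark.shark_id, [])):
                if rng.random() < config.survey_sighting_prob:
                    encounters.append(VisualEncounter(shark.shark_id, day, units))
    return encounters, survey_days


def simulate_argos(
    config: SimConfig,
    sharks: list[Shark],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[list[ArgosPosition], set[str]]:
    """Argos fixes for the satellite-tagged subset, with class-specific
    Gaussian noise and a configured share of class-Z junk."""
    window = config.window
    classes = list(config.argos_class_probs)
    probs = np.array([config.argos_class_probs[c] for c in classes])
    probs = probs / probs.sum()
    positions = []
    sat_tagged: set[str] = set()
    for shark in sharks:
        sid = shark.shark_id
        # dispersing sharks carry satellite tags preferentially, as in
        # studies that target double-tagging at likely migrants
        p_sat = config.satellite_fraction
        if truth.behavior.get(sid, "local_only") != "local_only":
            p_sat = min(1.0, config.satellite_fraction * 2)
        if rng.random() >= p_sat:
            continue
        sat_tagged.add(sid)
        for day_iso, (lat, lon) in truth.daily_position[sid].items():
            if rng.random() >= config.argos_rate_per_day:
                continue
            cls = classes[int(rng.choice(len(classes), p=probs))]
            sd_km = config.argos_class_sd_km[cls]
            noisy_lat = lat + rng.normal(0, sd_km / KM_PER_DEG_LAT)
            noisy_lon = lon + rng.normal(0, sd_km / (KM_PER_DEG_LAT * math.cos(math.radians(lat))))
            t = dt.datetime.combine(dt.date.fromisoformat(day_iso), dt.time.min) + dt.timedelta(
                seconds=float(rng.uniform(0, 86400))
            )
            positions.append(ArgosPosition(sid, t, float(noisy_lat), float(noisy_lon), cls))
    positions.sort(key=lambda p: (p.shark_id, p.timestamp))
    return positions, sat_tagged


# ---------------------------------------------------------------------------
# scenario assembly

def build_scenario(config: SimConfig) -> Scenario:
    """Simulate all streams; fully reproducible from ``config.seed``."""
    streams = config.streams()
    stations, array_truth = build_array(config, streams["array"])
    sharks, deployments, labels = simulate_sharks(config, streams["sharks"])
    truth = simulate_presence(config, sharks, labels, streams["presence"])
    truth.outage_days = array_truth.outage_days
    loss_day, evidence = simulate_tag_loss(config, sharks, truth, streams["tagloss"])
    detections = simulate_detections(
        config, stations, sharks, truth, loss_day, streams["detection"]
    )
    detections, clocks = apply_clock_drift(detections, stations, config, streams["clock"])
    encounters, survey_days = simulate_surveys(config, sharks, truth, streams["survey"])
    argos, _sat = simulate_argos(config, sharks, truth, streams["argos"])
    return Scenario(
        config=config,
        stations=stations,
        sharks=sharks,
        deployments=deployments,
        detections=detections,
        encounters=encounters,
        argos=argos,
        clocks=clocks,
        survey_days=survey_days,
        loss_evidence=evidence,
        truth=truth,
    )


def emit_scenario(config: SimConfig, outdir) -> Scenario:
    """Write the complete file set plus ground truth to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = build_scenario(config)
    core_io.write_detections(sc.detections, out / "detections.csv")
    core_io.write_stations(sc.stations, out / "stations.csv")
    core_io.write_deployments(sc.deployments, sc.sharks, out / "deployments.csv")
    core_io.write_encounters(sc.encounters, out / "encounters.csv")
    core_io.write_argos(sc.argos, out / "argos.csv")
    core_io.write_clocks(sc.clocks, out / "clocks.csv")
    (out / "groundtruth.json").write_text(sc.truth.to_json())
    evidence_rows = "\n".join(
        f"{sid},{d.isoformat()},{kind}" for sid, d, kind in sc.loss_evidence
    )
    (out / "loss_evidence.csv").write_text("shark_id,date,kind\n" + evidence_rows + "\n")
    surveys = "\n".join(f"{d.isoformat()},{u}" for d, u in sc.survey_days)
    (out / "surveys.csv").write_text("date,effort_units\n" + surveys + "\n")
    return sc
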