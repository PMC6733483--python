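"""Residence indices and station-level summaries.

A residence index is the number of days an animal was detected divided
by the number of days it was monitored.  Because passive telemetry
never observes the true monitoring endpoint (a silent tag may be shed,
or the animal may simply be elsewhere), two bracketing indices are
always computed and reported together:

* ``r_min`` — days detected / days from tagging to **study end**
  (maximum possible monitoring period; lower bound on residency);
* ``r_max`` — days detected / days from tagging to **last detection**
  (minimum monitoring period; upper bound on residency).

The true (unobservable) residency fraction lies between the two.
``r_spatial`` apportions an animal's array-detection days among
stations, excluding from a station's denominator the array-detection
days on which that station was not monitoring.

Day counts are inclusive of both endpoints: the tagging day is
monitored day 1.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import Detection, Shark, StudyWindow, TagDeployment, ValidationError


@dataclass
class ResidencyRecord:
    shark_id: str
    days_detected: set[dt.date] = field(default_factory=set)
    days_detected_by_station: dict[str, set[dt.date]] = field(default_factory=dict)
    tagging_date: Optional[dt.date] = None
    monitoring_days_max: Optional[int] = None  # tagging → study end, inclusive
    monitoring_days_min: Optional[int] = None  # tagging → last detection, inclusive
    r_min: Optional[float] = None
    r_max: Optional[float] = None
    r_spatial: dict[str, Optional[float]] = field(default_factory=dict)


def detection_days(
    detections: Iterable[Detection],
    tag_to_shark: dict[str, str],
    window: StudyWindow,
) -> dict[str, tuple[set[dt.date], dict[str, set[dt.date]]]]:
    """Collapse detections to calendar days (local offset) per shark.

    Returns, per shark, the array-wide day set and per-station subsets.
    """
    out: dict[str, tuple[set[dt.date], dict[str, set[dt.date]]]] = {}
    for d in detections:
        shark_id = tag_to_shark.get(d.tag_id)
        if shark_id is None:
            continue
        day = window.local_date(d.timestamp)
        array_days, by_station = out.setdefault(shark_id, (set(), {}))
        array_days.add(day)
        by_station.setdefault(d.station_id, set()).add(day)
    return out


def r_min(n_days_detected: int, tagging_date: dt.date, study_end: dt.date) -> Optional[float]:
    """Minimum residence index: detected days over tagging→study-end."""
    denom = (study_end - tagging_date).days + 1
    if denom <= 0:
        return None
    return n_days_detected / denom


def r_max(
    n_days_detected: int, tagging_date: dt.date, last_detection: Optional[dt.date]
) -> Optional[float]:
    """Maximum residence index: detected days over tagging→last-detection.

    Undefined (None) for sharks never detected — the denominator does
    not exist, which is not the same as zero residency.
    """
    if last_detection is None or n_days_detected == 0:
        return None
    denom = (last_detection - tagging_date).days + 1
    if denom <= 0:
        return None
    return n_days_detected / denom


def r_spatial(
    station_days: set[dt.date],
    array_days: set[dt.date],
    station_active_days: set[dt.date],
) -> Optional[float]:
    """Spatial residence index for one shark at one station.

    numerator = days detected at the station; denominator = array
    detection days on which the station was actively monitoring (days
    the station was down are excluded — the shark could not have been
    heard there).  Undefined when the denominator is empty.
    """
    denom = array_days & station_active_days
    if not denom:
        return None
    return len(station_days & denom) / len(denom)


def compute_residency(
    detections: list[Detection],
    sharks: list[Shark],
    effort: pd.DataFrame,
    window: StudyWindow,
) -> dict[str, ResidencyRecord]:
    """Per-shark residency records over QC'd detections.

    ``effort`` is the station × date boolean table; every station that
    appears in the detections must have a row in it.
    """
    tag_to_shark = {dep.tag_id: s.shark_id for s in sharks for dep in s.tagging_events}
    days = detection_days(detections, tag_to_shark, window)
    active_days = {
        sid: {d for d, on in effort.loc[sid].items() if on} for sid in effort.index
    }
    records: dict[str, ResidencyRecord] = {}
    for s in sharks:
        if s.first_tagged is None:
            continue
        tagging_date = window.local_date(s.first_tagged)
        array_days, by_station = days.get(s.shark_id, (set(), {}))
        last = max(array_days) if array_days else None
        # a detection late on the final UTC day can map to the local date
        # just past the nominal window end; the maximum monitoring period
        # must still cover it so that r_min <= r_max holds
        study_end = max(window.end, last) if last else window.end
        rec = ResidencyRecord(
            shark_id=s.shark_id,
            days_detected=array_days,
            days_detected_by_station=by_station,
            tagging_date=tagging_date,
            monitoring_days_max=(study_end - tagging_date).days + 1,
            monitoring_days_min=(last - tagging_date).days + 1 if last else None,
            r_min=r_min(len(array_days), tagging_date, study_end),
            r_max=r_max(len(array_days), tagging_date, last),
        )
        for sid in by_station:
            if sid not in active_days:
                raise ValidationError(f"station {sid} absent from effort table")
        rec.r_spatial = {
            sid: r_spatial(by_station.get(sid, set()), array_days, active)
            for sid, active in active_days.items()
            if array_days
        }
        records[s.shark_id] = rec
    return records


# ---------------------------------------------------------------------------
# effort-standardized detection rates and seasonality

def dpue(
    detections: Iterable[Detection],
    effort: pd.DataFrame,
    station_ids: set[str],
    months: Optional[set[int]] = None,
    window: Optional[StudyWindow] = None,
) -> Optional[float]:
    """Detections per active receiver-day for a station group.

    ``months`` optionally restricts both detections and effort to a set
    of calendar months (pooled across years).  Undefined (None) when
    the group has zero active receiver-days in the period.
    """
    window = window or StudyWindow(min(effort.columns), max(effort.columns))
    sub = effort.loc[[sid for sid in effort.index if sid in station_ids]]
    if months is not None:
        sub = sub.loc[:, [d for d in sub.columns if d.month in months]]
    receiver_days = int(sub.to_numpy().sum())
    if receiver_days == 0:
        return None
    n = sum(
        1
        for d in detections
        if d.station_id in station_ids
        and (months is None or window.local_date(d.timestamp).month in months)
    )
    return n / receiver_days


def monthly_fractions(
    detections: Iterable[Detection], window: StudyWindow
) -> dict[int, float]:
    """Per-calendar-month share of total detections (sums to 1)."""
    counts = np.zeros(12)
    for d in detections:
        counts[window.local_date(d.timestamp).month - 1] += 1
    total = counts.sum()
    if total == 0:
        return {}
    return {m + 1: counts[m] / total for m in range(12)}


# ---------------------------------------------------------------------------
# group comparisons

#: product n_a*n_b above which the tie-corrected normal approximation is
#: used instead of an exact null distribution
EXACT_PRODUCT_LIMIT = 400

#: cap on the number of group relabelings enumerated for the tied-data
#: exact path
_MAX_ENUMERATIONS = 200_000


def compare_groups(
    values_a: list[float], values_b: list[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two samples.

    Returns ``(U, p)`` with U oriented on the first sample.  For small
    problems (``n_a*n_b <= 400``) the p-value comes from the exact null
    distribution — the tie-free counting distribution when there are no
    ties, full enumeration of group relabelings when there are.  Larger
    problems use the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) == 1:
        # every relabeling yields the same midrank statistic
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    small = a.size * b.size <= EXACT_PRODUCT_LIMIT
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if (
        small
        and has_ties
        and min(a.size, b.size) >= 2
        and comb(pooled.size, a.size) <= _MAX_ENUMERATIONS
    ):
        u_stat = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)

        def _u(x, y):
            return stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic

        perm = stats.permutation_test(
            (a, b),
            _u,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        return u_stat, float(perm.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison critical value alpha/m."""
    if m < 1:
        raise ValidationError("number of comparisons must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# tabular outputs

def residency_table(records: dict[str, ResidencyRecord], sharks: list[Shark]) -> pd.DataFrame:
    meta = {s.shark_id: s for s in sharks}
    rows = []
    for sid, rec in sorted(records.items()):
        s = meta.get(sid)
        rows.append(
            {
                "shark_id": sid,
                "sex": s.sex if s else "U",
                "length_m": s.total_length_m if s else None,
                "days_detected": len(rec.days_detected),
                "monitoring_days_max": rec.monitoring_days_max,
                "monitoring_days_min": rec.monitoring_days_min,
                "r_min": rec.r_min,
                "r_max": rec.r_max,
            }
        )
    return pd.DataFrame(rows)


def rspatial_table(records: dict[str, ResidencyRecord]) -> pd.DataFrame:
    rows = []
    for sid, rec in sorted(records.items()):
        for station, value in sorted(rec.r_spatial.items()):
            rows.append({"shark_id": sid, "station_id": station, "r_spatial": value})
    return pd.DataFrame(rows)


def station_sex_comparison(
    records: dict[str, ResidencyRecord],
    sharks: list[Shark],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Station-wise male/female comparison of spatial residence values.

    One Mann-Whitney test per station; the Bonferroni-corrected critical
    value divides ``alpha`` by the number of stations tested.
    """
    sex_of = {s.shark_id: s.sex for s in sharks}
    stations = sorted({st for rec in records.values() for st in rec.r_spatial})
    alpha_bonf = bonferroni_alpha(alpha, len(stations)) if stations else alpha
    rows = []
    for st in stations:
        f_vals, m_vals = [], []
        for sid, rec in records.items():
            v = rec.r_spatial.get(st)
            if v is None:
                continue
            if sex_of.get(sid) == "F":
                f_vals.append(v)
            elif sex_of.get(sid) == "M":
                m_vals.append(v)
        if not f_vals or not m_vals:
            rows.append({"station_id": st, "mean_f": np.mean(f_vals) if f_vals else None,
                         "mean_m": np.mean(m_vals) if m_vals else None,
                         "U": None, "p": None,
                         "significant_alpha": None, "significant_bonferroni": None})
            continue
        u, p = compare_groups(f_vals, m_vals)
        rows.append(
            {
                "station_id": st,
                "mean_f": float(np.mean(f_vals)),
                "mean_m": float(np.mean(m_vals)),
                "U": u,
                "p": p,
                "significant_alpha": p < alpha,
                "significant_bonferroni": p < alpha_bonf,
            }
        )
    return pd.DataFrame(rows)
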