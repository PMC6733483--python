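"""Per-station daily monitoring effort.

The effort table is a boolean (station × date) matrix: a station-date
is active when **any** part of that calendar day intersects one of the
station's active intervals.  It is a pure function of station metadata
and never looks at detections, so monitoring effort can be audited
independently of the animals.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .types import Station, StudyWindow, ValidationError

#: default mapping of geographic regions onto the two effort covariates:
#: only the offshore-reef stations count as "offshore" receivers.
DEFAULT_SIDE_BY_REGION = {
    "exposed": "inshore_side",
    "sheltered": "inshore_side",
    "inshore": "inshore_side",
    "north_shelf": "inshore_side",
    "south_shelf": "inshore_side",
    "abu_latt": "inshore_side",
    "offshore": "offshore_side",
}


def build_effort_table(stations: list[Station], window: StudyWindow) -> pd.DataFrame:
    """Boolean DataFrame indexed by station_id with one column per date.

    A date is active if the station has an active interval overlapping
    any part of the day ``[00:00, 24:00)`` (any-overlap rule).
    """
    dates = window.dates()
    data = {}
    for s in stations:
        row = []
        for d in dates:
            day_start = dt.datetime.combine(d, dt.time.min)
            day_end = day_start + dt.timedelta(days=1)
            row.append(any(start < day_end and end > day_start for start, end in s.active_intervals))
        data[s.station_id] = row
    table = pd.DataFrame.from_dict(data, orient="index", columns=pd.Index(dates, name="date"))
    table.index.name = "station_id"
    return table


def station_days(effort: pd.DataFrame) -> pd.Series:
    """Active days per station (row sums)."""
    return effort.sum(axis=1)


def region_days(effort: pd.DataFrame, stations: list[Station]) -> pd.Series:
    region_of = {s.station_id: s.region for s in stations}
    return station_days(effort).groupby(lambda sid: region_of[sid]).sum()


def active_receiver_counts(
    effort: pd.DataFrame,
    grouping: dict[str, str],
) -> pd.DataFrame:
    """Per-date active receiver counts for the inshore/offshore groups.

    ``grouping`` maps every station_id to ``inshore_side`` or
    ``offshore_side``; a station missing a group is a validation error.
    Returns a DataFrame indexed by date with columns ``inshore_side``
    and ``offshore_side``.
    """
    missing = [sid for sid in effort.index if sid not in grouping]
    if missing:
        raise ValidationError(f"stations without inshore/offshore group: {missing}")
    counts = pd.DataFrame(
        0, index=effort.columns, columns=["inshore_side", "offshore_side"], dtype=int
    )
    for sid in effort.index:
        counts[grouping[sid]] += effort.loc[sid].astype(int).to_numpy()
    counts.index.name = "date"
    return counts


def side_grouping(stations: list[Station], by_region: dict[str, str] | None = None) -> dict[str, str]:
    """Derive the station → side mapping from regions (config-overridable)."""
    by_region = by_region or DEFAULT_SIDE_BY_REGION
    out = {}
    for s in stations:
        if s.region not in by_region:
            raise ValidationError(f"region {s.region!r} has no inshore/offshore side assignment")
        out[s.station_id] = by_region[s.region]
    return out


def write_effort(effort: pd.DataFrame, path) -> None:
    long = effort.stack().rename("active").reset_index()
    long.columns = ["station_id", "date", "active"]
    long.to_csv(path, index=False)
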