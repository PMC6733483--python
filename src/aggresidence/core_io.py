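"""Readers and writers for the tabular telemetry dialects.

All files are plain delimited text with a header row.  Documented
dialects:

* ``detections.csv``  — ``tag_id,station_id,timestamp`` (ISO 8601)
* ``stations.csv``    — ``station_id,region,lat,lon,active_start,active_end,nominal_range_m``
  (one row per active interval; station attributes repeated)
* ``deployments.csv`` — ``tag_id,shark_id,sex,length_m,start,end,end_reason``
  (empty ``end`` = open deployment)
* ``encounters.csv``  — ``shark_id,date,effort_units``
* ``argos.csv``       — ``shark_id,timestamp,lat,lon,error_class``
* ``clocks.csv``      — ``station_id,init_time,download_time,offset_s``

Every reader is total over its dialect: any file written by the
corresponding writer (or by the simulator) parses without error.
Malformed rows are reported with their line number rather than raised,
so a single bad record never discards a download.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

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
    ValidationError,
    VisualEncounter,
)

PathLike = Union[str, Path]

_ARGOS_TOKEN_MAP = {"0": "C0", "1": "C1", "2": "C2", "3": "C3"}


@dataclass
class RowError:
    line: int  # 1-based line number in the file (header = line 1)
    message: str


def _parse_ts(value: str) -> dt.datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.to_pydatetime()


# ---------------------------------------------------------------------------
# detections

def read_detections(
    path: PathLike,
    schema: Optional[dict[str, str]] = None,
    known_stations: Optional[set[str]] = None,
) -> tuple[list[Detection], list[RowError], list[str]]:
    """Read a detections file.

    Parameters
    ----------
    schema
        Optional mapping from the canonical column names
        (``tag_id``, ``station_id``, ``timestamp``) to the columns
        actually present in the file.
    known_stations
        If given, station ids absent from this set produce warnings
        (the rows are still returned — array metadata may simply be
        incomplete).

    Returns
    -------
    (detections, row_errors, warnings) — row order preserved.
    """
    schema = schema or {}
    cols = {k: schema.get(k, k) for k in ("tag_id", "station_id", "timestamp")}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out: list[Detection] = []
    errors: list[RowError] = []
    warnings: list[str] = []
    warned: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        line = i + 2  # header is line 1
        try:
            ts = _parse_ts(rec[cols["timestamp"]])
        except (ValueError, TypeError) as exc:
            errors.append(RowError(line, f"unparseable timestamp: {exc}"))
            continue
        sid = rec[cols["station_id"]]
        if known_stations is not None and sid not in known_stations and sid not in warned:
            warned.add(sid)
            warnings.append(f"line {line}: unknown station id {sid!r}")
        out.append(Detection(tag_id=rec[cols["tag_id"]], station_id=sid, timestamp_raw=ts))
    return out, errors, warnings


def write_detections(detections: list[Detection], path: PathLike) -> None:
    pd.DataFrame(
        {
            "tag_id": [d.tag_id for d in detections],
            "station_id": [d.station_id for d in detections],
            "timestamp": [d.timestamp_raw.isoformat() for d in detections],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stations

def read_stations(path: PathLike) -> list[Station]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    grouped: dict[str, dict] = {}
    for _, rec in df.iterrows():
        sid = rec["station_id"]
        entry = grouped.setdefault(
            sid,
            {
                "region": rec["region"],
                "lat": float(rec["lat"]),
                "lon": float(rec["lon"]),
                "nominal_range_m": float(rec["nominal_range_m"]),
                "intervals": [],
            },
        )
        if rec["active_start"] and rec["active_end"]:
            entry["intervals"].append((_parse_ts(rec["active_start"]), _parse_ts(rec["active_end"])))
    return [
        Station(
            station_id=sid,
            region=e["region"],
            lat=e["lat"],
            lon=e["lon"],
            active_intervals=e["intervals"],
            nominal_range_m=e["nominal_range_m"],
        )
        for sid, e in grouped.items()
    ]


def write_stations(stations: list[Station], path: PathLike) -> None:
    rows = []
    for s in stations:
        intervals = s.active_intervals or [(None, None)]
        for start, end in intervals:
            rows.append(
                {
                    "station_id": s.station_id,
                    "region": s.region,
                    "lat": s.lat,
                    "lon": s.lon,
                    "active_start": start.isoformat() if start else "",
                    "active_end": end.isoformat() if end else "",
                    "nominal_range_m": s.nominal_range_m,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# deployments / sharks

def read_deployments(path: PathLike) -> tuple[list[TagDeployment], list[Shark]]:
    """Read deployments; returns deployments plus the shark roster.

    A retagged shark appears on several rows with the same ``shark_id``;
    all its deployments are merged under one :class:`Shark`.  A tag
    assigned to two sharks over overlapping windows is a validation
    error (tag ids must resolve uniquely at any instant).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    deployments: list[TagDeployment] = []
    sharks: dict[str, Shark] = {}
    for _, rec in df.iterrows():
        end = _parse_ts(rec["end"]) if rec.get("end", "") else None
        dep = TagDeployment(
            tag_id=rec["tag_id"],
            shark_id=rec["shark_id"],
            start=_parse_ts(rec["start"]),
            end=end,
            end_reason=EndReason(rec.get("end_reason") or "study_end"),
        )
        deployments.append(dep)
        shark = sharks.setdefault(
            rec["shark_id"],
            Shark(
                shark_id=rec["shark_id"],
                sex=rec.get("sex") or "U",
                total_length_m=float(rec["length_m"]) if rec.get("length_m", "") else None,
            ),
        )
        shark.tagging_events.append(dep)
    _check_tag_uniqueness(deployments)
    for s in sharks.values():
        s.tagging_events.sort(key=lambda d: d.start)
    return deployments, list(sharks.values())


def _check_tag_uniqueness(deployments: list[TagDeployment]) -> None:
    by_tag: dict[str, list[TagDeployment]] = {}
    for d in deployments:
        by_tag.setdefault(d.tag_id, []).append(d)
    far_future = dt.datetime(9999, 1, 1)
    for tag, deps in by_tag.items():
        deps = sorted(deps, key=lambda d: d.start)
        for a, b in zip(deps, deps[1:]):
            a_end = a.end if a.end is not None else far_future
            if b.start < a_end and a.shark_id != b.shark_id:
                raise ValidationError(
                    f"tag {tag} assigned to sharks {a.shark_id} and {b.shark_id} simultaneously"
                )


def write_deployments(deployments: list[TagDeployment], sharks: list[Shark], path: PathLike) -> None:
    meta = {s.shark_id: s for s in sharks}
    rows = []
    for d in deployments:
        s = meta.get(d.shark_id)
        rows.append(
            {
                "tag_id": d.tag_id,
                "shark_id": d.shark_id,
                "sex": s.sex if s else "U",
                "length_m": "" if s is None or s.total_length_m is None else s.total_length_m,
                "start": d.start.isoformat(),
                "end": d.end.isoformat() if d.end else "",
                "end_reason": d.end_reason.value,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# encounters

def read_encounters(path: PathLike) -> list[VisualEncounter]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        VisualEncounter(
            shark_id=rec["shark_id"],
            date=pd.Timestamp(rec["date"]).date(),
            survey_effort_units=float(rec["effort_units"]) if rec.get("effort_units", "") else 1.0,
        )
        for _, rec in df.iterrows()
    ]


def write_encounters(encounters: list[VisualEncounter], path: PathLike) -> None:
    pd.DataFrame(
        {
            "shark_id": [e.shark_id for e in encounters],
            "date": [e.date.isoformat() for e in encounters],
            "effort_units": [e.survey_effort_units for e in encounters],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Argos

def read_argos(path: PathLike) -> list[ArgosPosition]:
    """Parse Argos positions.  Class tokens ``0``–``3`` are normalized to
    ``C0``–``C3``; class ``Z`` rows are retained — filtering is a later,
    explicit stage."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, rec in df.iterrows():
        token = rec["error_class"].strip()
        cls = _ARGOS_TOKEN_MAP.get(token, token)
        source = PositionSource(rec["source"]) if rec.get("source", "") else PositionSource.ARGOS
        out.append(
            ArgosPosition(
                shark_id=rec["shark_id"],
                timestamp=_parse_ts(rec["timestamp"]),
                lat=float(rec["lat"]),
                lon=float(rec["lon"]),
                error_class=cls,
                source=source,
            )
        )
    return out


def write_argos(positions: list[ArgosPosition], path: PathLike) -> None:
    pd.DataFrame(
        {
            "shark_id": [p.shark_id for p in positions],
            "timestamp": [p.timestamp.isoformat() for p in positions],
            "lat": [p.lat for p in positions],
            "lon": [p.lon for p in positions],
            "error_class": [p.error_class for p in positions],
            "source": [p.source.value for p in positions],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clock records

def read_clocks(path: PathLike) -> list[ClockRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        ClockRecord(
            station_id=rec["station_id"],
            init_time=_parse_ts(rec["init_time"]),
            download_time=_parse_ts(rec["download_time"]),
            offset_at_download_s=float(rec["offset_s"]),
        )
        for _, rec in df.iterrows()
    ]


def write_clocks(clocks: list[ClockRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "station_id": [c.station_id for c in clocks],
            "init_time": [c.init_time.isoformat() for c in clocks],
            "download_time": [c.download_time.isoformat() for c in clocks],
            "offset_s": [c.offset_at_download_s for c in clocks],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study config

def read_config(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def window_from_config(cfg: dict) -> StudyWindow:
    w = cfg["study_window"]
    return StudyWindow(
        start=pd.Timestamp(w["start"]).date(),
        end=pd.Timestamp(w["end"]).date(),
        timezone_offset_hours=int(w.get("timezone_offset_hours", 3)),
    )
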