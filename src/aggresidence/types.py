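"""Domain types shared across the pipeline.

Conventions enforced here, once:

* all timestamps are stored timezone-naive **UTC**; the calendar day of a
  detection is computed in a configurable local offset (default UTC+3,
  appropriate for a Red Sea study site);
* every interval is half-open ``[start, end)`` — an event exactly at
  ``end`` falls outside;
* Argos location-quality tokens ``0/1/2/3`` are stored as ``C0``–``C3``
  so quality classes are never confused with integers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

REGIONS = (
    "exposed",
    "sheltered",
    "inshore",
    "north_shelf",
    "south_shelf",
    "abu_latt",
    "offshore",
)

ARGOS_CLASSES = ("Z", "B", "A", "C0", "C1", "C2", "C3")

#: ranking of Argos classes from least to most accurate (Z unusable)
ARGOS_ACCURACY_RANK = {c: i for i, c in enumerate(ARGOS_CLASSES)}


class EndReason(str, Enum):
    STUDY_END = "study_end"
    TAG_LOSS_INFERRED = "tag_loss_inferred"
    MORTALITY = "mortality"
    RECOVERED = "recovered"


class PositionSource(str, Enum):
    ARGOS = "argos"
    ACOUSTIC_PSEUDO = "acoustic_pseudo"
    VISUAL_PSEUDO = "visual_pseudo"


class ValidationError(ValueError):
    """Raised when a record violates a documented invariant."""


@dataclass
class Station:
    """A moored acoustic receiver with its deployment history.

    ``active_intervals`` are non-overlapping, sorted, half-open UTC
    intervals during which the receiver was in the water and functioning.
    ``nominal_range_m`` is the field-measured 50% detection distance.
    """

    station_id: str
    region: str
    lat: float
    lon: float
    active_intervals: list[tuple[dt.datetime, dt.datetime]] = field(default_factory=list)
    nominal_range_m: float = 540.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r} for station {self.station_id}")
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValidationError(f"station {self.station_id}: coordinates out of range")
        if self.nominal_range_m <= 0:
            raise ValidationError(f"station {self.station_id}: nominal_range_m must be > 0")
        self.active_intervals.sort(key=lambda iv: iv[0])
        prev_end: Optional[dt.datetime] = None
        for start, end in self.active_intervals:
            if end <= start:
                raise ValidationError(f"station {self.station_id}: empty/inverted interval {start}–{end}")
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"station {self.station_id}: overlapping active intervals")
            prev_end = end

    def is_active_at(self, t: dt.datetime) -> bool:
        return any(start <= t < end for start, end in self.active_intervals)


@dataclass
class TagDeployment:
    """One transmitter attached to one shark over a time window."""

    tag_id: str
    shark_id: str
    start: dt.datetime
    end: Optional[dt.datetime] = None  # None = open (until study end)
    end_reason: EndReason = EndReason.STUDY_END

    def __post_init__(self) -> None:
        if self.end is not None and self.end < self.start:
            raise ValidationError(
                f"deployment {self.tag_id}/{self.shark_id}: end precedes start"
            )

    def covers(self, t: dt.datetime, study_end: Optional[dt.datetime] = None) -> bool:
        end = self.end if self.end is not None else study_end
        if end is None:
            return self.start <= t
        return self.start <= t < end


@dataclass
class Shark:
    shark_id: str
    sex: str = "U"  # F, M or U (undetermined)
    total_length_m: Optional[float] = None
    tagging_events: list[TagDeployment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "U"):
            raise ValidationError(f"shark {self.shark_id}: sex must be F, M or U")
        if self.total_length_m is not None and self.total_length_m <= 0:
            raise ValidationError(f"shark {self.shark_id}: total_length_m must be > 0")
        self.tagging_events.sort(key=lambda d: d.start)

    @property
    def first_tagged(self) -> Optional[dt.datetime]:
        return self.tagging_events[0].start if self.tagging_events else None


@dataclass
class Detection:
    """One receiver-logged transmission of a tagged animal."""

    tag_id: str
    station_id: str
    timestamp_raw: dt.datetime
    timestamp: Optional[dt.datetime] = None  # drift-corrected; set by QC

    def __post_init__(self) -> None:
        if self.timestamp is None:
            self.timestamp = self.timestamp_raw


@dataclass
class VisualEncounter:
    shark_id: str
    date: dt.date
    survey_effort_units: float = 1.0

    def __post_init__(self) -> None:
        if self.survey_effort_units < 0:
            raise ValidationError("survey_effort_units must be nonnegative")


@dataclass
class ArgosPosition:
    shark_id: str
    timestamp: dt.datetime
    lat: float
    lon: float
    error_class: str
    source: PositionSource = PositionSource.ARGOS

    def __post_init__(self) -> None:
        if self.error_class not in ARGOS_CLASSES:
            raise ValidationError(f"unknown Argos error class {self.error_class!r}")


@dataclass
class StudyWindow:
    """Study period plus the local offset that defines detection days."""

    start: dt.date
    end: dt.date
    timezone_offset_hours: int = 3

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("study window start must precede end")

    def local_date(self, t_utc: dt.datetime) -> dt.date:
        return (t_utc + dt.timedelta(hours=self.timezone_offset_hours)).date()

    @property
    def n_days(self) -> int:
        """Days in the window, both endpoints inclusive."""
        return (self.end - self.start).days + 1

    def dates(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]


@dataclass
class ClockRecord:
    """Receiver clock calibration: measured offset at download.

    ``offset_at_download_s`` is receiver clock minus true clock at the
    moment of download; the drift is assumed linear from zero at
    initialization.
    """

    station_id: str
    init_time: dt.datetime
    download_time: dt.datetime
    offset_at_download_s: float

    def __post_init__(self) -> None:
        if self.init_time >= self.download_time:
            raise ValidationError(
                f"clock record {self.station_id}: init_time must precede download_time"
            )
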