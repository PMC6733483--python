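"""Detection quality control.

Order of operations, mirroring standard passive-telemetry practice:

1. clock-drift correction (linear drift anchored at zero offset at
   receiver initialization, scaled to the offset measured at download);
2. restriction to known tag deployments (tag id + deployment window);
3. exclusion of the post-tagging acclimation window (default 24 h after
   each tag application — animals may behave atypically right after
   being tagged);
4. truncation of deployments at inferred tag loss or mortality: when a
   shark is later resighted without its tag (or found dead) the tag is
   assumed shed immediately after its last recorded detection.

Each stage reports input/retained/dropped counts so the final analyzed
sample is fully accounted for.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

from .types import ClockRecord, Detection, EndReason, TagDeployment


@dataclass
class QCReport:
    """Per-stage row accounting; ``input = retained + dropped`` per stage."""

    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append(
            {"stage": name, "input": n_in, "retained": n_out, "dropped": n_in - n_out}
        )

    def to_dict(self) -> dict:
        return {"stages": self.stages, "warnings": self.warnings}


def correct_clock_drift(
    detections: list[Detection],
    clocks: list[ClockRecord],
    report: Optional[QCReport] = None,
) -> list[Detection]:
    """Correct receiver clock drift assuming linear drift.

    The receiver clock is taken to read true time at initialization and
    to be ahead by ``offset_at_download_s`` at download, so a raw
    timestamp t is corrected to::

        t - offset * (t - init) / (download - init)

    A detection whose raw timestamp falls outside every clock interval
    for its station passes through unchanged with a warning.
    """
    by_station: dict[str, list[ClockRecord]] = {}
    for c in clocks:
        by_station.setdefault(c.station_id, []).append(c)
    out = []
    warned: set[str] = set()
    for d in detections:
        rec = None
        for c in by_station.get(d.station_id, []):
            if c.init_time <= d.timestamp_raw <= c.download_time:
                rec = c
                break
        if rec is None:
            key = d.station_id
            if report is not None and key not in warned:
                warned.add(key)
                report.warnings.append(
                    f"station {key}: detections outside all clock intervals left uncorrected"
                )
            out.append(Detection(d.tag_id, d.station_id, d.timestamp_raw, d.timestamp_raw))
            continue
        span = (rec.download_time - rec.init_time).total_seconds()
        frac = (d.timestamp_raw - rec.init_time).total_seconds() / span
        corrected = d.timestamp_raw - dt.timedelta(seconds=rec.offset_at_download_s * frac)
        out.append(Detection(d.tag_id, d.station_id, d.timestamp_raw, corrected))
    if report is not None:
        report.add_stage("clock_drift", len(detections), len(out))
    return out


def filter_to_deployments(
    detections: list[Detection],
    deployments: list[TagDeployment],
    study_end: Optional[dt.datetime] = None,
    report: Optional[QCReport] = None,
) -> list[Detection]:
    """Keep detections whose tag was deployed at the (corrected) time.

    A detection is retained iff some deployment of its tag satisfies
    ``start <= timestamp < end`` (open ends close at ``study_end``).
    Unmatched rows — unknown tags, or echoes before/after deployment —
    are dropped and counted.
    """
    by_tag: dict[str, list[TagDeployment]] = {}
    for dep in deployments:
        by_tag.setdefault(dep.tag_id, []).append(dep)
    out = [
        d
        for d in detections
        if any(dep.covers(d.timestamp, study_end) for dep in by_tag.get(d.tag_id, []))
    ]
    if report is not None:
        report.add_stage("deployment_filter", len(detections), len(out))
    return out


def exclude_post_tagging(
    detections: list[Detection],
    deployments: list[TagDeployment],
    window_h: float = 24.0,
    report: Optional[QCReport] = None,
) -> list[Detection]:
    """Drop detections within ``window_h`` hours of tag application.

    The exclusion window is half-open ``[start, start + window_h)`` and
    applies per tagging event: a retagged shark gets a fresh window for
    the new tag only.  A shark whose only detections fall inside the
    window simply contributes no analyzable records.
    """
    windows: dict[str, list[tuple[dt.datetime, dt.datetime]]] = {}
    for dep in deployments:
        windows.setdefault(dep.tag_id, []).append(
            (dep.start, dep.start + dt.timedelta(hours=window_h))
        )
    out = [
        d
        for d in detections
        if not any(start <= d.timestamp < end for start, end in windows.get(d.tag_id, []))
    ]
    if report is not None:
        report.add_stage("post_tagging_exclusion", len(detections), len(out))
    return out


def truncate_at_tag_loss(
    deployments: list[TagDeployment],
    detections: list[Detection],
    loss_evidence: list[tuple[str, dt.date, str]],
    report: Optional[QCReport] = None,
) -> list[TagDeployment]:
    """Truncate deployments of sharks with tag-loss/mortality evidence.

    ``loss_evidence`` rows are ``(shark_id, evidence_date, kind)`` with
    kind ``resighted_untagged`` or ``mortality``.  For each evidenced
    shark the tag is assumed shed immediately after its last recorded
    detection (array-wide), so the latest deployment ends one second
    after that detection — the detection itself stays inside the
    half-open deployment window.  A shark with zero detections gets a
    zero-length deployment (end = start) with a warning.  Deployments
    of sharks without evidence are returned unchanged.
    """
    last_det: dict[str, dt.datetime] = {}
    dep_by_tag = {d.tag_id: d for d in deployments}
    for det in detections:
        dep = dep_by_tag.get(det.tag_id)
        if dep is None:
            continue
        cur = last_det.get(dep.shark_id)
        if cur is None or det.timestamp > cur:
            last_det[dep.shark_id] = det.timestamp
    kind_reason = {
        "resighted_untagged": EndReason.TAG_LOSS_INFERRED,
        "mortality": EndReason.MORTALITY,
    }
    evidenced = {sid: kind for sid, _date, kind in loss_evidence}
    out = []
    for dep in deployments:
        kind = evidenced.get(dep.shark_id)
        if kind is None:
            out.append(dep)
            continue
        shark_deps = [d for d in deployments if d.shark_id == dep.shark_id]
        if dep is not max(shark_deps, key=lambda d: d.start):
            out.append(dep)  # only the final deployment is truncated
            continue
        last = last_det.get(dep.shark_id)
        if last is None:
            if report is not None:
                report.warnings.append(
                    f"shark {dep.shark_id}: loss evidence but zero detections; "
                    "deployment truncated to zero monitored days"
                )
            new_end = dep.start
        else:
            new_end = last + dt.timedelta(seconds=1)
        out.append(replace(dep, end=new_end, end_reason=kind_reason[kind]))
    return out


def run_qc(
    detections: list[Detection],
    deployments: list[TagDeployment],
    clocks: Optional[list[ClockRecord]] = None,
    loss_evidence: Optional[list[tuple[str, dt.date, str]]] = None,
    study_end: Optional[dt.datetime] = None,
    window_h: float = 24.0,
) -> tuple[list[Detection], list[TagDeployment], QCReport]:
    """Full QC chain.  Idempotent: re-running on its own output is a no-op."""
    report = QCReport()
    dets = correct_clock_drift(detections, clocks or [], report)
    deps = truncate_at_tag_loss(deployments, dets, loss_evidence or [], report)
    dets = filter_to_deployments(dets, deps, study_end, report)
    dets = exclude_post_tagging(dets, deps, window_h, report)
    return dets, deps, report
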