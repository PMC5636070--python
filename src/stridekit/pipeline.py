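"""End-to-end analysis: raw recording in, per-stride parameters out.

``analyze_recording`` runs the full measurement chain on one foot's
signal: msDTW segmentation against a stride template, turning/initiation
labelling, event detection per segment, sagittal pitch estimation, and
ZUPT double integration between the midstance anchors of consecutive
segments.  Each adjacent pair of non-turning segments yields one
:class:`~stridekit.parameters.StrideParameters` row; strides whose event
detection or orientation anchoring fails are counted, not fatal.

``analyze_walk`` pools both feet of one walk into a
:class:`~stridekit.parameters.WalkSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    EventError,
    GaitEvents,
    IntegrationError,
    OrientationError,
    detect_gait_events,
    estimate_pitch_course,
    reconstruct_trajectory,
    _cumtrapz0,
)
from .io import GaitTemplate, ImuRecording
from .parameters import (
    PARAMETER_FIELDS,
    StrideParameters,
    WalkSummary,
    normalize_parameters,
    summarize_walk,
)
from .segmentation import default_template, label_turning, segment_strides
from .synth import SENSOR_LEVER_ARM

__all__ = ["StrideRow", "AnalysisResult", "analyze_recording", "analyze_walk", "strides_to_frame"]


@dataclass
class StrideRow:
    """One measured stride with provenance for tables and debugging."""

    params: StrideParameters
    segment_index: int
    start: int
    end: int
    events: GaitEvents


@dataclass
class AnalysisResult:
    """Outcome of analyzing one recording."""

    rows: list[StrideRow] = field(default_factory=list)
    segments: list = field(default_factory=list)
    n_segments: int = 0
    n_turning: int = 0
    n_initiation: int = 0
    n_rejected: int = 0
    rejections: list[str] = field(default_factory=list)

    @property
    def parameters(self) -> list[StrideParameters]:
        return [r.params for r in self.rows]


def _anchored_pitch(rec: ImuRecording, ev: GaitEvents, a0: int, a1: int) -> np.ndarray:
    """Pitch (°) over samples [a0, a1], anchored at the accelerometer's
    static estimate at the opening midstance."""
    from .events import _gravity_anchor

    pitch0 = _gravity_anchor(rec, ev.midstance)
    gz = rec.gyr[a0 : a1 + 1, 2]
    t = rec.t[a0 : a1 + 1]
    course = _cumtrapz0(gz, t)
    return pitch0 + course - course[ev.midstance - a0]


def analyze_recording(
    rec: ImuRecording,
    template: GaitTemplate | None = None,
    threshold: float | None = None,
    lever_arm: float = SENSOR_LEVER_ARM,
    max_pair_gap: int = 2,
) -> AnalysisResult:
    """Measure every analyzable stride of one recording.

    Consecutive non-turning segments whose shared boundary agrees within
    ``max_pair_gap`` samples form one gait cycle; the trajectory is
    integrated between their midstance anchors.
    """
    if template is None:
        template = default_template(fs=rec.fs)
    segments = label_turning(
        segment_strides(rec, template, threshold=threshold), rec
    )
    result = AnalysisResult(segments=segments, n_segments=len(segments))
    result.n_turning = sum(s.label == "turning" for s in segments)
    result.n_initiation = sum(s.label == "initiation" for s in segments)

    detections: list[tuple[int, GaitEvents, object] | None] = []
    for seg in segments:
        if seg.label == "turning":
            detections.append(None)
            continue
        try:
            ev = detect_gait_events(rec, seg)
            pt = estimate_pitch_course(rec, seg, ev)
        except (EventError, OrientationError) as exc:
            result.n_rejected += 1
            result.rejections.append(f"segment [{seg.start},{seg.end}): {exc}")
            detections.append(None)
            continue
        detections.append((seg.start, ev, pt))
    for k in range(len(segments) - 1):
        d1, d2 = detections[k], detections[k + 1]
        if d1 is None or d2 is None:
            continue
        seg1, seg2 = segments[k], segments[k + 1]
        if abs(seg2.start - seg1.end) > max_pair_gap:
            continue
        _, ev1, pt1 = d1
        _, ev2, pt2 = d2
        try:
            pitch = _anchored_pitch(rec, ev1, ev1.midstance, ev2.midstance)
            traj = reconstruct_trajectory(
                rec, (ev1.midstance, ev2.midstance), pitch, lever_arm=lever_arm
            )
            params = compute_pair(ev1, ev2, traj, pt1, pt2, rec.fs, seg1.label)
        except (EventError, OrientationError, IntegrationError) as exc:
            result.n_rejected += 1
            result.rejections.append(f"pair [{seg1.start},{seg2.end}): {exc}")
            continue
        result.rows.append(
            StrideRow(
                params=params,
                segment_index=k,
                start=seg1.start,
                end=seg1.end,
                events=ev1,
            )
        )
    return result


def compute_pair(ev1, ev2, traj, pt1, pt2, fs, label):
    from .parameters import compute_stride_parameters

    return compute_stride_parameters((ev1, ev2), traj, (pt1, pt2), fs, label=label)


def analyze_walk(
    recordings,
    template: GaitTemplate | None = None,
    threshold: float | None = None,
    include_initiation: bool = True,
    height: float | None = None,
) -> tuple[WalkSummary, list[AnalysisResult]]:
    """Analyze one walk (typically both feet) into a single summary.

    ``recordings`` is an iterable of :class:`ImuRecording` (or a mapping
    side → recording); strides from all recordings are pooled, mirroring
    the one-value-per-subject presentation of cohort studies.
    """
    if isinstance(recordings, dict):
        recordings = list(recordings.values())
    results = [
        analyze_recording(rec, template=template, threshold=threshold)
        for rec in recordings
    ]
    params = [p for res in results for p in res.parameters]
    summary = summarize_walk(params, include_initiation=include_initiation)
    summary.n_excluded_turning = sum(res.n_turning for res in results)
    if height is not None:
        summary = normalize_parameters(summary, height)
    return summary, results


def strides_to_frame(rows: list[StrideRow]) -> pd.DataFrame:
    """Tabulate measured strides (one row per gait cycle)."""
    records = []
    for r in rows:
        d = {name: getattr(r.params, name) for name in PARAMETER_FIELDS}
        d.update(
            label=r.params.label,
            start=r.start,
            end=r.end,
            heel_strike=r.events.heel_strike,
            toe_off=r.events.toe_off,
            midstance=r.events.midstance,
        )
        records.append(d)
    return pd.DataFrame(records)
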