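"""Per-stride spatiotemporal parameters and per-walk summaries.

One stride is timed heel-strike to heel-strike; stance is heel-strike to
the following toe-off and swing the remainder, both reported as percent of
stride time.  Lengths come from the midstance-to-midstance trajectory
reconstruction.  Cadence is reported in strides per minute
(60 / stride time), the convention consistent with published cohort means
for this protocol.  Walk summaries report the mean and the coefficient of
variation (CV = 100·SD/mean, sample SD) per parameter over the accepted
strides, always excluding turning strides and optionally the first two
initiation strides of each bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .events import FootTrajectory, GaitEvents, PitchTrace

__all__ = [
    "StrideParameters",
    "WalkSummary",
    "OrderingError",
    "SummaryError",
    "NormalizationError",
    "compute_stride_parameters",
    "summarize_walk",
    "normalize_parameters",
    "PARAMETER_FIELDS",
]

#: Parameter fields aggregated in walk summaries (units as stored).
PARAMETER_FIELDS = (
    "stride_length",    # m
    "stride_time",      # s
    "stance_time_pct",  # % of stride
    "swing_time_pct",   # % of stride
    "gait_velocity",    # m/s
    "cadence",          # strides/min
    "hs_angle",         # °
    "to_angle",         # °
    "clearance",        # cm
)


class OrderingError(ValueError):
    """Event triple violates heel-strike / toe-off ordering."""


class SummaryError(ValueError):
    """No accepted strides left to summarize."""


class NormalizationError(ValueError):
    """Height missing or non-positive."""


@dataclass(frozen=True)
class StrideParameters:
    """Spatiotemporal parameters of one gait cycle.

    Invariants (held by construction): ``stance_time_pct +
    swing_time_pct == 100`` and ``gait_velocity == stride_length /
    stride_time``.
    """

    stride_length: float    # m
    stride_time: float      # s
    stance_time_pct: float  # %
    swing_time_pct: float   # %
    gait_velocity: float    # m/s
    cadence: float          # strides/min
    hs_angle: float         # °
    to_angle: float         # °
    clearance: float        # cm
    label: str = "straight"

    def __post_init__(self):
        if self.stride_time <= 0:
            raise OrderingError("stride time must be positive")
        if not 0 < self.stance_time_pct < 100:
            raise OrderingError("stance phase must be inside (0, 100)%")


def compute_stride_parameters(
    events: tuple[GaitEvents, GaitEvents],
    traj: FootTrajectory,
    pitch: tuple[PitchTrace, PitchTrace],
    fs: float,
    label: str = "straight",
) -> StrideParameters:
    """Assemble one stride's parameters from consecutive segments.

    ``events``/``pitch`` are the detections of stride k and its successor:
    the cycle runs heel-strike(k) → heel-strike(k+1) with its stance
    ending at toe-off(k+1); the heel-strike angle belongs to stride k and
    the toe-off angle to the following push-off of the same cycle.
    """
    ev1, ev2 = events
    p1, p2 = pitch
    hs1, hs2 = ev1.heel_strike_time, ev2.heel_strike_time
    to = ev2.toe_off_time
    if not hs1 < to < hs2:
        raise OrderingError(
            f"toe-off at {to:.3f}s not between heel strikes "
            f"({hs1:.3f}s, {hs2:.3f}s)"
        )
    stride_time = hs2 - hs1
    stance_pct = 100.0 * (to - hs1) / stride_time
    return StrideParameters(
        stride_length=traj.stride_length,
        stride_time=stride_time,
        stance_time_pct=stance_pct,
        swing_time_pct=100.0 - stance_pct,
        gait_velocity=traj.stride_length / stride_time,
        cadence=60.0 / stride_time,
        hs_angle=p1.hs_angle,
        to_angle=p2.to_angle,
        clearance=100.0 * traj.clearance,
        label=label,
    )


@dataclass
class WalkSummary:
    """Per-walk aggregation over accepted strides.

    ``means`` and ``cvs`` map parameter names (:data:`PARAMETER_FIELDS`)
    to the mean and coefficient of variation (%); CVs use the sample SD
    (n−1) and are NaN for a single stride.
    """

    means: dict = field(default_factory=dict)
    cvs: dict = field(default_factory=dict)
    n_strides: int = 0
    n_excluded_turning: int = 0
    n_excluded_initiation: int = 0
    include_initiation: bool = True
    normalized_stride_length: float | None = None


def summarize_walk(
    strides: Sequence[StrideParameters],
    include_initiation: bool = True,
) -> WalkSummary:
    """Mean and CV per parameter over the accepted strides.

    Turning strides are always excluded; initiation strides only when
    ``include_initiation`` is False.  Raises :class:`SummaryError` when no
    stride survives the exclusions.
    """
    turning = [s for s in strides if s.label == "turning"]
    initiation = [s for s in strides if s.label == "initiation"]
    kept = [s for s in strides if s.label != "turning"]
    n_excl_init = 0
    if not include_initiation:
        kept = [s for s in kept if s.label != "initiation"]
        n_excl_init = len(initiation)
    if not kept:
        raise SummaryError("all strides excluded; nothing to summarize")

    means, cvs = {}, {}
    for name in PARAMETER_FIELDS:
        x = np.array([getattr(s, name) for s in kept], dtype=float)
        mu = float(x.mean())
        means[name] = mu
        if len(x) > 1 and mu != 0.0:
            cvs[name] = float(100.0 * x.std(ddof=1) / abs(mu))
        else:
            cvs[name] = float("nan")
    return WalkSummary(
        means=means,
        cvs=cvs,
        n_strides=len(kept),
        n_excluded_turning=len(turning),
        n_excluded_initiation=n_excl_init,
        include_initiation=include_initiation,
    )


def normalize_parameters(summary: WalkSummary, height: float) -> WalkSummary:
    """Attach the height-normalized mean stride length (dimensionless)."""
    if height is None or not height > 0:
        raise NormalizationError("subject height must be positive")
    out = replace(summary)
    out.means = dict(summary.means)
    out.cvs = dict(summary.cvs)
    out.normalized_stride_length = summary.means["stride_length"] / height
    return out
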