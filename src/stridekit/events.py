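"""Gait-event detection, sagittal orientation, and ZUPT trajectory
reconstruction within segmented strides.

Within each stride segment (midstance to midstance) three events are
detected from the gyroscope:

* **midstance** — centre of the minimum-energy window of the gyroscope
  magnitude (0.1 s window): the quiet flat-foot instant that anchors the
  zero-velocity updates;
* **toe-off** — the most negative sagittal gyroscope peak *before* the
  swing maximum (rapid plantarflexion at push-off);
* **heel-strike** — the most negative sagittal peak *after* the swing
  maximum (the foot rotating down onto the ground).

Peak instants are refined to sub-sample precision by parabolic
interpolation, which matters at 51.2 Hz where one sample is ~20 ms.

The sagittal pitch course is initialised from the accelerometer at
midstance (the gravity direction, valid because the foot is static there)
and propagated by trapezoidal integration of the sagittal angular rate.
The foot trajectory comes from strapdown double integration between two
consecutive midstances: the specific force is rotated to the world frame
with the pitch course, gravity subtracted, integrated to velocity, the
velocity linearly detrended so it is exactly zero at both midstance
anchors (the zero-velocity update), and integrated again to position.
Toe clearance adds a lever-arm correction for the sensor sitting a known
distance behind the toe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import G, ImuRecording
from .segmentation import StrideSegment, gyro_energy
from .synth import SENSOR_LEVER_ARM

__all__ = [
    "GaitEvents",
    "PitchTrace",
    "FootTrajectory",
    "EventError",
    "OrientationError",
    "IntegrationError",
    "detect_gait_events",
    "estimate_pitch_course",
    "reconstruct_trajectory",
]


class EventError(ValueError):
    """No physiologically plausible event structure in the segment."""


class OrientationError(ValueError):
    """Static orientation estimate unavailable (accelerometer not at 1 g)."""


class IntegrationError(ValueError):
    """Integration interval too short or anchors invalid."""


@dataclass(frozen=True)
class GaitEvents:
    """Detected events of one stride segment (absolute sample indices).

    Within a segment running midstance→midstance the raw order is
    ``midstance < toe_off < heel_strike``; across consecutive segments the
    gait-cycle order heel_strike(k) < midstance(k+1) < toe_off(k+1) holds.
    ``*_time`` fields are the sub-sample refined instants in seconds.
    """

    midstance: int
    toe_off: int
    heel_strike: int
    midstance_time: float
    toe_off_time: float
    heel_strike_time: float

    def __post_init__(self):
        if not self.midstance < self.toe_off < self.heel_strike:
            raise EventError(
                "events out of order: expected midstance < toe_off < heel_strike "
                f"got {self.midstance}, {self.toe_off}, {self.heel_strike}"
            )


@dataclass
class PitchTrace:
    """Sagittal pitch course over one segment.

    ``pitch`` holds degrees per sample for ``rec[start:end]``; the angles
    at the refined event instants are interpolated from it.
    """

    start: int
    end: int
    pitch: np.ndarray        # °, per sample
    pitch_midstance: float   # ° (accelerometer-derived static estimate)
    hs_angle: float          # ° at heel strike
    to_angle: float          # ° at toe off


@dataclass
class FootTrajectory:
    """World-frame sensor trajectory between two midstance anchors.

    Origin at the first anchor; x is the horizontal direction of
    progression (sagittal), y vertical.  Velocity is exactly zero at both
    anchors after the ZUPT drift correction.
    """

    start: int
    end: int               # inclusive anchor sample
    position: np.ndarray   # (n, 2) m
    velocity: np.ndarray   # (n, 2) m/s
    stride_length: float   # m, |horizontal displacement|
    clearance: float       # m, max toe height during the stride
    closing_height: float  # m, sensor height at the closing anchor


# ---------------------------------------------------------------------------
# event detection


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample vertex of a parabola through (i-1, i, i+1); clamped ±0.5."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-12:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def detect_gait_events(
    rec: ImuRecording,
    seg: StrideSegment,
    energy_window_s: float = 0.1,
    stance_energy_max: float = 900.0,
    min_swing_rate: float = 20.0,
    min_duration_s: float = 0.3,
) -> GaitEvents:
    """Detect midstance, toe-off and heel-strike inside one segment.

    ``stance_energy_max`` (°²/s², windowed mean of the squared gyro
    magnitude, default equivalent to a 30 °/s RMS) rejects segments with
    no quiet stance; ``min_swing_rate`` (°/s) rejects segments with no
    swing rotation.

    Raises
    ------
    EventError
        Degenerate segment: no low-energy stance window or no swing peak.
    """
    fs = rec.fs
    if (seg.end - seg.start) / fs < min_duration_s:
        raise EventError("segment shorter than the minimum stride duration")

    energy = gyro_energy(rec, energy_window_s)[seg.start : seg.end]
    gz = rec.gyr[seg.start : seg.end, 2]
    n = len(gz)

    # midstance: centre of the minimum-energy window near the segment
    # start (the opening flat-foot phase occupies the first part of stance)
    search = max(3, int(0.30 * n))
    window = energy[:search]
    jmin = int(np.argmin(window))
    if window[jmin] > stance_energy_max:
        raise EventError("no quiet stance window: gyro energy stays high")
    tol = window[jmin] * 0.5 + 1e-12
    near = window <= window[jmin] + tol
    a = jmin
    while a > 0 and near[a - 1]:
        a -= 1
    b = jmin
    while b < search - 1 and near[b + 1]:
        b += 1
    ms = int(round((a + b) / 2.0))

    # swing maximum separates push-off from terminal swing
    swing = int(np.argmax(gz))
    if gz[swing] < min_swing_rate:
        raise EventError("no swing rotation peak in the sagittal gyroscope")
    if swing <= ms + 1 or swing >= n - 1:
        raise EventError("swing maximum not interior to the segment")

    to = ms + 1 + int(np.argmin(gz[ms + 1 : swing]))
    hs = swing + 1 + int(np.argmin(gz[swing + 1 :]))
    if not ms < to < hs:
        raise EventError("event ordering violated within the segment")

    to_t = (seg.start + _parabolic_refine(gz, to)) / fs
    hs_t = (seg.start + _parabolic_refine(gz, hs)) / fs
    return GaitEvents(
        midstance=seg.start + ms,
        toe_off=seg.start + to,
        heel_strike=seg.start + hs,
        midstance_time=(seg.start + ms) / fs,
        toe_off_time=to_t,
        heel_strike_time=hs_t,
    )


# ---------------------------------------------------------------------------
# sagittal orientation


def _static_window(
    rec: ImuRecording, center: int, max_half_s: float = 0.1, rate_max: float = 20.0
) -> slice:
    """Contiguous near-stationary samples around ``center``.

    Expands outward while the gyroscope magnitude stays below ``rate_max``
    (°/s), up to ``max_half_s`` on either side — so the gravity average
    never reaches into the push-off onset, even when the flat-foot window
    is short (e.g. the first stride of a walk).
    """
    gmag = np.linalg.norm(rec.gyr, axis=1)
    max_half = max(1, int(round(max_half_s * rec.fs)))
    lo = hi = int(np.clip(center, 0, rec.n_samples - 1))
    while lo - 1 >= 0 and center - (lo - 1) <= max_half and gmag[lo - 1] < rate_max:
        lo -= 1
    while hi + 1 < rec.n_samples and (hi + 1) - center <= max_half and gmag[hi + 1] < rate_max:
        hi += 1
    return slice(lo, hi + 1)


def _gravity_anchor(
    rec: ImuRecording, midstance: int, gravity_tolerance: float = 0.2
) -> float:
    """Static sagittal pitch (°) from the midstance gravity direction."""
    window = _static_window(rec, midstance)
    mean_acc = rec.acc[window].mean(axis=0)
    mag = float(np.linalg.norm(mean_acc))
    if abs(mag - G) > gravity_tolerance * G:
        raise OrientationError(
            f"midstance accelerometer magnitude {mag:.2f} m/s² deviates "
            f">{gravity_tolerance:.0%} from gravity"
        )
    return float(np.degrees(np.arctan2(mean_acc[0], mean_acc[1])))


def estimate_pitch_course(
    rec: ImuRecording,
    seg: StrideSegment,
    ev: GaitEvents,
    gravity_tolerance: float = 0.2,
) -> PitchTrace:
    """Accelerometer-anchored, gyroscope-propagated sagittal pitch.

    The static pitch at midstance is ``atan2(acc_x, acc_y)`` of the
    accelerometer averaged over the near-stationary samples around the
    midstance (gravity direction while the foot is flat); the pitch course
    adds the cumulative trapezoidal integral of the sagittal angular rate.
    Rejects the stride if the averaged accelerometer magnitude deviates
    more than ``gravity_tolerance`` (fraction) from 1 g — then the foot
    was not static and the anchor is unusable.
    """
    pitch0 = _gravity_anchor(rec, ev.midstance, gravity_tolerance)

    fs = rec.fs
    gz = rec.gyr[seg.start : seg.end, 2]
    t = rec.t[seg.start : seg.end]
    pitch = pitch0 + _cumtrapz0(gz, t) - _value_at(
        _cumtrapz0(gz, t), ev.midstance - seg.start
    )

    hs_angle = _interp_sample(pitch, ev.heel_strike_time * fs - seg.start)
    to_angle = _interp_sample(pitch, ev.toe_off_time * fs - seg.start)
    return PitchTrace(
        start=seg.start,
        end=seg.end,
        pitch=pitch,
        pitch_midstance=pitch0,
        hs_angle=hs_angle,
        to_angle=to_angle,
    )


def _cumtrapz0(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral with a leading zero."""
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum((y[1:] + y[:-1]) / 2.0 * np.diff(t), out=out[1:])
    return out


def _value_at(y: np.ndarray, i: int) -> float:
    return float(y[int(np.clip(i, 0, len(y) - 1))])


def _interp_sample(y: np.ndarray, x: float) -> float:
    x = float(np.clip(x, 0.0, len(y) - 1.0))
    i = int(np.floor(x))
    if i >= len(y) - 1:
        return float(y[-1])
    frac = x - i
    return float((1.0 - frac) * y[i] + frac * y[i + 1])


# ---------------------------------------------------------------------------
# strapdown reconstruction


def reconstruct_trajectory(
    rec: ImuRecording,
    anchors: tuple[int, int],
    pitch_deg: np.ndarray,
    lever_arm: float = SENSOR_LEVER_ARM,
    min_duration_s: float = 0.3,
    apply_zupt: bool = True,
) -> FootTrajectory:
    """ZUPT double integration between two midstance anchors.

    ``pitch_deg`` gives the sagittal pitch per sample over
    ``rec[anchors[0] : anchors[1] + 1]``.  The specific force is rotated
    to the world frame with the pitch, gravity subtracted, integrated to
    velocity; a linear drift correction forces the velocity to zero at
    both anchors (skipped when ``apply_zupt=False``, for validating the
    raw kinematics); a second integration yields position.

    Toe clearance = sensor height + lever-arm correction
    ``lever_arm · (sin pitch − sin pitch_midstance)``, maximised over the
    stride.
    """
    a0, a1 = anchors
    fs = rec.fs
    if (a1 - a0) / fs < min_duration_s:
        raise IntegrationError("midstance anchors closer than the minimum stride time")
    if not (0 <= a0 < a1 < rec.n_samples):
        raise IntegrationError("anchors outside the recording")
    sl = slice(a0, a1 + 1)
    pitch = np.asarray(pitch_deg, dtype=float)
    if pitch.shape[0] != a1 - a0 + 1:
        raise IntegrationError("pitch trace does not cover the anchor interval")

    th = np.radians(pitch)
    ct, st = np.cos(th), np.sin(th)
    fx = rec.acc[sl, 0]
    fy = rec.acc[sl, 1]
    # sensor -> world (sagittal): rotate by pitch, then remove gravity
    ax = ct * fx - st * fy
    ay = st * fx + ct * fy - G
    t = rec.t[sl]

    vx = _cumtrapz0(ax, t)
    vy = _cumtrapz0(ay, t)
    if apply_zupt:
        ramp = (t - t[0]) / (t[-1] - t[0])
        vx = vx - ramp * vx[-1]
        vy = vy - ramp * vy[-1]
    px = _cumtrapz0(vx, t)
    py = _cumtrapz0(vy, t)

    height = py + lever_arm * (st - st[0])
    return FootTrajectory(
        start=a0,
        end=a1,
        position=np.column_stack([px, py]),
        velocity=np.column_stack([vx, vy]),
        stride_length=float(abs(px[-1])),
        clearance=float(height.max()),
        closing_height=float(py[-1]),
    )
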