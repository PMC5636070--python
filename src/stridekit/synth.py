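"""Forward-kinematic simulator of foot-mounted IMU signals during gait.

The simulator plans, per stride, a twice continuously differentiable toe
trajectory and sagittal pitch course in closed form, places the sensor a
fixed lever arm behind the toe on the foot axis, and derives the ideal
6-axis IMU signal by rigid-body kinematics.  Every quantity a downstream
estimator should recover — stride length, stride/stance/swing times, event
times, heel-strike and toe-off angles, toe clearance — is therefore known
exactly by construction, independent of sensor noise.

One stride runs midstance-to-midstance over a period ``T``:

* a flat-foot window around each bounding midstance in which the foot is
  exactly stationary (pitch 0, zero velocity) — the anchor the
  zero-velocity-update reconstruction relies on;
* pitch rate built from three smooth pulses: a negative plantarflexion
  pulse peaking exactly at toe-off, a positive swing pulse (with a rate
  plateau when the required rotation would otherwise exceed a realistic
  peak angular velocity), and a negative pulse peaking exactly at heel
  strike.  Pulse areas are solved so the pitch at toe-off and heel strike
  equals the requested angles and the pitch returns to zero;
* a minimum-jerk horizontal toe displacement equal to the stride length and
  a smooth clearance bump whose maximum equals the requested toe clearance.

Turning strides are modelled as pivot steps: the toe stays put while the
heading changes by ``turn_yaw`` (clockwise-positive) during the swing
window, with a reduced-amplitude pitch pattern.  This mimics the short
on-the-spot steps subjects take during the 180° turns of a 4×10 m walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .io import ACC_RANGE, DEFAULT_FS, G, GYR_RANGE, ImuRecording, SubjectRecord

__all__ = [
    "StrideSpec",
    "StrideDistribution",
    "CohortSpec",
    "GroundTruth",
    "StridePlan",
    "plan_stride_trajectory",
    "synthesize_recording",
    "synthesize_walk",
    "synthesize_cohort",
    "CohortDataset",
    "default_stride_distribution",
    "pd_reference_distribution",
    "control_reference_distribution",
    "SENSOR_LEVER_ARM",
    "DEFAULT_NOISE_SD",
]

#: Sensor mounting lever arm: distance from toe to sensor along the foot
#: axis, metres.  The simulator emits signals for this geometry and the
#: trajectory reconstruction assumes the same value.
SENSOR_LEVER_ARM = 0.10

#: Default additive white-noise scales (accelerometer m/s², gyroscope °/s),
#: a plausible MEMS noise floor for this sensor class.
DEFAULT_NOISE_SD = (0.05, 0.5)

# Anti-aliasing front end emulated by the simulator: the ideal continuous
# signals are rendered on an oversampled grid, low-passed with a zero-phase
# FIR, and decimated to the output rate — like a real IMU's analogue filter
# before its ADC.  Zero-phase filtering preserves the locations of the
# locally symmetric event peaks and (because pitch curvature vanishes at
# the events) the pitch values there; flat-foot windows are wider than the
# kernel support, so midstance anchors and per-stride displacements are
# untouched.  White sensor noise is added after decimation.
_AA_OVERSAMPLE = 8
_AA_NUMTAPS = 33
_AA_CUTOFF_HZ = 16.0

#: Peak sagittal angular-rate target, °/s.  When a swing would require more,
#: the swing pulse grows a plateau instead of a taller peak, keeping the
#: signal inside the ±500 °/s gyroscope range for typical strides.
_RATE_CAP = 480.0

# Shape constants of the stride plan:
_MS_POS = 0.35      # midstance position within stance (fraction from HS);
                    # foot-flat occurs in the first half of stance, leaving
                    # most of late stance for the push-off rotation
_FLAT_HALF = 0.10   # flat-foot half-window as a fraction of stance time
_W_PEAK = 0.06      # half-width (s) of the symmetric event peaks at TO/HS
_RHO_POST = 1.21    # required event-peak prominence over the neighbouring
                    # plateau *after* anti-alias filtering; the pre-filter
                    # ratio compensates the width-dependent peak attenuation
_BETA_HS = 0.20     # fraction of the HS angle shed during the HS peak rise
_EDGE = 0.06        # cos² edge width (s) of the broad approach/landing pulses
_MIN_EDGE = 0.04    # minimum swing-pulse edge width, s

_SPEC_ERROR = "invalid StrideSpec: "


class SpecError(ValueError):
    """Stride or cohort specification violates its invariants."""


class SamplingError(ValueError):
    """Sampling rate too low to represent a stride."""


@dataclass(frozen=True)
class StrideSpec:
    """Target parameters of one stride (the simulator's ground truth).

    Angles follow the sagittal convention used throughout the package:
    toes-up pitch positive, so heel-strike angles are positive and toe-off
    angles negative.  ``turn_yaw`` is the net heading change in degrees,
    clockwise-positive.
    """

    stride_length: float = 1.23      # m
    stride_time: float = 1.04        # s
    stance_fraction: float = 0.639   # stance time / stride time
    max_clearance: float = 0.143     # m, peak toe height in swing
    hs_angle: float = 22.1           # °
    to_angle: float = -56.4          # °
    is_turning: bool = False
    turn_yaw: float = 0.0            # °, clockwise-positive

    def validate(self) -> None:
        if self.stride_length < 0:
            raise SpecError(_SPEC_ERROR + "stride_length must be >= 0")
        if not self.stride_time > 0:
            raise SpecError(_SPEC_ERROR + "stride_time must be > 0")
        if not 0.0 < self.stance_fraction < 1.0:
            raise SpecError(_SPEC_ERROR + "stance_fraction must be in (0, 1)")
        if self.stance_fraction > 0.9:
            raise SpecError(_SPEC_ERROR + "stance_fraction above 0.9 leaves no swing")
        if self.max_clearance < 0:
            raise SpecError(_SPEC_ERROR + "max_clearance must be >= 0")
        if self.hs_angle < 0 or self.to_angle > 0:
            raise SpecError(_SPEC_ERROR + "need hs_angle >= 0 >= to_angle")


# ---------------------------------------------------------------------------
# smooth pulse primitive


#: Fraction of a pulse edge's width·height covered by a cos⁴ ramp.
_EDGE_AREA = 3.0 / 8.0


class _SmoothPulse:
    """cos⁴-edged pulse with optional plateau: rate, running integral, rate
    derivative — all in closed form and vectorized.

    The pulse rises over ``[p0 - wa, p0]``, holds ``M`` on ``[p0, p1]`` and
    falls over ``[p1, p1 + wb]``.  cos⁴ ramps join with three continuous
    derivatives, which keeps the derived acceleration signal smooth enough
    that 51.2 Hz trapezoidal integration of the sampled signal is accurate
    to the millimetre; the rate is stationary on the plateau, so a detector
    looking for a rate extremum finds the plateau centre.
    """

    def __init__(self, p0: float, p1: float, wa: float, wb: float, M: float):
        if p1 < p0 or wa < 0 or wb < 0:
            raise ValueError("inconsistent pulse geometry")
        self.p0, self.p1, self.wa, self.wb, self.M = p0, p1, wa, wb, M

    # areas ------------------------------------------------------------
    @property
    def area_before_p0(self) -> float:
        return self.M * self.wa * _EDGE_AREA

    @property
    def area(self) -> float:
        return self.M * (self.wa + self.wb) * _EDGE_AREA + self.M * (self.p1 - self.p0)

    # evaluation -------------------------------------------------------
    @staticmethod
    def _edge(phi: np.ndarray) -> np.ndarray:
        return np.cos(phi) ** 4

    @staticmethod
    def _edge_int(phi: np.ndarray) -> np.ndarray:
        # ∫cos⁴φ dφ = 3φ/8 + sin(2φ)/4 + sin(4φ)/32
        return 3.0 * phi / 8.0 + np.sin(2.0 * phi) / 4.0 + np.sin(4.0 * phi) / 32.0

    def rate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.M == 0.0:
            return out
        if self.wa > 0:
            m = (t >= self.p0 - self.wa) & (t < self.p0)
            out[m] = self.M * self._edge(np.pi * (t[m] - self.p0) / (2 * self.wa))
        m = (t >= self.p0) & (t <= self.p1)
        out[m] = self.M
        if self.wb > 0:
            m = (t > self.p1) & (t <= self.p1 + self.wb)
            out[m] = self.M * self._edge(np.pi * (t[m] - self.p1) / (2 * self.wb))
        return out

    def integral(self, t: np.ndarray) -> np.ndarray:
        """∫ rate from −∞ to t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.M == 0.0:
            return out
        a_rise = self.M * self.wa * _EDGE_AREA
        a_plat = self.M * (self.p1 - self.p0)

        if self.wa > 0:
            m = (t >= self.p0 - self.wa) & (t < self.p0)
            phi = np.pi * (t[m] - self.p0) / (2 * self.wa)
            scale = self.M * 2.0 * self.wa / np.pi
            out[m] = scale * (self._edge_int(phi) - self._edge_int(np.array(-np.pi / 2)))
        m = (t >= self.p0) & (t <= self.p1)
        out[m] = a_rise + self.M * (t[m] - self.p0)
        if self.wb > 0:
            m = (t > self.p1) & (t <= self.p1 + self.wb)
            phi = np.pi * (t[m] - self.p1) / (2 * self.wb)
            scale = self.M * 2.0 * self.wb / np.pi
            out[m] = a_rise + a_plat + scale * self._edge_int(phi)
        m = t > self.p1 + self.wb
        out[m] = self.area
        return out

    def rate_deriv(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.M == 0.0:
            return out
        if self.wa > 0:
            m = (t >= self.p0 - self.wa) & (t < self.p0)
            phi = np.pi * (t[m] - self.p0) / (2 * self.wa)
            out[m] = -self.M * (2 * np.pi / self.wa) * np.cos(phi) ** 3 * np.sin(phi)
        if self.wb > 0:
            m = (t > self.p1) & (t <= self.p1 + self.wb)
            phi = np.pi * (t[m] - self.p1) / (2 * self.wb)
            out[m] = -self.M * (2 * np.pi / self.wb) * np.cos(phi) ** 3 * np.sin(phi)
        return out


_ATTEN_CACHE: dict[float, float] = {}


def _peak_attenuation(w: float) -> float:
    """Apex attenuation of a cos⁴ peak of half-width ``w`` under the
    anti-aliasing kernel; used to keep event peaks prominent post-filter."""
    key = round(w, 4)
    if key not in _ATTEN_CACHE:
        from scipy.signal import firwin

        fso = DEFAULT_FS * _AA_OVERSAMPLE
        kernel = firwin(_AA_NUMTAPS, _AA_CUTOFF_HZ, fs=fso)
        t = np.arange(-4.0 * w, 4.0 * w, 1.0 / fso)
        x = np.where(np.abs(t) < w, np.cos(np.pi * t / (2 * w)) ** 4, 0.0)
        _ATTEN_CACHE[key] = float(np.convolve(x, kernel, mode="same").max())
    return _ATTEN_CACHE[key]


def _quintic_step(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """7th-order smoothstep on [0, 1] and its first two derivatives.

    The first three derivatives vanish at both ends, so position profiles
    built from it have C¹ acceleration across the junctions with the
    stationary flat-foot windows.
    """
    s = np.clip(s, 0.0, 1.0)
    p = s**4 * (35.0 - 84.0 * s + 70.0 * s**2 - 20.0 * s**3)
    dp = 140.0 * (s * (1.0 - s)) ** 3
    ddp = 420.0 * s**2 * (1.0 - s) ** 2 * (1.0 - 2.0 * s)
    return p, dp, ddp


# ---------------------------------------------------------------------------
# stride plan


@dataclass
class StridePlan:
    """Closed-form pose course of one stride (local frame, toe point).

    Local frame: x anterior along the stride heading, y superior; the
    stride starts at the opening midstance (t = 0, toe at the origin, foot
    flat and stationary) and ends at the closing midstance (t = T).
    """

    spec: StrideSpec
    T: float
    flat_half: float          # flat-foot half window, s
    t_to: float               # toe-off time, s from opening midstance
    t_hs: float               # heel-strike time
    t_clearance_peak: float
    pulses: list[_SmoothPulse]
    yaw_window: tuple[float, float] | None = None  # pivot strides only

    # ---- pitch (degrees) ------------------------------------------------
    def _accumulate(self, t, method: str) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for p in self.pulses:
            out += getattr(p, method)(t)
        return out

    def pitch_deg(self, t) -> np.ndarray:
        return self._accumulate(t, "integral")

    def pitch_rate_deg(self, t) -> np.ndarray:
        return self._accumulate(t, "rate")

    def pitch_acc_deg(self, t) -> np.ndarray:
        return self._accumulate(t, "rate_deriv")

    # ---- yaw (degrees, clockwise-positive) ------------------------------
    def _yaw_terms(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        if self.yaw_window is None or self.spec.turn_yaw == 0.0:
            z = np.zeros_like(t)
            return z, z.copy(), z.copy()
        a, b = self.yaw_window
        s = (t - a) / (b - a)
        p, dp, ddp = _quintic_step(s)
        total = self.spec.turn_yaw
        return total * p, total * dp / (b - a), total * ddp / (b - a) ** 2

    def yaw_deg(self, t) -> np.ndarray:
        return self._yaw_terms(t)[0]

    def yaw_rate_deg(self, t) -> np.ndarray:
        return self._yaw_terms(t)[1]

    # ---- toe trajectory (local sagittal frame, metres) ------------------
    def _x_terms(self, t):
        t = np.asarray(t, dtype=float)
        a = self.flat_half
        b = self.T - self.flat_half
        s = (t - a) / (b - a)
        p, dp, ddp = _quintic_step(s)
        L = self.spec.stride_length
        return L * p, L * dp / (b - a), L * ddp / (b - a) ** 2

    def _y_terms(self, t):
        t = np.asarray(t, dtype=float)
        a = self.t_to
        b = self.T - self.flat_half
        s = np.clip((t - a) / (b - a), 0.0, 1.0)
        C = self.spec.max_clearance
        sin_, cos_ = np.sin(np.pi * s), np.cos(np.pi * s)
        y = C * sin_**4
        dy = C * 4.0 * np.pi * sin_**3 * cos_ / (b - a)
        ddy = C * 4.0 * np.pi**2 * (3.0 * sin_**2 * cos_**2 - sin_**4) / (b - a) ** 2
        return y, dy, ddy

    def toe_pos(self, t) -> np.ndarray:
        """Toe position, shape (n, 2): columns x (anterior), y (up)."""
        x, _, _ = self._x_terms(t)
        y, _, _ = self._y_terms(t)
        return np.column_stack([x, y])

    def toe_acc(self, t) -> np.ndarray:
        _, _, ax = self._x_terms(t)
        _, _, ay = self._y_terms(t)
        return np.column_stack([ax, ay])

    def pose(self, t):
        """(toe position (n, 2), pitch ° (n,)) — the continuous pose course."""
        return self.toe_pos(t), self.pitch_deg(t)


def plan_stride_trajectory(spec: StrideSpec) -> StridePlan:
    """Solve the closed-form pose course meeting every ``spec`` target.

    By construction the returned plan satisfies, exactly: zero velocity and
    zero toe height at both bounding midstances, net displacement equal to
    ``stride_length``, peak toe height equal to ``max_clearance``, pitch at
    the heel-strike/toe-off instants equal to the requested angles.
    """
    spec.validate()
    T = spec.stride_time
    gamma = spec.stance_fraction
    fw = _FLAT_HALF * gamma * T
    # events located so that consecutive identical strides give exactly
    # the requested stance fraction: TO ends the stance that began at the
    # previous cycle's HS; midstance sits _MS_POS into its own stance
    t_to = (1.0 - _MS_POS) * gamma * T
    t_hs = T - _MS_POS * gamma * T

    hs = spec.hs_angle
    to = spec.to_angle

    def _tukey(lo: float, hi: float, area: float) -> _SmoothPulse | None:
        """Broad plateau'd pulse filling [lo, hi] with the given area."""
        span = hi - lo
        if span <= 0 or area == 0.0:
            return None
        we = min(_EDGE, 0.35 * span)
        m = area / (span - 2.0 * we * (1.0 - _EDGE_AREA))
        pw = span - 2.0 * we
        c = (lo + hi) / 2.0
        return _SmoothPulse(c - pw / 2.0, c + pw / 2.0, we, we, m)

    def _build_pulses(w_peak: float) -> tuple[list[_SmoothPulse], float]:
        """Pulse set for a given event-peak half-width; returns (pulses,
        peak swing rate)."""
        pulses: list[_SmoothPulse] = []
        w1 = min(w_peak, 0.45 * (t_to - fw))
        w3 = min(w_peak, 0.45 * (T - fw - t_hs))

        theta_min = to
        if to < 0.0:
            # push-off: broad plantarflexion approach ending cleanly before
            # a symmetric peak pulse at toe-off, so the rate minimum sits
            # exactly at the event with locally symmetric curvature
            wa_lo, wa_hi = fw, t_to - w1
            span = wa_hi - wa_lo
            we = min(_EDGE, 0.35 * span)
            kappa = span - 2.0 * we * (1.0 - _EDGE_AREA)
            rho = _RHO_POST / _peak_attenuation(w1)
            m_a = to / (kappa + rho * _EDGE_AREA * w1)
            m1 = rho * m_a
            s1 = _EDGE_AREA * m1 * w1
            approach = _tukey(wa_lo, wa_hi, to - s1)
            if approach is not None:
                pulses.append(approach)
            pulses.append(_SmoothPulse(t_to, t_to, w1, w1, m1))
            theta_min = to + s1

        theta_at_hs_rise = hs
        if hs > 0.0:
            # heel strike: symmetric peak pulse at the event, then a gentle
            # landing pulse returning the foot to flat.  The peak's share
            # of the rotation adapts so it stays well above the landing
            # plateau even for short strides (the anti-aliasing front end
            # attenuates the narrow peak more than the broad plateau).
            span_l = (T - fw) - (t_hs + w3)
            we_l = min(_EDGE, 0.35 * span_l)
            kappa_l = span_l - 2.0 * we_l * (1.0 - _EDGE_AREA)
            x = (_RHO_POST / _peak_attenuation(w3)) * _EDGE_AREA * w3 / max(kappa_l, 1e-6)
            beta = float(np.clip(x / (1.0 + x), _BETA_HS, 0.5))
            s3 = -beta * hs
            m3 = s3 / (_EDGE_AREA * w3)
            pulses.append(_SmoothPulse(t_hs, t_hs, w3, w3, m3))
            landing = _tukey(t_hs + w3, T - fw, -(hs + s3))
            if landing is not None:
                pulses.append(landing)
            theta_at_hs_rise = hs - s3  # pitch just before the HS peak rise

        # swing pulse: dorsiflexion from the post-push-off minimum up to
        # the pre-heel-strike maximum, rate-capped via a plateau
        a2 = theta_at_hs_rise - theta_min
        lo = t_to + w1
        hi = t_hs - w3
        w2_total = hi - lo
        if w2_total <= 0:
            raise SpecError(_SPEC_ERROR + "no swing room for the stride geometry")
        m2 = 0.0
        if a2 > 0:
            m2 = a2 / (_EDGE_AREA * w2_total)  # pure cos⁴ pulse, no plateau
            if m2 <= _RATE_CAP:
                w, pw = w2_total / 2.0, 0.0
            else:
                m2 = _RATE_CAP
                w = (w2_total - a2 / m2) / (2.0 * (1.0 - _EDGE_AREA))
                pw = w2_total - 2.0 * w
                if w < _MIN_EDGE:
                    # very fast stride: keep edges sane, accept a taller peak
                    w = min(_MIN_EDGE, w2_total / 2.0)
                    pw = max(w2_total - 2.0 * w, 0.0)
                    m2 = a2 / (pw + 2.0 * _EDGE_AREA * w)
            c = (lo + hi) / 2.0
            pulses.append(_SmoothPulse(c - pw / 2.0, c + pw / 2.0, w, w, m2))
        return pulses, m2

    # prefer wide, well-resolved event peaks; for fast strides whose swing
    # would saturate the gyroscope, narrow the peaks to free swing room and
    # angle budget before accepting saturation
    pulses, m2 = _build_pulses(_W_PEAK)
    if m2 > GYR_RANGE:
        narrow, m2_narrow = _build_pulses(0.045)
        if m2_narrow < m2:
            pulses = narrow

    yaw_window = None
    if spec.is_turning and spec.turn_yaw != 0.0:
        yaw_window = (t_to, t_hs)

    return StridePlan(
        spec=spec,
        T=T,
        flat_half=fw,
        t_to=t_to,
        t_hs=t_hs,
        t_clearance_peak=(t_to + (T - fw)) / 2.0,
        pulses=pulses,
        yaw_window=yaw_window,
    )


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class GroundTruth:
    """Exact per-stride labels for a synthesized recording.

    Times are absolute seconds from the start of the recording; boundary
    and event sample indices are the nearest-sample rounding of those
    times.  ``boundaries`` has one more entry than there are strides
    (shared midstance boundaries, half-open index convention).
    """

    fs: float
    specs: list[StrideSpec]
    boundary_times: np.ndarray       # (n+1,) midstance boundary times, s
    ms_times: np.ndarray             # (n,) opening midstance per stride
    to_times: np.ndarray             # (n,)
    hs_times: np.ndarray             # (n,)
    clearance_peak_times: np.ndarray  # (n,)
    headings: np.ndarray             # (n,) heading at stride start, ° CW
    displacements: np.ndarray        # (n, 3) world displacement, m

    @property
    def n_strides(self) -> int:
        return len(self.specs)

    @property
    def boundaries(self) -> np.ndarray:
        return np.rint(self.boundary_times * self.fs).astype(int)

    @property
    def is_turning(self) -> np.ndarray:
        return np.array([s.is_turning for s in self.specs])

    @property
    def stride_lengths(self) -> np.ndarray:
        return np.array([s.stride_length for s in self.specs])

    @property
    def stride_times(self) -> np.ndarray:
        return np.array([s.stride_time for s in self.specs])

    @property
    def max_clearances(self) -> np.ndarray:
        return np.array([s.max_clearance for s in self.specs])

    @property
    def turn_yaws(self) -> np.ndarray:
        return np.array([s.turn_yaw for s in self.specs])

    def measured_pair_truth(self) -> dict[str, np.ndarray]:
        """Ground truth on the measurement grid of consecutive stride pairs.

        The pipeline times strides heel-strike to heel-strike and measures
        lengths midstance to midstance, pairing each segment with its
        successor; this returns the matching truths for pairs (k, k+1)
        where both strides are non-turning.
        """
        n = self.n_strides
        idx = [
            k
            for k in range(n - 1)
            if not self.specs[k].is_turning and not self.specs[k + 1].is_turning
        ]
        idx = np.array(idx, dtype=int)
        if idx.size == 0:
            empty = np.empty(0)
            return {
                "index": idx,
                "stride_time": empty,
                "stride_length": empty,
                "stance_pct": empty,
                "clearance": empty,
            }
        hs1 = self.hs_times[idx]
        hs2 = self.hs_times[idx + 1]
        to2 = self.to_times[idx + 1]
        stride_time = hs2 - hs1
        stance_pct = 100.0 * (to2 - hs1) / stride_time
        return {
            "index": idx,
            "stride_time": stride_time,
            "stride_length": self.stride_lengths[idx],
            "stance_pct": stance_pct,
            "clearance": self.max_clearances[idx],
        }


# ---------------------------------------------------------------------------
# world-frame assembly


def _rot_y(alpha: np.ndarray):
    """Heading rotation: local sagittal (x, y) plane into the world frame.

    ``alpha`` is the clockwise-positive heading in radians about the
    vertical; returns the world components of a local vector (x, y, z_loc).
    """
    c, s = np.cos(alpha), np.sin(alpha)

    def apply(vx, vy, vz):
        return np.stack([vx * c + vz * s, vy, -vx * s + vz * c], axis=-1)

    return apply


def _sensor_world_kinematics(plan: StridePlan, tau: np.ndarray, heading_deg: float):
    """World position/acceleration of the sensor and its frame angles.

    Returns (pos (n,3), acc (n,3), pitch_rad, heading_rad_cw) for local
    stride times ``tau``.
    """
    theta = np.deg2rad(plan.pitch_deg(tau))
    omega = np.deg2rad(plan.pitch_rate_deg(tau))
    dot_omega = np.deg2rad(plan.pitch_acc_deg(tau))
    yaw, yaw_rate, yaw_acc = plan._yaw_terms(tau)
    alpha = np.deg2rad(heading_deg + yaw)       # CW-positive heading
    nu = np.deg2rad(yaw_rate)
    dot_nu = np.deg2rad(yaw_acc)

    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(alpha), np.sin(alpha)

    # foot-axis unit vector and its second time derivative (world frame),
    # consistent with the heading rotation x -> (x cos a, 0, -x sin a):
    # u = (ct*ca, st, -ct*sa)
    u = np.stack([ct * ca, st, -ct * sa], axis=-1)
    uddx = (
        -dot_omega * st * ca
        - (omega**2 + nu**2) * ct * ca
        + 2.0 * omega * nu * st * sa
        - dot_nu * ct * sa
    )
    uddy = dot_omega * ct - omega**2 * st
    uddz = (
        dot_omega * st * sa
        + (omega**2 + nu**2) * ct * sa
        + 2.0 * omega * nu * st * ca
        - dot_nu * ct * ca
    )
    udd = np.stack([uddx, uddy, uddz], axis=-1)

    toe = plan.toe_pos(tau)
    toe_acc = plan.toe_acc(tau)
    rot = _rot_y(np.deg2rad(np.full_like(tau, heading_deg)))
    toe_w = rot(toe[:, 0], toe[:, 1], np.zeros_like(tau))
    toe_acc_w = rot(toe_acc[:, 0], toe_acc[:, 1], np.zeros_like(tau))

    pos = toe_w - SENSOR_LEVER_ARM * u
    acc = toe_acc_w - SENSOR_LEVER_ARM * udd
    return pos, acc, theta, alpha


def _specific_force_and_gyro(acc_world, theta, alpha, omega_deg, nu_deg):
    """Ideal sensor readings given world acceleration and frame angles."""
    g_vec = np.array([0.0, G, 0.0])
    v = acc_world + g_vec
    # world -> sensor: undo heading (inverse of x -> (x cos a, 0, -x sin a)),
    # then undo pitch
    ca, sa = np.cos(alpha), np.sin(alpha)
    vx = v[:, 0] * ca - v[:, 2] * sa
    vy = v[:, 1]
    vz = v[:, 0] * sa + v[:, 2] * ca
    ct, st = np.cos(theta), np.sin(theta)
    fx = vx * ct + vy * st
    fy = -vx * st + vy * ct
    fz = vz
    acc_s = np.stack([fx, fy, fz], axis=-1)
    gyr_s = np.stack(
        [nu_deg * st, nu_deg * ct, omega_deg], axis=-1
    )
    return acc_s, gyr_s


# ---------------------------------------------------------------------------
# recording synthesis


def synthesize_recording(
    strides: Sequence[StrideSpec],
    fs: float = DEFAULT_FS,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator | None = None,
    pad_s: float = 0.4,
    sway: bool = True,
    side: str = "left",
    subject_id: str = "synthetic",
    walk_id: str = "walk",
    headings: Sequence[float] | None = None,
) -> tuple[ImuRecording, GroundTruth]:
    """Sample an ideal stride sequence into a noisy IMU recording.

    Strides abut midstance-to-midstance; ``pad_s`` seconds of quiet
    standing (with a faint physiological sway unless ``sway=False``) are
    prepended and appended.  ``headings`` optionally gives each stride's
    heading in degrees (clockwise-positive); turning strides additionally
    apply their own ``turn_yaw`` within the stride.

    Returns the recording plus exact :class:`GroundTruth` labels.
    """
    if len(strides) == 0:
        raise SpecError("need at least one stride")
    if not fs > 0:
        raise SpecError("fs must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    plans = [plan_stride_trajectory(s) for s in strides]
    for p in plans:
        if p.T * fs < 8:
            raise SamplingError(
                f"stride of {p.T} s has fewer than 8 samples at {fs} Hz"
            )
    if headings is None:
        headings = np.zeros(len(strides))
    headings = np.asarray(headings, dtype=float)
    if headings.shape[0] != len(strides):
        raise SpecError("headings must match the number of strides")

    boundary_times = pad_s + np.concatenate(
        [[0.0], np.cumsum([p.T for p in plans])]
    )
    total = boundary_times[-1] + pad_s
    n = int(round(total * fs)) + 1

    # render the ideal continuous signals on an oversampled grid
    over = _AA_OVERSAMPLE
    fso = fs * over
    n_o = (n - 1) * over + 1
    t_o = np.arange(n_o) / fso

    acc_o = np.zeros((n_o, 3))
    gyr_o = np.zeros((n_o, 3))
    acc_o[:, 1] = G  # standing: specific force is +1 g superior

    displacements = np.zeros((len(strides), 3))
    for k, plan in enumerate(plans):
        t0, t1 = boundary_times[k], boundary_times[k + 1]
        m = (t_o >= t0) & (t_o < t1) if k < len(plans) - 1 else (t_o >= t0) & (t_o <= t1)
        tau = t_o[m] - t0
        pos, acc_w, theta, alpha = _sensor_world_kinematics(plan, tau, headings[k])
        omega_deg = plan.pitch_rate_deg(tau)
        nu_deg = plan.yaw_rate_deg(tau)
        acc_s, gyr_s = _specific_force_and_gyro(acc_w, theta, alpha, omega_deg, nu_deg)
        acc_o[m] = acc_s
        gyr_o[m] = gyr_s
        end = np.array([plan.T])
        rot = _rot_y(np.deg2rad(np.array([headings[k]])))
        toe_end = plan.toe_pos(end)
        displacements[k] = rot(toe_end[:, 0], toe_end[:, 1], np.array([0.0]))[0]

    if sway and pad_s > 0:
        for m in (t_o < boundary_times[0], t_o > boundary_times[-1]):
            tp = t_o[m]
            gyr_o[m, 0] += 4.0 * np.sin(2 * np.pi * 0.7 * tp + 0.3)
            gyr_o[m, 1] += 3.0 * np.sin(2 * np.pi * 1.1 * tp + 1.1)
            gyr_o[m, 2] += 5.0 * np.sin(2 * np.pi * 0.9 * tp + 2.0)
            acc_o[m, 0] += 0.12 * np.sin(2 * np.pi * 0.9 * tp + 0.8)

    # anti-aliasing front end: zero-phase FIR low-pass, then decimation
    from scipy.signal import firwin

    kernel = firwin(_AA_NUMTAPS, _AA_CUTOFF_HZ, fs=fso)
    half = _AA_NUMTAPS // 2
    acc = np.empty((n, 3))
    gyr = np.empty((n, 3))
    for ch in range(3):
        a = np.convolve(np.pad(acc_o[:, ch], half, mode="edge"), kernel, "valid")
        g = np.convolve(np.pad(gyr_o[:, ch], half, mode="edge"), kernel, "valid")
        acc[:, ch] = a[::over]
        gyr[:, ch] = g[::over]
    t = t_o[::over]

    acc_sd, gyr_sd = noise_sd
    if acc_sd > 0:
        acc = acc + rng.normal(0.0, acc_sd, size=acc.shape)
    if gyr_sd > 0:
        gyr = gyr + rng.normal(0.0, gyr_sd, size=gyr.shape)

    n_clip_acc = int(np.sum(np.abs(acc) > ACC_RANGE))
    n_clip_gyr = int(np.sum(np.abs(gyr) > GYR_RANGE))
    acc = np.clip(acc, -ACC_RANGE, ACC_RANGE)
    gyr = np.clip(gyr, -GYR_RANGE, GYR_RANGE)

    rec = ImuRecording(
        side=side,
        fs=fs,
        t=t,
        acc=acc,
        gyr=gyr,
        subject_id=subject_id,
        walk_id=walk_id,
        meta={"n_clipped_acc": n_clip_acc, "n_clipped_gyr": n_clip_gyr},
    )
    truth = GroundTruth(
        fs=fs,
        specs=list(strides),
        boundary_times=boundary_times,
        ms_times=boundary_times[:-1].copy(),
        to_times=boundary_times[:-1] + np.array([p.t_to for p in plans]),
        hs_times=boundary_times[:-1] + np.array([p.t_hs for p in plans]),
        clearance_peak_times=boundary_times[:-1]
        + np.array([p.t_clearance_peak for p in plans]),
        headings=headings.copy(),
        displacements=displacements,
    )
    return rec, truth


def stride_is_feasible(spec: StrideSpec, margin: float = 1.0) -> bool:
    """True when the planned sagittal rates fit the gyroscope range.

    ``margin`` scales the admissible range (use < 1 to demand headroom).
    """
    try:
        plan = plan_stride_trajectory(spec)
    except SpecError:
        return False
    peak = max(abs(p.M) for p in plan.pulses) if plan.pulses else 0.0
    return peak <= margin * GYR_RANGE


# ---------------------------------------------------------------------------
# stride distributions


@dataclass(frozen=True)
class StrideDistribution:
    """Independent Gaussian stride-to-stride (or subject-to-subject)
    distributions over the :class:`StrideSpec` fields, with physiological
    truncation bounds applied by rejection."""

    mean: StrideSpec = StrideSpec()
    sd: dict = field(
        default_factory=lambda: {
            "stride_length": 0.05,
            "stride_time": 0.03,
            "stance_fraction": 0.008,
            "max_clearance": 0.010,
            "hs_angle": 1.5,
            "to_angle": 1.5,
        }
    )

    _BOUNDS = {
        "stride_length": (0.2, 2.5),
        "stride_time": (0.6, 2.2),
        "stance_fraction": (0.50, 0.80),
        "max_clearance": (0.01, 0.30),
        "hs_angle": (2.0, 45.0),
        "to_angle": (-80.0, -5.0),
    }

    def sample(self, rng: np.random.Generator, n: int = 1) -> list[StrideSpec]:
        """Draw strides, rejecting draws the sensor cannot represent.

        Besides the per-field physiological bounds, a joint feasibility
        constraint applies: the planned sagittal rates must stay inside
        the ±500 °/s gyroscope range (fast strides with full angle
        excursions would saturate the sensor and carry no usable signal).
        Infeasible draws are resampled.
        """
        out = []
        for _ in range(n):
            spec = None
            for _attempt in range(200):
                values = {}
                for name, (lo, hi) in self._BOUNDS.items():
                    mu = getattr(self.mean, name)
                    sd = self.sd.get(name, 0.0)
                    x = mu if sd == 0 else rng.normal(mu, sd)
                    for _inner in range(100):
                        if lo <= x <= hi:
                            break
                        x = rng.normal(mu, sd)
                    values[name] = float(np.clip(x, lo, hi))
                candidate = StrideSpec(**values)
                if stride_is_feasible(candidate):
                    spec = candidate
                    break
            if spec is None:  # pragma: no cover - pathological distribution
                raise SpecError(
                    "no sensor-feasible stride found in 200 draws; "
                    "distribution incompatible with the gyroscope range"
                )
            out.append(spec)
        return out

    def sample_stratified(self, rng: np.random.Generator, n: int) -> list[StrideSpec]:
        """Latin-hypercube draw of ``n`` specs (stratified per parameter).

        Each parameter's marginal is sampled on a jittered stratified grid
        of the truncated normal, independently permuted across parameters,
        so a small cohort represents the configured distribution with far
        less sampling error than independent draws.  Sensor-infeasible
        combinations fall back to independent rejection draws.
        """
        from scipy.stats import norm

        columns = {}
        for name, (lo, hi) in self._BOUNDS.items():
            mu = getattr(self.mean, name)
            sd = self.sd.get(name, 0.0)
            if sd == 0:
                columns[name] = np.full(n, float(np.clip(mu, lo, hi)))
                continue
            u_lo = norm.cdf((lo - mu) / sd)
            u_hi = norm.cdf((hi - mu) / sd)
            strata = (rng.permutation(n) + rng.uniform(size=n)) / n
            u = u_lo + (u_hi - u_lo) * strata
            columns[name] = np.clip(mu + sd * norm.ppf(u), lo, hi)
        out = []
        for i in range(n):
            spec = StrideSpec(**{name: float(columns[name][i]) for name in columns})
            if not stride_is_feasible(spec):
                spec = self.sample(rng, 1)[0]
            out.append(spec)
        return out


def default_stride_distribution() -> StrideDistribution:
    """Healthy-walker stride distribution (control-group means, modest
    stride-to-stride variability)."""
    return StrideDistribution()


# Group-level gait parameters of large PD / age-matched control cohorts
# (clinical reference values; mean, standard error of the mean, cohort n).
_PD_REFERENCE = {
    "n": 190,
    "stride_length": (1.15, 0.02),
    "stride_time": (1.10, 0.01),
    "stance_fraction": (0.650, 0.002),
    "max_clearance": (0.106, 0.003),
    "hs_angle": (19.0, 0.7),
    "to_angle": (-54.8, 0.7),
}
_CONTROL_REFERENCE = {
    "n": 101,
    "stride_length": (1.23, 0.02),
    "stride_time": (1.04, 0.01),
    "stance_fraction": (0.639, 0.002),
    "max_clearance": (0.143, 0.005),
    "hs_angle": (22.1, 1.0),
    "to_angle": (-56.4, 0.9),
}


def _reference_distribution(ref: dict) -> StrideDistribution:
    """Between-subject distribution implied by mean ± SEM at cohort size n
    (SD = SEM·√n)."""
    root_n = math.sqrt(ref["n"])
    mean = StrideSpec(
        **{k: v[0] for k, v in ref.items() if k != "n"}
    )
    sd = {k: v[1] * root_n for k, v in ref.items() if k != "n"}
    return StrideDistribution(mean=mean, sd=sd)


def pd_reference_distribution() -> StrideDistribution:
    """Between-subject stride distribution of a reference PD cohort."""
    return _reference_distribution(_PD_REFERENCE)


def control_reference_distribution() -> StrideDistribution:
    """Between-subject stride distribution of a reference control cohort."""
    return _reference_distribution(_CONTROL_REFERENCE)


#: Default within-subject (stride-to-stride) SDs used for cohort synthesis.
WITHIN_SUBJECT_SD = {
    "stride_length": 0.04,
    "stride_time": 0.025,
    "stance_fraction": 0.008,
    "max_clearance": 0.006,
    "hs_angle": 1.2,
    "to_angle": 1.2,
}


# ---------------------------------------------------------------------------
# walks


def synthesize_walk(
    stride_source: StrideSpec | StrideDistribution | Callable[[np.random.Generator], StrideSpec],
    n_strides_per_bout: int = 8,
    n_bouts: int = 4,
    n_turn_strides: int = 2,
    fs: float = DEFAULT_FS,
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator | None = None,
    sides: Sequence[str] = ("left", "right"),
    subject_id: str = "synthetic",
    walk_id: str = "walk",
    initiation_scale: tuple[float, float] | None = None,
) -> dict[str, tuple[ImuRecording, GroundTruth]]:
    """Simulate a multi-bout walk with 180° turns between bouts.

    The walk emulates the 4×10 m protocol: ``n_bouts`` straight bouts of
    ``n_strides_per_bout`` strides, separated by 180° turns executed as
    ``n_turn_strides`` pivot steps each.  Turn direction alternates
    clockwise, counter-clockwise, clockwise, …  Each foot gets its own
    independent stride sequence and recording.

    ``initiation_scale`` optionally shortens/slows the first two strides of
    every bout: a pair ``(length_factor, time_factor)`` applied at factor
    and (factor+1)/2 for strides one and two.

    Returns ``{side: (recording, ground_truth)}``.
    """
    if n_strides_per_bout < 3:
        raise SpecError("need at least 3 strides per bout")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def draw(r: np.random.Generator) -> StrideSpec:
        if isinstance(stride_source, StrideSpec):
            return stride_source
        if isinstance(stride_source, StrideDistribution):
            return stride_source.sample(r, 1)[0]
        return stride_source(r)

    out = {}
    for side in sides:
        specs: list[StrideSpec] = []
        headings: list[float] = []
        heading = 0.0
        for bout in range(n_bouts):
            for j in range(n_strides_per_bout):
                s = draw(rng)
                if initiation_scale is not None and j < 2:
                    lf, tf = initiation_scale
                    if j == 1:
                        lf, tf = (lf + 1.0) / 2.0, (tf + 1.0) / 2.0
                    s = replace(
                        s,
                        stride_length=s.stride_length * lf,
                        stride_time=s.stride_time * tf,
                    )
                specs.append(s)
                headings.append(heading)
            if bout < n_bouts - 1:
                turn_sign = 1.0 if bout % 2 == 0 else -1.0  # CW, CCW, CW, ...
                per = turn_sign * 180.0 / n_turn_strides
                base = draw(rng)
                for _ in range(n_turn_strides):
                    specs.append(
                        replace(
                            base,
                            stride_length=0.0,
                            max_clearance=0.02,
                            is_turning=True,
                            turn_yaw=per,
                        )
                    )
                    headings.append(heading)
                    heading += per
        rec, truth = synthesize_recording(
            specs,
            fs=fs,
            noise_sd=noise_sd,
            seed=rng,
            side=side,
            subject_id=subject_id,
            walk_id=walk_id,
            headings=headings,
        )
        out[side] = (rec, truth)
    return out


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Specification of one synthetic group of walking subjects.

    ``between`` gives the subject-mean distribution; ``within_sd`` the
    stride-to-stride SDs around each subject's means.  When
    ``n_strides_per_bout`` is None the bout stride count is derived from
    each subject's stride length and the 10 m bout distance.
    """

    group: str = "PD"
    n_subjects: int = 50
    between: StrideDistribution = field(default_factory=pd_reference_distribution)
    within_sd: dict = field(default_factory=lambda: dict(WITHIN_SUBJECT_SD))
    n_strides_per_bout: int | None = None
    n_bouts: int = 4
    n_turn_strides: int = 2
    noise_sd: tuple[float, float] = DEFAULT_NOISE_SD
    fs: float = DEFAULT_FS
    seed: int = 0
    initiation_scale: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise SpecError("cohort needs at least 2 subjects")
        if any(v < 0 for v in self.within_sd.values()):
            raise SpecError("within-subject SDs must be >= 0")


@dataclass
class CohortDataset:
    """Synthesized cohort: per-subject recordings, truths and metadata."""

    spec: CohortSpec
    subjects: list[SubjectRecord]
    true_subject_means: list[StrideSpec]
    walks: dict[str, dict[str, tuple[ImuRecording, GroundTruth]]]  # subject -> side -> ...


def synthesize_cohort(spec: CohortSpec) -> CohortDataset:
    """Draw subject means from the group distribution, then per-stride
    values around each subject's means, and synthesize each subject's
    4×10 m walk for both feet."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    walks = {}
    # subject means drawn stratified (Latin hypercube) so the cohort
    # represents the configured group distribution with minimal
    # cohort-level sampling error
    means = spec.between.sample_stratified(rng, spec.n_subjects)
    for i in range(spec.n_subjects):
        sid = f"{spec.group}{i:03d}"
        subject_mean = means[i]
        per_stride = StrideDistribution(mean=subject_mean, sd=dict(spec.within_sd))
        if spec.n_strides_per_bout is None:
            n_per_bout = int(np.clip(round(10.0 / subject_mean.stride_length), 4, 16))
        else:
            n_per_bout = spec.n_strides_per_bout
        walks[sid] = synthesize_walk(
            per_stride,
            n_strides_per_bout=n_per_bout,
            n_bouts=spec.n_bouts,
            n_turn_strides=spec.n_turn_strides,
            fs=spec.fs,
            noise_sd=spec.noise_sd,
            seed=rng,
            subject_id=sid,
            walk_id="visit1",
            initiation_scale=spec.initiation_scale,
        )
        if spec.group == "PD":
            hy = int(rng.integers(1, 4))
            gait_item = int(rng.integers(0, 3))
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group="PD",
                    age=float(np.clip(rng.normal(63.7, 9.0), 36, 85)),
                    height=float(np.clip(rng.normal(1.72, 0.09), 1.45, 2.00)),
                    weight=float(np.clip(rng.normal(77.5, 12.0), 45, 130)),
                    hoehn_yahr=hy,
                    updrs_iii_total=int(np.clip(rng.normal(18.6, 10.0), 2, 50)),
                    gait_item=gait_item,
                    postural_stability_item=int(rng.integers(0, 3)),
                    visit_date="2014-01-01",
                )
            )
        else:
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group="control",
                    age=float(np.clip(rng.normal(61.2, 10.0), 41, 84)),
                    height=float(np.clip(rng.normal(1.70, 0.09), 1.45, 2.00)),
                    weight=float(np.clip(rng.normal(75.7, 12.0), 45, 130)),
                    visit_date="2014-01-01",
                )
            )
    return CohortDataset(
        spec=spec, subjects=subjects, true_subject_means=means, walks=walks
    )
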