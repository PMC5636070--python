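"""Template-based multi-dimensional DTW stride segmentation.

A normalized stride template (sagittal gyroscope by default, optionally
more channels) is matched against the continuous recording with
subsequence dynamic time warping: the template must be consumed in full,
but may start and end anywhere in the recording.  Local cost is the
Euclidean distance across channels; the step set is {match, insert,
delete}, every step paying the local cost of the cell it enters.

Candidate strides are local minima of the end-cost profile below a
per-template-sample threshold; overlaps are resolved greedily by ascending
cost, and accepted boundaries are snapped to the nearest minimum of the
windowed gyroscope energy — the midstance — which anchors the downstream
zero-velocity-update integration.

Turning strides are identified after segmentation by integrating the yaw
rate over each segment; strides with more than 45° net heading change are
excluded from parameter analysis, mirroring the walking protocol's 180°
turns.  The first two non-turning strides of every bout are labelled
initiation strides so summaries can be formed with or without them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .io import DEFAULT_FS, GaitTemplate, ImuRecording

try:  # optional JIT; the pure-NumPy/Python fallback is functionally identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "StrideSegment",
    "dtw_distance",
    "build_template",
    "segment_strides",
    "label_turning",
    "net_yaw",
    "default_template",
    "default_threshold",
    "TURNING_YAW_THRESHOLD",
]

#: Default msDTW matching channels: the sagittal gyroscope carries the
#: stride signature; the anterior and superior accelerometers make the
#: match robust for atypical stride shapes (e.g. barely lifted heels).
DEFAULT_CHANNELS = ("gyr_z", "acc_x", "acc_y")

#: Net yaw (°) above which a segment is labelled a turning stride.  The
#: 180° protocol turns put 60–90° on each turn stride; straight strides
#: integrate to essentially zero, so 45° separates the two by a wide margin.
TURNING_YAW_THRESHOLD = 45.0

_CHANNEL_INDEX = {
    "acc_x": ("acc", 0),
    "acc_y": ("acc", 1),
    "acc_z": ("acc", 2),
    "gyr_x": ("gyr", 0),
    "gyr_y": ("gyr", 1),
    "gyr_z": ("gyr", 2),
}


class InputError(ValueError):
    """Segmentation input violates a precondition."""


@dataclass(frozen=True)
class StrideSegment:
    """Half-open sample interval [start, end) of one candidate stride.

    ``dtw_cost`` is the subsequence match cost per template sample
    (dimensionless, on z-scored signals).
    """

    start: int
    end: int
    dtw_cost: float
    label: str = "straight"  # straight | turning | initiation

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise InputError(f"invalid segment [{self.start}, {self.end})")
        if self.dtw_cost < 0:
            raise InputError("dtw_cost must be non-negative")
        if self.label not in ("straight", "turning", "initiation"):
            raise InputError(f"unknown label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# DTW kernels


def _local_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance across channels, shape (len(a), len(b))."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


@_njit(cache=True)
def _full_dp(c):  # pragma: no cover - exercised through dtw_distance
    m, n = c.shape
    D = np.empty((m, n))
    D[0, 0] = c[0, 0]
    for j in range(1, n):
        D[0, j] = c[0, j] + D[0, j - 1]
    for i in range(1, m):
        D[i, 0] = c[i, 0] + D[i - 1, 0]
        for j in range(1, n):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c[i, j] + best
    return D


@_njit(cache=True)
def _subsequence_dp(c):  # pragma: no cover - exercised through segment_strides
    """Subsequence DP: free start/end on the sequence (column) axis.

    Returns the accumulated-cost matrix and a step matrix for backtracking
    (0 diagonal, 1 vertical (template insert), 2 horizontal (sequence
    skip), 3 free start on row 0).
    """
    m, n = c.shape
    D = np.empty((m, n))
    S = np.zeros((m, n), dtype=np.uint8)
    for j in range(n):
        D[0, j] = c[0, j]
        S[0, j] = 3
    for i in range(1, m):
        D[i, 0] = c[i, 0] + D[i - 1, 0]
        S[i, 0] = 1
        for j in range(1, n):
            best = D[i - 1, j - 1]
            step = 0
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                step = 1
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                step = 2
            D[i, j] = c[i, j] + best
            S[i, j] = step
    return D, S


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def dtw_distance(a, b) -> float:
    """Full-boundary multi-channel DTW cost between two sequences.

    Local cost is the Euclidean distance across channels; steps are
    {match, insert, delete}, each adding the local cost of the entered
    cell.  Symmetric in its arguments and zero for identical inputs.
    """
    a, b = _as_2d(a), _as_2d(b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise InputError("sequences must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise InputError(
            f"channel mismatch: {a.shape[1]} vs {b.shape[1]} channels"
        )
    return float(_full_dp(_local_cost(a, b))[-1, -1])


# ---------------------------------------------------------------------------
# template construction


def _zscore(x: np.ndarray, axis=0) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    if np.any(sd < 1e-12):
        raise InputError("cannot z-score a constant (zero-variance) signal")
    return (x - mu) / sd

def _resample(x: np.ndarray, length: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, x.shape[0])
    dst = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(dst, src, x[:, k]) for k in range(x.shape[1])])


def build_template(strides, channels=("gyr_z",)) -> GaitTemplate:
    """Average labelled stride signals into a matching template.

    Each stride (array of shape (n_i, n_channels) or (n_i,)) is resampled
    to the median stride length in samples, z-scored per channel, then
    averaged pointwise.
    """
    if len(strides) == 0:
        raise InputError("need at least one stride")
    arrays = [_as_2d(s) for s in strides]
    k = arrays[0].shape[1]
    if any(a.shape[1] != k for a in arrays) or k != len(channels):
        raise InputError("strides and channels disagree on channel count")
    length = int(np.median([a.shape[0] for a in arrays]))
    stack = np.stack([_zscore(_resample(a, length)) for a in arrays])
    return GaitTemplate(channels=list(channels), data=stack.mean(axis=0))


def extract_channels(rec: ImuRecording, channels) -> np.ndarray:
    """Pull named channels out of a recording as an (n, k) matrix."""
    cols = []
    for name in channels:
        if name not in _CHANNEL_INDEX:
            raise InputError(f"unknown channel {name!r}")
        attr, idx = _CHANNEL_INDEX[name]
        cols.append(getattr(rec, attr)[:, idx])
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# midstance boundary snapping


def gyro_energy(rec: ImuRecording, window_s: float = 0.1) -> np.ndarray:
    """Windowed mean of the squared gyroscope magnitude, per sample."""
    e = np.sum(rec.gyr**2, axis=1)
    w = max(1, int(round(window_s * rec.fs)) | 1)  # odd window
    kernel = np.ones(w) / w
    return np.convolve(e, kernel, mode="same")


def _snap_to_energy_minimum(j: int, energy: np.ndarray, radius: int) -> int:
    lo = max(0, j - radius)
    hi = min(len(energy), j + radius + 1)
    window = energy[lo:hi]
    jmin = int(np.argmin(window))
    emin = window[jmin]
    # flat-foot windows are energy plateaus: take the centre of the
    # contiguous near-minimum run rather than the noise-selected argmin
    tol = emin * 0.5 + 1e-12
    near = window <= emin + tol
    a = jmin
    while a > 0 and near[a - 1]:
        a -= 1
    b = jmin
    while b < len(window) - 1 and near[b + 1]:
        b += 1
    return lo + int(round((a + b) / 2.0))


# ---------------------------------------------------------------------------
# subsequence segmentation


def segment_strides(
    rec: ImuRecording,
    template: GaitTemplate,
    threshold: float | None = None,
    snap_radius_s: float = 0.15,
    min_length_factor: float = 0.5,
    max_length_factor: float = 1.9,
) -> list[StrideSegment]:
    """Find stride-shaped subsequences of ``rec`` matching ``template``.

    The recording channels named by the template are z-scored over the
    whole recording, matched by subsequence DTW, and local end-cost minima
    with per-sample cost ≤ ``threshold`` become candidates; overlapping
    candidates are resolved greedily by ascending cost (ties by earlier
    start) and boundaries snapped to windowed gyro-energy minima.

    An empty result is not an error — a recording without gait simply has
    no strides.
    """
    if rec.n_samples == 0:
        raise InputError("empty recording")
    m = template.length
    if rec.n_samples <= m:
        raise InputError("recording must be longer than the template")
    if threshold is None:
        threshold = default_threshold(tuple(template.channels), rec.fs)

    seq = extract_channels(rec, template.channels)
    sd = seq.std(axis=0)
    if np.any(sd < 1e-12):
        return []  # constant recording: no gait
    seq = (seq - seq.mean(axis=0)) / sd

    c = _local_cost(np.asarray(template.data), seq)
    D, S = _subsequence_dp(c)
    end_cost = D[-1] / m

    # greedy selection of non-overlapping low-cost matches
    order = np.argsort(end_cost, kind="stable")
    accepted: list[tuple[int, int, float]] = []
    min_len = max(2, int(min_length_factor * m))
    max_len = int(max_length_factor * m)
    overlap_tol = max(2, int(0.04 * m))
    suppress = np.zeros(len(end_cost), dtype=bool)
    nms = max(1, m // 2)
    for j in order:
        cost = end_cost[j]
        if cost > threshold:
            break
        if suppress[j]:
            continue
        start = _backtrack_start(S, int(j))
        end = int(j) + 1
        if not (min_len <= end - start <= max_len):
            suppress[max(0, j - 2) : j + 3] = True
            continue
        ok = True
        for s0, e0, _ in accepted:
            overlap = min(end, e0) - max(start, s0)
            if overlap > overlap_tol:
                ok = False
                break
        if ok:
            accepted.append((start, end, float(cost)))
        suppress[max(0, j - nms) : j + nms + 1] = True

    if not accepted:
        return []

    # snap boundaries to midstance-like energy minima and de-conflict
    energy = gyro_energy(rec)
    radius = max(1, int(round(snap_radius_s * rec.fs)))
    snapped = []
    for start, end, cost in accepted:
        s = _snap_to_energy_minimum(start, energy, radius)
        e = _snap_to_energy_minimum(end, energy, radius)
        if e - s >= min_len:
            snapped.append((s, e, cost))
    snapped.sort(key=lambda x: (x[0], x[2]))

    segments: list[StrideSegment] = []
    for s, e, cost in snapped:
        if segments:
            prev = segments[-1]
            if s < prev.end:
                if e <= prev.end:  # duplicate / contained: keep cheaper
                    if cost < prev.dtw_cost and s >= (
                        segments[-2].end if len(segments) > 1 else 0
                    ):
                        segments[-1] = StrideSegment(s, e, cost)
                    continue
                s = prev.end
                if e - s < min_len:
                    continue
        segments.append(StrideSegment(s, e, cost))
    return segments


def _backtrack_start(S: np.ndarray, j_end: int) -> int:
    i = S.shape[0] - 1
    j = j_end
    while True:
        step = S[i, j]
        if step == 3:
            return j
        if step == 0:
            i -= 1
            j -= 1
        elif step == 1:
            i -= 1
        else:
            j -= 1
        if i < 0 or j < 0:  # pragma: no cover - defensive
            return max(j, 0)


# ---------------------------------------------------------------------------
# turning / initiation labelling


def label_turning(
    segments: list[StrideSegment],
    rec: ImuRecording,
    yaw_threshold: float = TURNING_YAW_THRESHOLD,
) -> list[StrideSegment]:
    """Label turning strides by integrated yaw rate, then mark the first
    two non-turning strides of each bout as initiation strides.

    Net yaw is the time integral of the yaw-rate channel (``gyr_y``,
    clockwise-positive) over the segment.  A new bout starts at the
    beginning of the recording, after every run of turning strides, and
    after any gap longer than half a stride — the template matcher
    usually rejects turning strides outright (their accelerometer
    signature does not resemble a straight stride), so the turns of a
    multi-bout walk typically appear as gaps rather than as labelled
    segments.
    """
    ordered = sorted(segments, key=lambda s: s.start)
    if not ordered:
        return []
    median_len = float(np.median([s.length for s in ordered]))
    out = []
    bout_count = 0
    prev_end = None
    for seg in ordered:
        if prev_end is not None and seg.start - prev_end > 0.5 * median_len:
            bout_count = 0  # unmatched stretch (e.g. a turn): new bout
        prev_end = seg.end
        yaw = float(np.trapezoid(rec.gyr[seg.start : seg.end, 1], dx=1.0 / rec.fs))
        if abs(yaw) > yaw_threshold:
            out.append(replace(seg, label="turning"))
            bout_count = 0
        else:
            label = "initiation" if bout_count < 2 else "straight"
            out.append(replace(seg, label=label))
            bout_count += 1
    return out


def net_yaw(rec: ImuRecording, seg: StrideSegment) -> float:
    """Net heading change over a segment, degrees clockwise-positive."""
    return float(np.trapezoid(rec.gyr[seg.start : seg.end, 1], dx=1.0 / rec.fs))


# ---------------------------------------------------------------------------
# deterministic defaults


@lru_cache(maxsize=8)
def default_template(channels: tuple[str, ...] = DEFAULT_CHANNELS, fs: float = DEFAULT_FS) -> GaitTemplate:
    """Average template from simulated healthy strides (deterministic).

    Ten noisy strides are synthesized from the default stride
    distribution with a fixed internal seed and averaged with
    :func:`build_template`; the result depends only on ``channels``/``fs``.
    """
    from .synth import default_stride_distribution, synthesize_recording

    rng = np.random.default_rng(123456)
    dist = default_stride_distribution()
    specs = dist.sample(rng, 10)
    rec, truth = synthesize_recording(specs, fs=fs, seed=rng)
    bounds = truth.boundaries
    data = extract_channels(rec, channels)
    strides = [data[bounds[k] : bounds[k + 1]] for k in range(truth.n_strides)]
    return build_template(strides, channels=channels)


@lru_cache(maxsize=8)
def default_threshold(channels: tuple[str, ...] = DEFAULT_CHANNELS, fs: float = DEFAULT_FS) -> float:
    """Data-driven matching threshold, cost per template sample.

    Calibrated on held-out simulated walks under deployment conditions
    (whole-recording normalization): subjects are drawn from both the PD
    and the control reference distributions so the threshold covers the
    stride-shape diversity of a patient cohort; the per-stride minimum end
    cost near each true stride boundary is collected and the threshold set
    at mean + 3·SD.
    """
    from .synth import (
        StrideDistribution,
        control_reference_distribution,
        pd_reference_distribution,
        synthesize_walk,
    )

    template = default_template(channels, fs)
    rng = np.random.default_rng(654321)
    costs = []
    for group_dist in (pd_reference_distribution(), control_reference_distribution()):
        for _ in range(3):
            subject_mean = group_dist.sample(rng, 1)[0]
            per_stride = StrideDistribution(mean=subject_mean)
            walks = synthesize_walk(
                per_stride,
                n_strides_per_bout=6,
                n_bouts=1,
                seed=rng,
                sides=("left",),
            )
            rec, truth = walks["left"]
            seq = extract_channels(rec, template.channels)
            seq = (seq - seq.mean(axis=0)) / seq.std(axis=0)
            D, _ = _subsequence_dp(_local_cost(np.asarray(template.data), seq))
            end_cost = D[-1] / template.length
            bounds = truth.boundaries
            for k in range(truth.n_strides):
                if truth.specs[k].is_turning:
                    continue
                j = bounds[k + 1]
                lo, hi = max(0, j - 5), min(len(end_cost), j + 6)
                costs.append(end_cost[lo:hi].min())
    costs = np.asarray(costs)
    return float(costs.mean() + 3.0 * costs.std(ddof=1))
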