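"""msDTW segmentation: kernel correctness against a brute-force oracle,
template construction, subsequence matching, turning/initiation labels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stridekit.io import G, ImuRecording
from stridekit.segmentation import (
    InputError,
    build_template,
    default_template,
    dtw_distance,
    extract_channels,
    label_turning,
    net_yaw,
    segment_strides,
)
from stridekit.synth import StrideSpec, synthesize_recording, synthesize_walk
from tests.conftest import CONTROL_SPEC


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate every monotone warping path


def dtw_brute_force(a, b):
    a = np.atleast_2d(np.asarray(a, float).T).T if np.ndim(a) == 1 else np.asarray(a, float)
    if a.ndim == 1:
        a = a[:, None]
    b = np.asarray(b, float)
    if b.ndim == 1:
        b = b[:, None]
    m, n = len(a), len(b)
    cost = {(0, 0): float(np.linalg.norm(a[0] - b[0]))}
    best = {}

    def rec(i, j):
        if (i, j) in best:
            return best[(i, j)]
        c = float(np.linalg.norm(a[i] - b[j]))
        if i == 0 and j == 0:
            value = c
        else:
            prev = []
            if i > 0 and j > 0:
                prev.append(rec(i - 1, j - 1))
            if i > 0:
                prev.append(rec(i - 1, j))
            if j > 0:
                prev.append(rec(i, j - 1))
            value = c + min(prev)
        best[(i, j)] = value
        return value

    return rec(m - 1, n - 1)


class TestDtwDistance:
    def test_identity_alignment(self):
        assert dtw_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_single_cell(self):
        assert dtw_distance([1.0], [3.0]) == 2.0

    def test_repeat_absorption(self):
        assert dtw_distance([0, 1, 2], [0, 1, 1, 2]) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            m, n = rng.integers(1, 7, size=2)
            k = int(rng.integers(1, 3))
            a = rng.integers(-3, 4, size=(m, k)).astype(float)
            b = rng.integers(-3, 4, size=(n, k)).astype(float)
            assert dtw_distance(a, b) == pytest.approx(dtw_brute_force(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=6),
        b=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=6),
    )
    def test_symmetry_and_nonnegativity(self, a, b):
        d = dtw_distance(a, b)
        assert d >= 0.0
        assert d == pytest.approx(dtw_distance(b, a), rel=1e-12, abs=1e-12)

    def test_channel_mismatch(self):
        with pytest.raises(InputError):
            dtw_distance(np.zeros((3, 1)), np.zeros((3, 2)))

    def test_empty_sequence(self):
        with pytest.raises(InputError):
            dtw_distance([], [1.0])


class TestBuildTemplate:
    def test_single_stride_is_zscored_identity(self):
        stride = np.sin(np.linspace(0, 2 * np.pi, 40))
        tpl = build_template([stride])
        expected = (stride - stride.mean()) / stride.std()
        np.testing.assert_allclose(tpl.data[:, 0], expected, rtol=1e-12)

    def test_two_identical_strides_idempotent(self):
        stride = np.sin(np.linspace(0, 2 * np.pi, 40))
        one = build_template([stride])
        two = build_template([stride, stride])
        np.testing.assert_allclose(one.data, two.data, rtol=1e-12)

    def test_constant_stride_rejected(self):
        with pytest.raises(InputError):
            build_template([np.zeros(40)])

    def test_template_closer_to_stride_than_flat(self):
        # average template from noisy strides matches a clean stride better
        # than a flat signal of equal length
        rng = np.random.default_rng(3)
        specs = [CONTROL_SPEC] * 10
        rec, truth = synthesize_recording(specs, seed=rng)
        b = truth.boundaries
        gz = rec.gyr[:, 2]
        tpl = build_template([gz[b[k] : b[k + 1]] for k in range(10)])
        clean, truth_c = synthesize_recording([CONTROL_SPEC] * 3, noise_sd=(0, 0), seed=0)
        bc = truth_c.boundaries
        stride = clean.gyr[bc[1] : bc[2], 2]
        stride_z = (stride - stride.mean()) / stride.std()
        d_stride = dtw_distance(tpl.data[:, 0], stride_z)
        d_flat = dtw_distance(tpl.data[:, 0], np.zeros(len(stride_z)))
        assert d_stride < d_flat


def _segments_match(segments, boundaries, turning, tol=3):
    """Greedy match of segments to true strides within ±tol samples."""
    hits = []
    for k in range(len(boundaries) - 1):
        found = [
            s
            for s in segments
            if abs(s.start - boundaries[k]) <= tol and abs(s.end - boundaries[k + 1]) <= tol
        ]
        hits.append(found[0] if found else None)
    return hits


class TestSegmentStrides:
    def test_self_match(self, template):
        # the subsequence DP matches the template against itself with zero
        # end cost and a backtracked start at sample zero
        from stridekit.segmentation import _backtrack_start, _local_cost, _subsequence_dp

        c = _local_cost(np.asarray(template.data), np.asarray(template.data))
        D, S = _subsequence_dp(c)
        m = template.length
        assert D[-1, -1] == pytest.approx(0.0, abs=1e-12)
        assert _backtrack_start(S, m - 1) == 0

    def test_single_stride_recording_matches_once(self, template, threshold):
        rec, truth = synthesize_recording([CONTROL_SPEC], noise_sd=(0, 0), seed=0)
        segs = segment_strides(rec, template, threshold)
        assert len(segs) == 1
        b = truth.boundaries
        assert abs(segs[0].start - b[0]) <= 3 and abs(segs[0].end - b[1]) <= 3

    def test_constant_recording_has_no_strides(self, template):
        n = 500
        rec = ImuRecording(
            "left", 51.2, np.arange(n) / 51.2,
            np.tile([0.0, G, 0.0], (n, 1)), np.zeros((n, 3)),
        )
        assert segment_strides(rec, template, threshold=1.0) == []

    @pytest.mark.parametrize("fixture", ["clean_walk", "noisy_walk"])
    def test_full_recall_and_precision(self, fixture, request, template, threshold):
        # every straight stride found within ±3 samples, nothing spurious;
        # turning strides are rejected by the matcher itself (their
        # accelerometer signature does not resemble a straight stride)
        rec, truth = request.getfixturevalue(fixture)
        segs = segment_strides(rec, template, threshold)
        hits = _segments_match(segs, truth.boundaries, truth.is_turning)
        straight = ~truth.is_turning
        assert all(h is not None for k, h in enumerate(hits) if straight[k])  # recall
        assert len(segs) == int(straight.sum())                              # precision

    def test_threshold_monotonicity(self, noisy_walk, template, threshold):
        rec, _ = noisy_walk
        counts = [
            len(segment_strides(rec, template, thr))
            for thr in (0.3 * threshold, 0.7 * threshold, threshold, 1.5 * threshold)
        ]
        assert counts == sorted(counts)

    def test_segments_sorted_and_disjoint(self, noisy_walk, template, threshold):
        rec, _ = noisy_walk
        segs = segment_strides(rec, template, threshold)
        for a, b in itertools.pairwise(segs):
            assert a.start < a.end <= b.start < b.end

    def test_empty_recording_rejected(self, template):
        rec = ImuRecording(
            "left", 51.2, np.arange(10) / 51.2,
            np.tile([0.0, G, 0.0], (10, 1)), np.zeros((10, 3)),
        )
        with pytest.raises(InputError):
            segment_strides(rec, template)  # shorter than the template


class TestLabelTurning:
    def test_zero_yaw_means_no_turning(self, template, threshold):
        rec, _ = synthesize_recording([CONTROL_SPEC] * 4, seed=2)
        segs = label_turning(segment_strides(rec, template, threshold), rec)
        assert all(s.label != "turning" for s in segs)

    def test_true_segments_turning_labels(self, noisy_walk):
        # operating on the exact stride intervals, the yaw integral labels
        # precisely the six pivot strides as turning
        rec, truth = noisy_walk
        b = truth.boundaries
        from stridekit.segmentation import StrideSegment

        segs = [StrideSegment(b[k], b[k + 1], 0.0) for k in range(truth.n_strides)]
        labelled = label_turning(segs, rec)
        got = np.array([s.label == "turning" for s in labelled])
        np.testing.assert_array_equal(got, truth.is_turning)
        assert sum(s.label == "initiation" for s in labelled) == 8  # 2 × 4 bouts

    def test_estimated_yaw_signs_and_magnitude(self, noisy_walk):
        rec, truth = noisy_walk
        b = truth.boundaries
        from stridekit.segmentation import StrideSegment

        yaws = [
            net_yaw(rec, StrideSegment(b[k], b[k + 1], 0.0))
            for k in range(truth.n_strides)
            if truth.is_turning[k]
        ]
        # each pivot stride carries ±90° of heading change; the sagittal
        # tilt of the yaw axis shrinks the integral a little
        assert all(55 < abs(y) < 100 for y in yaws)
        assert list(np.sign(yaws)) == [1, 1, -1, -1, 1, 1]

    def test_initiation_resets_at_bout_gaps(self, clean_walk, template, threshold):
        # turns appear as gaps between matched segments; after every gap
        # exactly the next two strides are labelled initiation
        rec, _ = clean_walk
        segs = label_turning(segment_strides(rec, template, threshold), rec)
        assert sum(s.label == "initiation" for s in segs) == 8
        state = 0
        prev_end = None
        for s in segs:
            if prev_end is not None and s.start - prev_end > s.length // 2:
                state = 0
            prev_end = s.end
            if s.label == "turning":
                state = 0
            elif state < 2:
                assert s.label == "initiation"
                state += 1
            else:
                assert s.label == "straight"


class TestDefaults:
    def test_default_template_deterministic(self):
        a = default_template()
        b = default_template()
        assert a is b  # cached
        assert a.length >= 8 and len(a.channels) == a.data.shape[1]

    def test_extract_channels_unknown(self, noisy_walk):
        rec, _ = noisy_walk
        with pytest.raises(InputError):
            extract_channels(rec, ["magnetometer_x"])
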