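"""Simulator: constructive exactness, world-frame consistency, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from stridekit.io import G, GYR_RANGE
from stridekit.synth import (
    CohortSpec,
    SamplingError,
    SpecError,
    StrideDistribution,
    StrideSpec,
    control_reference_distribution,
    default_stride_distribution,
    pd_reference_distribution,
    plan_stride_trajectory,
    stride_is_feasible,
    synthesize_cohort,
    synthesize_recording,
    synthesize_walk,
)
from tests.conftest import CONTROL_SPEC, PD_SPEC


class TestStridePlan:
    @pytest.mark.parametrize("spec", [CONTROL_SPEC, PD_SPEC], ids=["control", "pd"])
    def test_constructive_exactness(self, spec):
        plan = plan_stride_trajectory(spec)
        T = plan.T
        # pitch hits the requested angles exactly at the events
        assert plan.pitch_deg([plan.t_to])[0] == pytest.approx(spec.to_angle, abs=1e-9)
        assert plan.pitch_deg([plan.t_hs])[0] == pytest.approx(spec.hs_angle, abs=1e-9)
        # flat and stationary at both bounding midstances
        for t in (0.0, T):
            assert plan.pitch_deg([t])[0] == pytest.approx(0.0, abs=1e-9)
            assert plan.pitch_rate_deg([t])[0] == 0.0
        # displacement and clearance by construction
        toe = plan.toe_pos(np.array([0.0, T]))
        assert toe[1, 0] - toe[0, 0] == pytest.approx(spec.stride_length, abs=1e-12)
        tq = np.append(np.linspace(0, T, 20001), plan.t_clearance_peak)
        assert plan.toe_pos(tq)[:, 1].max() == pytest.approx(spec.max_clearance, abs=1e-12)

    def test_null_stride_constant_pose(self):
        spec = StrideSpec(stride_length=0, stride_time=1.0, stance_fraction=0.6,
                          max_clearance=0, hs_angle=0, to_angle=0)
        plan = plan_stride_trajectory(spec)
        tq = np.linspace(0, 1.0, 501)
        assert np.all(plan.pitch_rate_deg(tq) == 0)
        assert np.all(plan.toe_pos(tq) == 0)

    def test_differentiation_integration_round_trip(self):
        # differentiate the planned pose twice on a fine grid, integrate back
        plan = plan_stride_trajectory(CONTROL_SPEC)
        t = np.linspace(0, plan.T, 200001)
        x = plan.toe_pos(t)[:, 0]
        a = np.gradient(np.gradient(x, t), t)
        dt = t[1] - t[0]
        v = np.concatenate([[0], np.cumsum((a[1:] + a[:-1]) / 2) * dt])
        xr = np.concatenate([[0], np.cumsum((v[1:] + v[:-1]) / 2) * dt])
        assert abs(xr[-1] - CONTROL_SPEC.stride_length) < 1e-6

    @pytest.mark.parametrize(
        "bad",
        [
            dict(stance_fraction=0.0),
            dict(stance_fraction=1.0),
            dict(stride_length=-0.1),
            dict(stride_time=0.0),
            dict(hs_angle=-5.0),
            dict(to_angle=5.0),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(SpecError):
            plan_stride_trajectory(replace(CONTROL_SPEC, **bad))

    def test_rates_inside_sensor_range_for_reference_strides(self):
        for spec in (CONTROL_SPEC, PD_SPEC):
            plan = plan_stride_trajectory(spec)
            tq = np.linspace(0, plan.T, 50001)
            assert np.abs(plan.pitch_rate_deg(tq)).max() <= GYR_RANGE
            assert stride_is_feasible(spec)

    def test_infeasible_when_too_fast(self):
        assert not stride_is_feasible(replace(CONTROL_SPEC, stride_time=0.62))


class TestSynthesizeRecording:
    def test_null_stride_statics(self):
        spec = StrideSpec(stride_length=0, stride_time=1.0, stance_fraction=0.6,
                          max_clearance=0, hs_angle=0, to_angle=0)
        rec, _ = synthesize_recording([spec], noise_sd=(0, 0), seed=0, sway=False)
        assert np.abs(rec.gyr).max() == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rec.acc[:, 1], G, atol=1e-6)
        np.testing.assert_allclose(rec.acc[:, [0, 2]], 0.0, atol=1e-6)

    def test_world_frame_double_integration(self):
        # trapezoid double integration of the emitted (anti-aliased,
        # 51.2 Hz-sampled) world acceleration recovers the stride length
        from scipy.signal import firwin
        from stridekit.synth import (
            _AA_CUTOFF_HZ,
            _AA_NUMTAPS,
            _AA_OVERSAMPLE,
            _sensor_world_kinematics,
        )

        plan = plan_stride_trajectory(CONTROL_SPEC)
        fs, over = 51.2, _AA_OVERSAMPLE
        fso = fs * over
        pad = 0.4
        n_o = int(round((plan.T + 2 * pad) * fso))
        t_o = np.arange(n_o) / fso
        tau = np.clip(t_o - pad, 0.0, plan.T)
        pos, acc_w, _, _ = _sensor_world_kinematics(plan, tau, 0.0)
        kernel = firwin(_AA_NUMTAPS, _AA_CUTOFF_HZ, fs=fso)
        half = _AA_NUMTAPS // 2
        for axis, expected in ((0, CONTROL_SPEC.stride_length), (1, 0.0)):
            a = np.convolve(np.pad(acc_w[:, axis], half, mode="edge"), kernel, "valid")
            a = a[::over]
            t = t_o[::over]
            dt = t[1] - t[0]
            v = np.concatenate([[0], np.cumsum((a[1:] + a[:-1]) / 2) * dt])
            p = np.concatenate([[0], np.cumsum((v[1:] + v[:-1]) / 2) * dt])
            assert abs(p[-1] - expected) < 1e-3

    def test_seed_determinism(self):
        specs = [CONTROL_SPEC] * 3
        r1, _ = synthesize_recording(specs, seed=5)
        r2, _ = synthesize_recording(specs, seed=5)
        r3, _ = synthesize_recording(specs, seed=6)
        np.testing.assert_array_equal(r1.acc, r2.acc)
        np.testing.assert_array_equal(r1.gyr, r2.gyr)
        assert not np.array_equal(r1.gyr, r3.gyr)

    def test_ground_truth_indexing(self):
        specs = [CONTROL_SPEC] * 4
        rec, truth = synthesize_recording(specs, seed=0, pad_s=0.5)
        assert truth.n_strides == 4
        b = truth.boundaries
        assert np.all(np.diff(b) > 0) and b[-1] < rec.n_samples
        # event ordering per stride: ms < to < hs, all inside the stride
        for k in range(4):
            assert truth.ms_times[k] < truth.to_times[k] < truth.hs_times[k]
            assert truth.hs_times[k] < truth.boundary_times[k + 1]

    def test_sampling_error_for_low_fs(self):
        with pytest.raises(SamplingError):
            synthesize_recording([CONTROL_SPEC], fs=5.0, seed=0)

    def test_empty_stride_list(self):
        with pytest.raises(SpecError):
            synthesize_recording([], seed=0)


class TestSynthesizeWalk:
    def test_stride_counts(self, clean_walk):
        _, truth = clean_walk
        turning = truth.is_turning
        assert truth.n_strides == 38
        assert int(turning.sum()) == 6        # 3 turns × 2 pivot strides
        assert int((~turning).sum()) == 32    # 4 bouts × 8 strides

    def test_turn_yaw_signs_alternate(self, clean_walk):
        _, truth = clean_walk
        yaws = truth.turn_yaws[truth.is_turning]
        # CW (+), CCW (−), CW (+): each 180° split over 2 pivot strides
        assert list(np.sign(yaws)) == [1, 1, -1, -1, 1, 1]
        per_turn = yaws.reshape(3, 2).sum(axis=1)
        np.testing.assert_allclose(per_turn, [180.0, -180.0, 180.0])

    def test_bout_displacements_sum(self, clean_walk):
        _, truth = clean_walk
        straight = ~truth.is_turning
        total = np.linalg.norm(truth.displacements[straight], axis=1).sum()
        assert total == pytest.approx(4 * 8 * CONTROL_SPEC.stride_length, abs=1e-6)
        # pivot strides do not translate
        assert np.abs(truth.displacements[truth.is_turning]).max() < 1e-12

    def test_minimum_bout_length(self):
        with pytest.raises(SpecError):
            synthesize_walk(CONTROL_SPEC, n_strides_per_bout=2, seed=0)

    def test_initiation_scaling(self):
        walks = synthesize_walk(
            CONTROL_SPEC, n_strides_per_bout=4, n_bouts=1, seed=0,
            sides=("left",), initiation_scale=(0.75, 1.1),
        )
        _, truth = walks["left"]
        lengths = truth.stride_lengths
        assert lengths[0] == pytest.approx(0.75 * CONTROL_SPEC.stride_length)
        assert lengths[1] == pytest.approx(0.875 * CONTROL_SPEC.stride_length)
        assert lengths[2] == pytest.approx(CONTROL_SPEC.stride_length)


class TestDistributionsAndCohort:
    def test_degenerate_distribution(self, rng):
        dist = StrideDistribution(mean=CONTROL_SPEC, sd={})
        specs = dist.sample(rng, 5)
        assert all(s == CONTROL_SPEC for s in specs)

    def test_reference_means_recovered(self, rng):
        # law of large numbers on the truncated sampler: empirical means of
        # the target parameters stay within 3 SEM of the configured means
        for dist, mean in [
            (pd_reference_distribution(), PD_SPEC),
            (control_reference_distribution(), CONTROL_SPEC),
        ]:
            specs = dist.sample(rng, 400)
            for name in ("stride_length", "max_clearance", "stance_fraction"):
                draws = np.array([getattr(s, name) for s in specs])
                sem = draws.std(ddof=1) / np.sqrt(len(draws))
                assert abs(draws.mean() - getattr(mean, name)) < 3 * sem

    def test_group_clearance_difference_positive(self, rng):
        pd = pd_reference_distribution().sample(rng, 50)
        ctrl = control_reference_distribution().sample(rng, 50)
        diff = np.mean([s.max_clearance for s in ctrl]) - np.mean(
            [s.max_clearance for s in pd]
        )
        assert diff > 0

    def test_all_samples_feasible(self, rng):
        for dist in (pd_reference_distribution(), control_reference_distribution()):
            assert all(stride_is_feasible(s) for s in dist.sample(rng, 50))

    def test_cohort_dataset_structure(self):
        spec = CohortSpec(group="PD", n_subjects=2, n_strides_per_bout=4,
                          n_bouts=2, seed=3)
        data = synthesize_cohort(spec)
        assert len(data.subjects) == 2 and len(data.walks) == 2
        for rec_subject in data.subjects:
            assert rec_subject.group == "PD"
            assert 1 <= rec_subject.hoehn_yahr <= 3
            assert 0 <= rec_subject.gait_item <= 2
        sides = next(iter(data.walks.values()))
        assert set(sides) == {"left", "right"}

    def test_cohort_seed_determinism(self):
        spec = CohortSpec(group="PD", n_subjects=2, n_strides_per_bout=4,
                          n_bouts=2, seed=3)
        a = synthesize_cohort(spec)
        b = synthesize_cohort(spec)
        ra = next(iter(a.walks.values()))["left"][0]
        rb = next(iter(b.walks.values()))["left"][0]
        np.testing.assert_array_equal(ra.acc, rb.acc)

    def test_invalid_cohort(self):
        with pytest.raises(SpecError):
            synthesize_cohort(CohortSpec(n_subjects=1))
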