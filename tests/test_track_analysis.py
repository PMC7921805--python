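"""Run/pause segmentation and displacement-weighted velocity statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from kchtow.track_analysis import (
    TrackStats,
    cohort_compare,
    point_displacements,
    per_track_stats,
    segment_runs,
    weighted_velocity_distribution,
)

from conftest import track_from_positions, track_from_velocities


class TestPointDisplacements:
    def test_arithmetic(self):
        iv = point_displacements(track_from_positions([0.0, 0.05, 0.05]))
        np.testing.assert_allclose(iv.dx_um, [0.05, 0.0])
        np.testing.assert_allclose(iv.v_nm_s, [10.0, 0.0])
        assert list(iv.cls) == ["forward", "pause"]

    def test_telescoping_sum(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0, 0.02, 50))
        iv = point_displacements(track_from_positions(x))
        assert iv.dx_um.sum() == pytest.approx(x[-1] - x[0], abs=1e-12)

    def test_reversal_negates_velocities(self):
        x = np.array([0.0, 0.01, 0.05, 0.02])
        fwd = point_displacements(track_from_positions(x))
        rev = point_displacements(track_from_positions(x[::-1]))
        np.testing.assert_allclose(rev.v_nm_s.to_numpy(), -fwd.v_nm_s.to_numpy()[::-1])

    def test_errors(self):
        with pytest.raises(ValueError):
            point_displacements(track_from_positions([0.0]))


class TestSegmentation:
    def test_hand_enumerated_blocks(self):
        track = track_from_velocities([2, 3, -0.5, -2, -2], dt=5.0)
        runs = segment_runs(point_displacements(track))
        assert list(runs.cls) == ["forward", "pause", "backward"]
        np.testing.assert_allclose(runs.duration_s, [10.0, 5.0, 10.0])

    def test_all_subthreshold_is_one_pause(self):
        track = track_from_velocities([0.5, -0.9, 0.0, 0.2])
        runs = segment_runs(point_displacements(track))
        assert len(runs) == 1
        assert runs.cls[0] == "pause"
        assert runs.duration_s[0] == pytest.approx(20.0)

    def test_threshold_boundary_is_pause(self):
        track = track_from_velocities([1.0, -1.0, 1.0000001])
        runs = segment_runs(point_displacements(track), threshold=1.0)
        assert list(runs.cls) == ["pause", "forward"]

    def test_strict_merging_reclassifies_singletons(self):
        track = track_from_velocities([5, 0, 5, 5, 0, -5, -5])
        runs = segment_runs(point_displacements(track), min_intervals_per_run=2)
        # lone forward interval becomes pause and merges with its neighbours
        assert list(runs.cls) == ["pause", "forward", "pause", "backward"]
        np.testing.assert_allclose(runs.duration_s, [10.0, 10.0, 5.0, 10.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        v=st.lists(st.floats(-30, 30), min_size=1, max_size=60),
        threshold=st.floats(0.1, 5.0),
    )
    def test_conservation_laws(self, v, threshold):
        """Run durations and displacements tile the track exactly."""
        track = track_from_velocities(v, dt=2.0)
        iv = point_displacements(track, threshold)
        runs = segment_runs(iv, threshold)
        assert runs.duration_s.sum() == pytest.approx(track.duration_s)
        assert runs.displacement_um.sum() == pytest.approx(
            track.positions_um[-1] - track.positions_um[0], abs=1e-9
        )
        # adjacent runs always differ in class
        assert all(a != b for a, b in zip(runs.cls, runs.cls[1:]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(v=st.lists(st.floats(-30, 30), min_size=3, max_size=60))
    def test_pause_time_monotone_in_threshold(self, v):
        track = track_from_velocities(v, dt=2.0)
        iv = point_displacements(track)

        def pause_time(thr):
            runs = segment_runs(iv, thr)
            return runs[runs.cls == "pause"].duration_s.sum()

        times = [pause_time(t) for t in (0.5, 1.0, 2.0, 5.0, 10.0)]
        assert all(b >= a for a, b in zip(times, times[1:]))


class TestVelocityDistribution:
    def test_degenerate_single_bin(self):
        iv = point_displacements(track_from_velocities([10.0] * 5))
        dist = weighted_velocity_distribution(iv, "forward")
        assert not dist.fit_ok
        assert dist.weighted_mean == pytest.approx(10.0)

    def test_weighted_mean_arithmetic(self):
        iv = pd.DataFrame(
            {"v_nm_s": [10.0, 20.0], "dx_um": [0.001, 0.003], "dt_s": [1, 1]}
        )
        dist = weighted_velocity_distribution(iv, "forward")
        assert dist.weighted_mean == pytest.approx(17.5)

    def test_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(1)
        v = rng.normal(11.55, 6.85, 10_000)
        v = v[v > 1.0]
        iv = pd.DataFrame({"v_nm_s": v, "dx_um": np.full(len(v), 1e-3), "dt_s": 1.0})
        dist = weighted_velocity_distribution(iv, "forward")
        assert dist.fit_ok
        assert abs(dist.fit_mean - 11.55) < 0.5
        assert abs(dist.fit_sd - 6.85) < 0.5

    def test_no_intervals_raises(self):
        iv = point_displacements(track_from_velocities([10.0, 10.0]))
        with pytest.raises(ValueError):
            weighted_velocity_distribution(iv, "backward")


class TestPerTrackStats:
    def test_pure_forward_track(self):
        s = per_track_stats(track_from_velocities([10, 12, 11, 10]))
        assert s.backward_velocity_nm_s is None
        assert s.backward_run_duration_s is None
        assert s.n_backward_runs == 0
        assert s.net_velocity_nm_s == pytest.approx(np.mean([10, 12, 11, 10]))

    def test_time_reversal_swaps_directions(self):
        v = [10, 12, 0, -6, -5, 0, 8, 9]
        fwd = per_track_stats(track_from_velocities(v))
        rev = per_track_stats(track_from_velocities([-x for x in v[::-1]]))
        assert rev.n_forward_runs == fwd.n_backward_runs
        assert rev.n_backward_runs == fwd.n_forward_runs
        assert rev.forward_run_duration_s == pytest.approx(fwd.backward_run_duration_s)
        assert rev.backward_run_duration_s == pytest.approx(fwd.forward_run_duration_s)

    def test_ground_truth_segment_recovery(self):
        from kchtow.synthetic_tracks import SegmentSpec, make_track

        segs = [
            SegmentSpec("forward", 100.0, 12.0),
            SegmentSpec("pause", 50.0, 0.0),
            SegmentSpec("backward", 75.0, -8.0),
        ]
        track, truth = make_track(segs, frame_interval_s=5.0, noise_sd_nm=0.0, seed=0)
        s = per_track_stats(track)
        assert s.forward_run_duration_s == pytest.approx(100.0)
        assert s.backward_run_duration_s == pytest.approx(75.0)
        assert s.n_forward_runs == s.n_backward_runs == 1


def make_stats(track_id, fv, bv, fd, bd):
    return TrackStats(
        track_id=track_id,
        duration_s=3600.0,
        net_velocity_nm_s=1.0,
        forward_velocity_nm_s=fv,
        backward_velocity_nm_s=bv,
        forward_run_duration_s=fd,
        backward_run_duration_s=bd,
        n_forward_runs=10,
        n_backward_runs=10,
    )


class TestCohortCompare:
    def test_constructed_asymmetric_cohort_highly_significant(self):
        rng = np.random.default_rng(42)
        stats = [
            make_stats(str(i), fv=10 + i * 0.1, bv=-(10 + i * 0.1 - rng.normal(3, 1)),
                       fd=40.0 + i + rng.normal(0, 0.5), bd=30.0 + i)
            for i in range(21)
        ]
        cs = cohort_compare(stats)
        assert cs.p_velocity < 1e-3
        assert cs.p_run_duration < 1e-3
        assert cs.n_paired == 21

    def test_mirrored_null_cohort_rarely_significant(self):
        rng = np.random.default_rng(0)
        n_sig = 0
        reps = 40
        for _ in range(reps):
            stats = [
                make_stats(str(i), fv=rng.normal(10, 2), bv=-rng.normal(10, 2),
                           fd=rng.normal(40, 5), bd=rng.normal(40, 5))
                for i in range(21)
            ]
            n_sig += cohort_compare(stats).p_velocity < 0.05
        assert n_sig <= 0.15 * reps

    def test_paired_t_matches_sign_permutation_oracle(self):
        rng = np.random.default_rng(42)
        diffs = rng.normal(1.0, 1.0, 10)
        stats = [
            make_stats(str(i), fv=10.0 + d, bv=-10.0, fd=40.0 + 0.3 * i, bd=30.0)
            for i, d in enumerate(diffs)
        ]
        p_t = cohort_compare(stats).p_velocity
        obs = diffs.mean()
        signs = np.array(list(itertools.product([1, -1], repeat=10)))
        perm = (signs * diffs).mean(axis=1)
        p_perm = np.mean(np.abs(perm) >= abs(obs) - 1e-12)
        assert abs(p_t - p_perm) < 0.05

    def test_wilcoxon_alternative(self):
        stats = [
            make_stats(str(i), fv=12.0 + i * 0.1, bv=-6.0 - i * 0.05,
                       fd=40.0 + i, bd=30.0)
            for i in range(12)
        ]
        cs = cohort_compare(stats, test="wilcoxon")
        assert cs.test == "wilcoxon"
        assert cs.p_velocity < 0.01

    def test_too_few_paired_tracks(self):
        stats = [make_stats("a", 10, -5, 40, 30), make_stats("b", 10, None, 40, None)]
        with pytest.raises(ValueError):
            cohort_compare(stats)
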