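"""Tests of kinematics, filtering, orientational ACF and the exponential fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from shoalkit.trajectories import (
    ACFResult,
    FlatACFError,
    InsufficientDataError,
    OrientationSeries,
    Trajectory,
    count_histogram_modes,
    distributions,
    filter_kinematics,
    fit_exponential_acf,
    kinematics,
    orientation_acf,
)


def _traj(positions, frames=None, fps=15.0, ind="f0"):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Trajectory(individual_id=ind, frame_rate=fps, frames=frames, positions=positions)


class TestKinematics:
    def test_single_step_difference(self):
        kin = kinematics(_traj([[0, 0, 0], [1, 0, 0]]))
        assert kin.speeds[0] == pytest.approx(15.0)
        assert np.allclose(kin.orientations.headings[0], [1, 0, 0])
        assert kin.orientations.valid[0]

    def test_stationary_trajectory_masks_all_headings(self):
        kin = kinematics(_traj([[1, 1, 1]] * 5))
        assert not kin.orientations.valid.any()
        assert np.allclose(kin.speeds, 0.0)

    def test_straight_line_constant_heading(self):
        pos = np.outer(np.arange(10), [1.0, 2.0, 2.0])
        kin = kinematics(_traj(pos))
        assert kin.orientations.valid.all()
        assert np.allclose(kin.orientations.headings, kin.orientations.headings[0])

    def test_gap_masks_bridging_pair(self):
        kin = kinematics(_traj([[0, 0, 0], [1, 0, 0], [5, 0, 0], [6, 0, 0]],
                               frames=[0, 1, 3, 4]))
        # pair (1 -> 3) spans a missing frame
        assert list(kin.valid) == [True, False, True]

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            kinematics(_traj([[0, 0, 0]]))

    def test_strictly_increasing_frames_enforced(self):
        with pytest.raises(ValueError):
            _traj([[0, 0, 0], [1, 0, 0]], frames=[3, 3])


class TestFilterKinematics:
    def test_speed_threshold_keeps_boundary_value(self):
        speeds = np.array([10.0, 60.0, 49.9, 50.0, 200.0])
        pos = np.tile([0.0, 0.0, 100.0], (5, 1))
        mask = filter_kinematics(speeds, pos)
        assert mask.sum() == 3  # 60, 50 and 200 survive; "speed < 50" excluded
        assert list(mask) == [False, True, False, True, True]

    def test_height_band_is_strictly_open(self):
        speeds = np.full(4, 100.0)
        pos = np.array([[0, 0, 50.0], [0, 0, 100.0], [0, 0, 150.0], [0, 0, 149.9]])
        mask = filter_kinematics(speeds, pos)
        assert list(mask) == [False, True, False, True]

    def test_all_below_threshold_empty(self):
        mask = filter_kinematics(np.array([1.0, 2.0]), min_speed=50.0, z_range=None)
        assert not mask.any()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            filter_kinematics(np.array([100.0]), np.array([[0, 0, 0.0]]),
                              z_range=(150.0, 50.0))


def _series(headings, valid=None, fps=15.0, frames=None):
    headings = np.asarray(headings, dtype=float)
    if valid is None:
        valid = np.ones(len(headings), bool)
    if frames is None:
        frames = np.arange(len(headings))
    return OrientationSeries("s", fps, np.asarray(frames), headings, np.asarray(valid))


class TestOrientationACF:
    def test_constant_heading_gives_unit_acf(self):
        acf = orientation_acf(_series([[0, 0, 1]] * 40), max_lag=1.0)
        assert np.allclose(acf.values, 1.0)
        assert acf.counts[0] == 40

    def test_lag_zero_is_one_and_counts_decrease(self, rng):
        h = rng.normal(size=(100, 3))
        h /= np.linalg.norm(h, axis=1, keepdims=True)
        acf = orientation_acf(_series(h), max_lag=2.0)
        assert acf.values[0] == pytest.approx(1.0)
        assert np.all(np.diff(acf.counts) <= 0)

    def test_iid_random_headings_decorrelate(self, rng):
        h = rng.normal(size=(6000, 3))
        h /= np.linalg.norm(h, axis=1, keepdims=True)
        acf = orientation_acf(_series(h), max_lag=0.5)
        # dot of two independent uniform unit vectors has variance 1/3
        se = np.sqrt(1.0 / 3.0 / acf.counts[1:])
        assert np.all(np.abs(acf.values[1:]) < 4 * se)

    def test_masked_samples_break_pairs(self):
        h = np.tile([1.0, 0, 0], (10, 1))
        valid = np.ones(10, bool)
        valid[4] = False
        acf = orientation_acf(_series(h, valid), max_lag=0.2)
        # lag 1 pairs: within runs of length 4 and 5 -> 3 + 4 = 7
        assert acf.counts[1] == 7

    def test_no_valid_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            orientation_acf(_series([[1, 0, 0]], valid=[False]), max_lag=1.0)

    def test_pooling_over_individuals(self):
        s1 = _series([[1, 0, 0]] * 10)
        s2 = _series([[0, 1, 0]] * 20)
        acf = orientation_acf([s1, s2], max_lag=0.2)
        assert np.allclose(acf.values, 1.0)
        assert acf.counts[0] == 30


class TestExponentialFit:
    def test_exact_recovery_of_noiseless_exponential(self):
        t = np.arange(0, int(3 * 15) + 1) / 15.0
        c = 0.9 * np.exp(-t / 0.38)
        acf = ACFResult(lags=t, values=c, counts=np.full(len(t), 100))
        fit = fit_exponential_acf(acf)
        assert fit.amplitude == pytest.approx(0.9, abs=1e-6)
        assert fit.tau == pytest.approx(0.38, abs=1e-6)
        assert fit.residual < 1e-8

    def test_flat_acf_raises_diagnostic(self):
        t = np.arange(0, 46) / 15.0
        acf = ACFResult(lags=t, values=np.ones(len(t)), counts=np.full(len(t), 10))
        with pytest.raises(FlatACFError):
            fit_exponential_acf(acf)

    def test_window_must_hold_three_lags(self):
        acf = ACFResult(
            lags=np.array([0.0, 0.1, 0.2]),
            values=np.array([1.0, 0.5, 0.2]),
            counts=np.array([5, 5, 5]),
        )
        with pytest.raises(InsufficientDataError):
            fit_exponential_acf(acf, fit_window=(0.0, 0.05))

    def test_amplitude_constrained_to_at_most_one(self):
        t = np.arange(0, 31) / 15.0
        c = np.exp(-t / 0.5) * 1.2  # would fit A = 1.2 unconstrained
        c = np.clip(c, None, 1.0)
        acf = ACFResult(lags=t, values=c, counts=np.full(len(t), 10))
        fit = fit_exponential_acf(acf)
        assert fit.amplitude <= 1.0

    def test_tau_in_seconds_invariant_under_frame_rate(self):
        # same analytic decay sampled at 15 and 30 fps
        for fps in (15.0, 30.0):
            t = np.arange(0, int(3 * fps) + 1) / fps
            acf = ACFResult(t, 0.95 * np.exp(-t / 0.8), np.full(len(t), 10))
            assert fit_exponential_acf(acf).tau == pytest.approx(0.8, rel=1e-6)


class TestRotationInvariance:
    def test_speeds_acf_and_tau_unchanged_by_global_rotation(self, rng):
        from shoalkit.synthetic import WalkGenSpec, gen_persistent_walk

        traj = gen_persistent_walk(WalkGenSpec(duration=200.0, tau=0.4, seed=8))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        traj_r = Trajectory("rot", traj.frame_rate, traj.frames, traj.positions @ rot.T)
        kin, kin_r = kinematics(traj), kinematics(traj_r)
        assert np.allclose(kin.speeds, kin_r.speeds)
        acf = orientation_acf(kin.orientations, max_lag=3.0)
        acf_r = orientation_acf(kin_r.orientations, max_lag=3.0)
        assert np.allclose(acf.values, acf_r.values, atol=1e-10)
        assert fit_exponential_acf(acf).tau == pytest.approx(
            fit_exponential_acf(acf_r).tau, rel=1e-6
        )


class TestDistributions:
    def test_single_point_single_unit_mass_bin(self):
        traj = _traj([[3.0, 4.0, 10.0]])
        out = distributions([traj], r_bins=5, z_bins=5)
        assert out["rz_probs"].sum() == pytest.approx(1.0)
        assert (out["rz_probs"] == 1.0).sum() == 1

    def test_ring_concentrates_in_one_cell(self):
        theta = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pos = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), np.full(50, 7.0)])
        out = distributions([_traj(pos)], r_bins=4, z_bins=4)
        assert out["rz_probs"].max() == pytest.approx(1.0)

    def test_bimodal_speed_sample_shows_two_modes(self):
        from shoalkit.synthetic import BIMODAL_DEFAULT, WalkGenSpec, gen_persistent_walk

        spec = WalkGenSpec(duration=400.0, tau=0.4, speed_model=BIMODAL_DEFAULT, seed=2)
        out = distributions([gen_persistent_walk(spec)],
                            speed_bins=np.linspace(0, 300, 16))
        assert count_histogram_modes(out["speed_probs"]) >= 2

    def test_probability_normalisation(self, rng):
        pos = rng.random((200, 3)) * 100
        out = distributions([_traj(pos)])
        assert out["speed_probs"].sum() == pytest.approx(1.0)
        assert out["rz_probs"].sum() == pytest.approx(1.0)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 60))
def test_acf_always_bounded_by_one(seed, n):
    rng = np.random.default_rng(seed)
    h = rng.normal(size=(n, 3))
    h /= np.linalg.norm(h, axis=1, keepdims=True)
    acf = orientation_acf(
        OrientationSeries("h", 15.0, np.arange(n), h, np.ones(n, bool)), max_lag=n / 15.0
    )
    assert np.all(np.abs(acf.values) <= 1.0 + 1e-12)
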