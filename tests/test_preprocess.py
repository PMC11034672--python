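"""Rotation, length filter, standardization, padding, label encoding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dragtraj.core import TrajectoryDataset
from dragtraj import preprocess
from conftest import make_trajectory

finite = st.floats(-500, 500, allow_nan=False)


@st.composite
def random_trajectories(draw):
    n = draw(st.integers(3, 30))
    pts = np.array([[draw(finite), draw(finite)] for _ in range(n)])
    # ensure a usable endpoint away from the origin
    pts[-1] += np.array([draw(st.floats(1.0, 100.0)), draw(st.floats(1.0, 100.0))])
    return make_trajectory(pts)


class TestRotationAngle:
    def test_positive_x_axis_endpoint_needs_no_rotation(self):
        assert preprocess.rotation_angle((240.0, 0.0)).theta_deg == 0.0

    def test_negative_angles_wrap_into_0_360(self):
        assert preprocess.rotation_angle((0.0, -120.0)).theta_deg == pytest.approx(270.0)

    def test_upper_left_target_angle(self):
        # atan2(108, -214.3269) in degrees
        angle = preprocess.rotation_angle((-214.3269, 108.0))
        assert angle.theta_deg == pytest.approx(153.258, abs=0.01)

    def test_origin_endpoint_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            preprocess.rotation_angle((0.0, 0.0))


class TestRotateTrajectory:
    def test_already_canonical_trajectory_unchanged_bitwise(self):
        traj = make_trajectory([(0.0, 0.0), (100.0, 5.0), (240.0, 0.0)])
        rotated = preprocess.rotate_trajectory(traj)
        assert rotated.points is traj.points

    def test_quarter_turn_maps_vertical_to_horizontal(self):
        traj = make_trajectory([(0.0, 0.0), (0.0, 120.0)])
        rotated = preprocess.rotate_trajectory(traj)
        np.testing.assert_allclose(rotated.points[-1], [120.0, 0.0], atol=1e-9)

    def test_diagonal_target_lands_at_its_norm_on_x_axis(self):
        traj = make_trajectory([(0.0, 0.0), (-214.3269, 108.0)])
        rotated = preprocess.rotate_trajectory(traj)
        norm = np.hypot(-214.3269, 108.0)
        assert norm == pytest.approx(240.0, abs=0.01)
        np.testing.assert_allclose(rotated.points[-1], [norm, 0.0], atol=1e-6)

    @given(random_trajectories())
    def test_rotation_is_an_isometry_onto_positive_x_axis(self, traj):
        rotated = preprocess.rotate_trajectory(traj)
        scale = np.linalg.norm(traj.endpoint)
        assert abs(rotated.points[-1, 1]) <= 1e-6 * scale
        assert rotated.points[-1, 0] > 0
        d_orig = np.linalg.norm(
            traj.points[:, None] - traj.points[None, :], axis=-1
        )
        d_rot = np.linalg.norm(
            rotated.points[:, None] - rotated.points[None, :], axis=-1
        )
        np.testing.assert_allclose(d_rot, d_orig, rtol=1e-9, atol=1e-9 * scale)

    @given(random_trajectories())
    def test_rotation_is_idempotent(self, traj):
        once = preprocess.rotate_trajectory(traj)
        angle = preprocess.rotation_angle(once.endpoint)
        assert angle.theta_deg == pytest.approx(0.0, abs=1e-6) or \
            angle.theta_deg == pytest.approx(360.0, abs=1e-6)
        twice = preprocess.rotate_trajectory(once)
        np.testing.assert_allclose(
            twice.points, once.points, atol=1e-6 * max(1.0, np.abs(once.points).max())
        )


class TestLengthFilter:
    def test_bounds_are_inclusive(self):
        rng = np.random.default_rng(0)
        trajs = [
            make_trajectory(rng.normal(size=(n, 2)), trajectory_id=f"t{n}")
            for n in (19, 20, 69, 70)
        ]
        kept = preprocess.filter_by_length(TrajectoryDataset(trajs))
        assert sorted(len(t) for t in kept) == [20, 69]

    def test_in_range_dataset_passes_unchanged(self, small_dataset):
        kept = preprocess.filter_by_length(small_dataset)
        assert len(kept) == len(small_dataset)

    def test_empty_dataset_is_legal(self):
        assert len(preprocess.filter_by_length(TrajectoryDataset([]))) == 0


class TestScaler:
    def test_two_point_standardization(self):
        scaler = preprocess.fit_scaler([np.array([[1.0], [3.0]])])
        out = preprocess.apply_scaler(scaler, np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0])

    def test_fitting_set_becomes_zero_mean_unit_variance(self):
        rng = np.random.default_rng(1)
        seqs = [rng.normal(5, 3, size=(n, 3)) for n in (10, 20, 15)]
        scaler = preprocess.fit_scaler(seqs)
        stacked = np.concatenate([preprocess.apply_scaler(scaler, s) for s in seqs])
        np.testing.assert_allclose(stacked.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(stacked.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            preprocess.fit_scaler([np.ones((5, 2))])

    def test_held_out_data_keeps_nonzero_mean(self):
        rng = np.random.default_rng(2)
        train = [rng.normal(0, 1, size=(50, 2))]
        held_out = rng.normal(0.5, 1, size=(50, 2))
        scaler = preprocess.fit_scaler(train)
        transformed = preprocess.apply_scaler(scaler, held_out)
        assert abs(transformed.mean()) > 1e-6  # no leakage of held-out stats


class TestPadding:
    def test_short_sequence_gets_zero_rows(self):
        out = preprocess.pad_sequence(np.ones((20, 2)))
        assert out.shape == (69, 2)
        np.testing.assert_array_equal(out[20:], 0.0)
        np.testing.assert_array_equal(out[:20], 1.0)

    def test_full_length_sequence_is_noop(self):
        x = np.arange(69 * 4, dtype=float).reshape(69, 4)
        np.testing.assert_array_equal(preprocess.pad_sequence(x), x)

    def test_overlong_sequence_rejected(self):
        with pytest.raises(ValueError, match="69"):
            preprocess.pad_sequence(np.ones((70, 2)))

    def test_truncation_recovers_the_original(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(33, 4))
        padded = preprocess.pad_sequence(x)
        np.testing.assert_array_equal(padded[:33], x)


class TestLabels:
    def test_encoding_follows_the_convention(self):
        assert preprocess.encode_label("TD") == (1.0, 0.0)
        assert preprocess.encode_label("ASD") == (0.0, 1.0)

    @pytest.mark.parametrize("group", ["TD", "ASD"])
    def test_decode_inverts_encode(self, group):
        assert preprocess.decode_label(preprocess.encode_label(group)) == group

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="AUT"):
            preprocess.encode_label("AUT")
        with pytest.raises(ValueError):
            preprocess.decode_label((0.5, 0.5))
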