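"""Plane rotations and rigid / non-rigid trajectory generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from hyperrigid import (
    MotionSpec,
    RotationPlane,
    default_motion_spec,
    generate_trajectory,
    nonrigid_pose,
    rigid_pose,
    rotation_operator,
)


class TestRotationOperator:
    def test_quarter_turn_permutes_zw(self):
        """Fixing the x-y plane, 90 degrees sends z to w."""
        R = rotation_operator(4, ("x", "y"), 90.0)
        assert np.allclose(R @ np.array([0.0, 0.0, 1.0, 0.0]), [0, 0, 0, 1], atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-720, 720, allow_nan=False),
        plane=st.sampled_from(
            [(3, "x"), (3, "y"), (3, "z"), (4, ("x", "y")), (4, ("x", "z")),
             (4, ("y", "z")), (4, ("x", "w")), (4, ("z", "w"))]
        ),
    )
    def test_orthonormal_with_unit_determinant(self, angle, plane):
        dim, inv = plane
        R = rotation_operator(dim, inv, angle)
        assert np.allclose(R.T @ R, np.eye(dim), atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-12)

    def test_composition_adds_angles(self):
        """15 then 30 degrees in one plane equals a single 45-degree turn."""
        a = rotation_operator(4, ("x", "y"), 15.0)
        b = rotation_operator(4, ("x", "y"), 30.0)
        c = rotation_operator(4, ("x", "y"), 45.0)
        assert np.allclose(b @ a, c, atol=1e-12)

    def test_fixes_invariant_coordinates(self):
        R = rotation_operator(4, ("y", "z"), 37.0)
        for v in (np.array([0, 1.0, 0, 0]), np.array([0, 0, 1.0, 0])):
            assert np.allclose(R @ v, v, atol=1e-12)

    @pytest.mark.parametrize("bad", [("q",), ("x", "x"), ("x",), ("x", "y", "z")])
    def test_invalid_invariant_rejected(self, bad):
        with pytest.raises(ValueError):
            rotation_operator(4, bad, 10.0)

    def test_3d_invariant_is_a_single_axis(self):
        """In 3D the invariant degenerates to the familiar rotation axis."""
        R = rotation_operator(3, "x", 30.0)
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        assert np.allclose(R, [[1, 0, 0], [0, c, -s], [0, s, c]], atol=1e-12)


class TestRigidPose:
    def test_zero_phase_at_t0_is_identity(self, hypercube):
        spec = default_motion_spec(4, "rigid")
        spec = MotionSpec(
            kind="rigid",
            rotation_planes=tuple(
                RotationPlane(p.invariant, p.amplitude_deg, p.frequency_hz, 0.0)
                for p in spec.rotation_planes
            ),
        )
        assert np.allclose(rigid_pose(hypercube, spec, 0.0), hypercube.vertices)

    @pytest.mark.parametrize("t", [0.3, 1.0, 2.7])
    def test_isometry_at_any_time(self, hypercube, t):
        spec = default_motion_spec(4, "rigid", jitter_amplitude=0.0)
        snap = rigid_pose(hypercube, spec, t)
        assert np.allclose(pdist(snap), pdist(hypercube.vertices), rtol=1e-9)

    def test_quarter_period_reaches_full_amplitude(self, cube):
        """A 30-deg, 0.25 Hz x-axis plane is exactly 30 deg at t = 1 s."""
        spec = MotionSpec(
            kind="rigid", rotation_planes=(RotationPlane("x", 30.0, 0.25, 0.0),)
        )
        expected = cube.vertices @ rotation_operator(3, "x", 30.0).T
        assert np.allclose(rigid_pose(cube, spec, 1.0), expected, atol=1e-9)


class TestNonrigidPose:
    def test_degenerate_nonrigidity_equals_rigid(self, cube):
        spec = MotionSpec(
            kind="nonrigid",
            rotation_planes=default_motion_spec(3, "rigid").rotation_planes,
            shear_axis="x",
            shear_amplitude=0.0,
            deform_amplitude=0.0,
        )
        t = 0.8
        assert np.allclose(
            nonrigid_pose(cube, spec, t, seed=4), rigid_pose(cube, spec, t)
        )

    def test_shear_changes_pairwise_distances_at_peak(self, cube):
        """At peak shear phase at least one distance moves by > 1% of side."""
        spec = MotionSpec(
            kind="nonrigid",
            rotation_planes=(),
            shear_axis="x",
            shear_amplitude=0.2,
            shear_frequency_hz=0.5,
        )
        t_peak = 0.5  # sin(2*pi*0.5*0.5) = 1
        snap = nonrigid_pose(cube, spec, t_peak, seed=4)
        dev = np.abs(pdist(snap) - pdist(cube.vertices))
        assert dev.max() > 0.01 * cube.side_length

    def test_shear_acts_on_transverse_coordinate(self, cube):
        """x-shear at peak adds 0.2 * y to x exactly (cyclic transverse)."""
        spec = MotionSpec(
            kind="nonrigid", rotation_planes=(), shear_axis="x",
            shear_amplitude=0.2, shear_frequency_hz=0.5,
        )
        snap = nonrigid_pose(cube, spec, 0.5, seed=0)
        expected = cube.vertices.copy()
        expected[:, 0] += 0.2 * expected[:, 1]
        assert np.allclose(snap, expected, atol=1e-9)

    def test_seeded_determinism(self, cube):
        spec = default_motion_spec(3, "nonrigid", "y", jitter_amplitude=0.0)
        a = nonrigid_pose(cube, spec, 1.1, seed=5)
        b = nonrigid_pose(cube, spec, 1.1, seed=5)
        c = nonrigid_pose(cube, spec, 1.1, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_missing_shear_axis_rejected(self):
        with pytest.raises(ValueError):
            MotionSpec(kind="nonrigid", rotation_planes=(), shear_axis=None)

    def test_rigid_spec_cannot_carry_shear(self):
        with pytest.raises(ValueError):
            MotionSpec(kind="rigid", rotation_planes=(), shear_axis="x",
                       shear_amplitude=0.1)


class TestGenerateTrajectory:
    def test_frame_count_is_duration_times_rate(self, hypercube):
        """3 s at 90 Hz yields 270 frames at uniform times."""
        spec = default_motion_spec(4, "rigid")
        traj = generate_trajectory(hypercube, spec, seed=1)
        assert traj.n_frames == 270
        assert np.allclose(np.diff(traj.frame_times), 1 / 90)

    def test_jitter_free_rigid_frames_are_isometries(self, rigid_traj_4d, hypercube):
        d0 = pdist(hypercube.vertices)
        for t in range(0, rigid_traj_4d.n_frames, 27):
            assert np.allclose(pdist(rigid_traj_4d.frames[t]), d0, rtol=1e-9)

    def test_trajectory_bit_reproducible(self, cube):
        spec = default_motion_spec(3, "nonrigid", "z")  # jitter on
        a = generate_trajectory(cube, spec, seed=21)
        b = generate_trajectory(cube, spec, seed=21)
        assert np.array_equal(a.frames, b.frames)

    def test_jitter_displacement_bounded_by_amplitude(self, cube):
        rigid = default_motion_spec(3, "rigid", jitter_amplitude=0.0)
        jittered = default_motion_spec(3, "rigid", jitter_amplitude=0.5)
        base = generate_trajectory(cube, rigid, seed=3)
        jit = generate_trajectory(cube, jittered, seed=3)
        norms = np.linalg.norm(jit.frames - base.frames, axis=2)
        assert norms.max() <= 0.5 + 1e-12
        assert norms.max() > 0.1  # jitter actually present

    def test_csv_and_json_round_trip(self, tmp_path, cube):
        spec = default_motion_spec(3, "rigid", duration_s=0.1)
        traj = generate_trajectory(cube, spec, seed=2)
        df = traj.to_frame()
        assert len(df) == traj.n_frames * 8
        assert list(df.columns) == ["frame", "time_s", "vertex", "x", "y", "z"]
        path = tmp_path / "traj.json"
        traj.to_json(path)
        back = type(traj).from_json(path)
        assert np.allclose(back.frames, traj.frames)
        assert back.source_spec == traj.source_spec
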