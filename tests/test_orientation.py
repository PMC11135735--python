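"""Local frames, floating axes, and the three orientation angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from softarm import (
    ColinearityError,
    LocalFrame,
    SingularConfigurationError,
    build_local_frame,
    floating_axes,
    relative_orientation,
)
from conftest import random_triple


def frame_axes(frame):
    return np.array([frame.I_hat, frame.J_hat, frame.K_hat])


class TestLocalFrame:
    def test_hand_computed_example(self):
        f = build_local_frame((0, 0, 0), (1, 0.2, 0), (2, 0, 0))
        np.testing.assert_allclose(f.K_hat, [-1, 0, 0], atol=1e-15)
        np.testing.assert_allclose(f.I_hat, [0, 0, 1], atol=1e-15)
        np.testing.assert_allclose(f.J_hat, [0, 1, 0], atol=1e-15)

    def test_orthonormal_right_handed(self, rng):
        for _ in range(200):
            f = build_local_frame(*random_triple(rng, min_area=1.0))
            axes = frame_axes(f)
            np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-12)
            assert np.cross(f.K_hat, f.I_hat) @ f.J_hat == pytest.approx(
                1.0, abs=1e-12
            )

    def test_colinear_raises(self):
        with pytest.raises(ColinearityError):
            build_local_frame((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_coincident_raises(self):
        with pytest.raises(ColinearityError):
            build_local_frame((0, 0, 0), (0, 0, 0), (2, 0, 0))

    def test_equivariance_under_rigid_motion(self, rng, random_rigid):
        # rotating the markers rotates the frame axes identically
        for _ in range(100):
            pts = random_triple(rng, min_area=1.0)
            f = build_local_frame(*pts)
            q, t = random_rigid()
            g = build_local_frame(*(q.apply(pts) + t))
            np.testing.assert_allclose(
                frame_axes(g), q.apply(frame_axes(f)), atol=1e-12
            )


def make_frame(rotation=None):
    """A LocalFrame from an orthonormal basis, optionally rotated."""
    axes = np.eye(3)
    if rotation is not None:
        axes = rotation.apply(axes)
    return LocalFrame(
        I_hat=axes[0], J_hat=axes[1], K_hat=axes[2], origin=np.zeros(3)
    )


class TestFloatingAxes:
    def test_identical_frames_well_defined(self):
        f = make_frame()
        ax = floating_axes(f, f)
        assert np.linalg.norm(ax.e2) == pytest.approx(1.0, abs=1e-12)

    def test_parallel_fixed_axes_raise_with_angle(self):
        prox = make_frame()
        # distal long axis k parallel to proximal I
        dist = LocalFrame(
            I_hat=np.array([0.0, 0, 1]),
            J_hat=np.array([0.0, 1, 0]),
            K_hat=np.array([1.0, 0, 0]),
            origin=np.zeros(3),
        )
        with pytest.raises(SingularConfigurationError) as exc:
            floating_axes(prox, dist)
        assert exc.value.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_e2_orthogonal_to_both(self, rng):
        for _ in range(200):
            prox = make_frame(Rotation.random(rng=rng))
            dist = make_frame(Rotation.random(rng=rng))
            try:
                ax = floating_axes(prox, dist)
            except SingularConfigurationError:
                continue
            assert abs(ax.e2 @ ax.e1) < 1e-12
            assert abs(ax.e2 @ ax.e3) < 1e-12


class TestRelativeOrientation:
    def test_identity_configuration_is_zero(self):
        f = make_frame()
        a = relative_orientation(f, f)
        assert a.as_tuple() == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_pure_flexion_recovered(self):
        # -40 deg flexion: rotate the distal frame by +40 about I (the
        # arcsin(-e2.K) convention maps +theta about I to alpha = -theta)
        prox = make_frame()
        dist = make_frame(Rotation.from_rotvec(np.radians(40) * np.eye(3)[0]))
        a = relative_orientation(prox, dist)
        assert a.alpha == pytest.approx(-40.0, abs=1e-6)
        assert a.beta == pytest.approx(0.0, abs=1e-6)
        assert a.gamma == pytest.approx(0.0, abs=1e-6)

    def test_long_axis_twist_beyond_90_recovered(self):
        # gamma must resolve the full revolution, not fold at +-90
        prox = make_frame()
        dist = make_frame(Rotation.from_rotvec(np.radians(155) * np.eye(3)[2]))
        a = relative_orientation(prox, dist)
        assert a.gamma == pytest.approx(155.0, abs=1e-6)
        assert a.alpha == pytest.approx(0.0, abs=1e-6)
        assert a.beta == pytest.approx(0.0, abs=1e-6)

    def test_rigid_invariance_of_all_angles(self, rng, random_rigid):
        # one common rigid motion of all six markers changes nothing
        for _ in range(50):
            prox_pts = random_triple(rng, min_area=1.0)
            dist_pts = random_triple(rng, min_area=1.0)
            try:
                a0 = relative_orientation(
                    build_local_frame(*prox_pts), build_local_frame(*dist_pts)
                )
            except SingularConfigurationError:
                continue
            q, t = random_rigid()
            a1 = relative_orientation(
                build_local_frame(*(q.apply(prox_pts) + t)),
                build_local_frame(*(q.apply(dist_pts) + t)),
            )
            assert a1.as_tuple() == pytest.approx(a0.as_tuple(), abs=1e-9)

    def test_alpha_bounded_by_90(self, rng):
        # arcsin range: |alpha| can never exceed 90 deg
        n = 0
        while n < 2000:
            prox = make_frame(Rotation.random(rng=rng))
            dist = make_frame(Rotation.random(rng=rng))
            try:
                a = relative_orientation(prox, dist)
            except SingularConfigurationError:
                continue
            assert abs(a.alpha) <= 90.0
            assert -180.0 < a.gamma <= 180.0
            assert abs(a.beta) <= 90.0
            n += 1

    def test_near_singular_degrades_without_error(self):
        # just above the parallel tolerance the angles still compute
        eps = 1e-6
        prox = make_frame()
        dist = make_frame(
            Rotation.from_rotvec((np.pi / 2 - eps) * np.eye(3)[1])
        )
        # rotating k toward I by almost 90 deg: close to singular
        a = relative_orientation(prox, dist)
        assert np.isfinite(a.as_tuple()).all()
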