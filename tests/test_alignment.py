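import math

import numpy as np
import pytest

from shapeqtl import (
    AlignConfig, PoseParameters, ShapeSet, align_shapes, apply_pose,
    energy_gradient, joint_energy, pose_matrix,
)
from shapeqtl.alignment import JointAligner, pose_from_matrix
from shapeqtl.errors import InvalidPoseError
from shapeqtl.simulate import perturb_poses


class TestPoseMatrix:
    def test_identity_pose(self):
        assert np.allclose(pose_matrix(PoseParameters()), np.eye(3))

    def test_pure_translation(self):
        T = pose_matrix(PoseParameters(a=2, b=3))
        assert np.allclose(T @ [1, 1, 1], [3, 4, 1])

    def test_scale_then_rotate_point(self):
        # M(0,0) H(2) R(pi/2) maps centered (1, 0) to (0, 2)
        T = pose_matrix(PoseParameters(h=2, theta=math.pi / 2))
        assert np.allclose(T @ [1, 0, 1], [0, 2, 1], atol=1e-12)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(InvalidPoseError):
            PoseParameters(h=0.0)

    def test_round_trip_through_matrix(self):
        p = PoseParameters(a=1.5, b=-2.0, h=0.8, theta=0.7)
        q = pose_from_matrix(pose_matrix(p))
        assert np.allclose(p.as_array(), q.as_array())


class TestApplyPose:
    def test_identity_returns_input(self, wild_leaf):
        out = apply_pose(wild_leaf, PoseParameters())
        assert np.allclose(out, wild_leaf.pixels)

    def test_integer_shift_nearest_preserves_count(self, wild_leaf):
        out = apply_pose(wild_leaf, PoseParameters(a=3, b=-2), order=0)
        assert out.sum() == wild_leaf.foreground_count

    def test_two_half_turns_recover_image(self, wild_leaf):
        once = apply_pose(wild_leaf, PoseParameters(theta=math.pi), order=1)
        twice = apply_pose(once, PoseParameters(theta=math.pi), order=1)
        assert np.abs(twice - wild_leaf.pixels).max() <= 0.5


class TestJointEnergy:
    def test_identical_images_zero(self, wild_leaf):
        imgs = [wild_leaf.pixels.astype(float)] * 4
        assert joint_energy(imgs) == 0.0

    def test_single_image_zero(self, wild_leaf):
        assert joint_energy([wild_leaf.pixels.astype(float)]) == 0.0

    def test_matches_brute_force_double_loop(self, rng):
        a = (rng.random((4, 4)) < 0.5).astype(float)
        b = a.copy()
        flip = [(0, 1), (2, 3)]
        for r, c in flip:
            b[r, c] = 1 - b[r, c]
        num = den = 0.0
        for r in range(4):
            for c in range(4):
                num += (a[r, c] - b[r, c]) ** 2
                den += (a[r, c] + b[r, c]) ** 2
        assert joint_energy([a, b]) == pytest.approx(num / den, rel=1e-12)
        assert joint_energy([a, b], normalized=False) == pytest.approx(num)

    def test_invariant_under_common_pose(self, leaf_pair):
        """Shared-pose gauge degeneracy: one rigid pose applied to every shape
        leaves the energy unchanged up to interpolation error."""
        aligner = JointAligner(leaf_pair, AlignConfig())
        e0 = aligner.energy([PoseParameters()] * 2)
        common = PoseParameters(a=1.0, b=-0.5, theta=0.15)
        assert aligner.energy([common] * 2) == pytest.approx(e0, abs=1e-2)


class TestEnergyGradient:
    def test_zero_at_identical_images(self, wild_leaf):
        shapes = ShapeSet([wild_leaf] * 3)
        g = energy_gradient(shapes, [PoseParameters()] * 3)
        assert np.allclose(g, 0.0, atol=1e-10)

    def test_single_image_zero_gradient(self, wild_leaf):
        g = energy_gradient(ShapeSet([wild_leaf, wild_leaf]), [PoseParameters()] * 2)
        assert np.allclose(g, 0.0, atol=1e-10)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_finite_differences(self, leaf_pair, normalized):
        cfg = AlignConfig(normalized=normalized)
        aligner = JointAligner(leaf_pair, cfg)
        poses = [PoseParameters(0.5, -0.3, 1.05, 0.1),
                 PoseParameters(-0.2, 0.4, 0.95, -0.08)]
        _, grad = aligner.energy_and_gradient(poses)
        eps = 1e-5
        for i in range(2):
            for k in range(4):
                vals = []
                for s in (eps, -eps):
                    arrs = [p.as_array() for p in poses]
                    arrs[i][k] += s
                    vals.append(aligner.energy([PoseParameters(*v) for v in arrs]))
                fd = (vals[0] - vals[1]) / (2 * eps)
                assert grad[i, k] == pytest.approx(fd, rel=1e-3, abs=1e-10)


class TestAlignShapes:
    def test_already_aligned_identical_shapes_stay_put(self, wild_leaf):
        res = align_shapes(ShapeSet([wild_leaf] * 3))
        assert res.energy_trace[-1] == pytest.approx(0.0, abs=1e-9)
        for p in res.poses:
            assert np.allclose(p.as_array(), [0, 0, 1, 0], atol=1e-6)

    def test_energy_trace_non_increasing(self, wild_leaf):
        shapes = ShapeSet([wild_leaf] * 4)
        pert, _ = perturb_poses(shapes, max_shift=2.0, max_log_scale=0.05,
                                max_angle=0.15, seed=9)
        res = align_shapes(pert)
        assert (np.diff(res.energy_trace) <= 1e-12).all()

    def test_disjoint_translates_end_far_below_unaligned_energy(self):
        from shapeqtl import BinaryShapeImage

        base = np.zeros((24, 24), dtype=np.uint8)
        base[4:9, 4:9] = 1
        other = np.zeros((24, 24), dtype=np.uint8)
        other[15:20, 14:19] = 1
        shapes = ShapeSet([BinaryShapeImage(base), BinaryShapeImage(other)])
        unaligned = joint_energy([base.astype(float), other.astype(float)])
        res = align_shapes(shapes)
        assert res.energy_trace[-1] < unaligned
        assert (np.diff(res.energy_trace) <= 1e-12).all()

    def test_known_pose_perturbations_recovered(self, wild_leaf):
        """Simulate-and-recover: relative poses must invert the perturbations."""
        shapes = ShapeSet([wild_leaf] * 4)
        pert, truth = perturb_poses(shapes, max_shift=2.0,
                                    max_log_scale=math.log(1.05),
                                    max_angle=math.radians(8), seed=21)
        res = align_shapes(pert)
        T1 = pose_matrix(truth[0])
        for i in range(4):
            expected = pose_from_matrix(T1 @ np.linalg.inv(pose_matrix(truth[i])))
            got = res.poses[i]
            assert got.a == pytest.approx(expected.a, abs=0.5)
            assert got.b == pytest.approx(expected.b, abs=0.5)
            assert got.h == pytest.approx(expected.h, rel=0.02)
            assert abs(got.theta - expected.theta) <= math.radians(2)
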