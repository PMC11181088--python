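"""Pose parameterizations, MPJPE, model RDM construction and normalization."""

import numpy as np
import pytest

import poselight as pl
from poselight import (
    ConfigurationError,
    DegenerateRDMError,
    InvalidInputError,
    PoseRecord,
    RDM,
    ShapeError,
    align_view_independent,
    build_model_rdm,
    mean_per_joint_distance,
    normalize_rdm,
    project_to_2d,
)
from poselight.pose import JOINT_NAMES, N_JOINTS
from poselight.rdm import lower_triangle


def make_pose(image_id, joints, R=None, joint_rotations=None):
    return PoseRecord(
        image_id=image_id,
        joints3d=joints,
        global_rotation=np.eye(3) if R is None else R,
        joint_rotations=joint_rotations,
    )


class TestPoseRecord:
    def test_wrong_joint_count(self):
        with pytest.raises(ShapeError):
            make_pose("a", np.zeros((5, 3)))

    def test_invalid_rotation(self):
        with pytest.raises(InvalidInputError):
            make_pose("a", np.zeros((N_JOINTS, 3)), R=np.ones((3, 3)))


class TestProjection:
    def test_drops_depth_coordinate(self):
        joints = np.tile([1.0, 2.0, 3.0], (N_JOINTS, 1))
        p2d = project_to_2d(make_pose("a", joints))
        assert np.array_equal(p2d, np.tile([1.0, 2.0], (N_JOINTS, 1)))

    def test_depth_is_invisible_in_2d(self, rng):
        joints = rng.normal(size=(N_JOINTS, 3))
        other = joints.copy()
        other[:, 2] = rng.normal(size=N_JOINTS)
        assert np.array_equal(
            project_to_2d(make_pose("a", joints)), project_to_2d(make_pose("b", other))
        )


class TestViewIndependentAlignment:
    def test_identity_rotation_is_noop(self, rng):
        joints = rng.normal(size=(N_JOINTS, 3))
        assert np.allclose(align_view_independent(make_pose("a", joints)), joints)

    def test_inverts_known_rotation(self, rng):
        P = rng.normal(size=(N_JOINTS, 3))
        R = pl.random_rotation_matrix(rng)
        pose = make_pose("a", P @ R.T, R=R)
        assert np.abs(align_view_independent(pose) - P).max() < 1e-9

    def test_shared_canonical_pose_aligns_identically(self, rng):
        P = rng.normal(size=(N_JOINTS, 3))
        R1, R2 = pl.random_rotation_matrix(rng), pl.random_rotation_matrix(rng)
        a = align_view_independent(make_pose("a", P @ R1.T, R=R1))
        b = align_view_independent(make_pose("b", P @ R2.T, R=R2))
        assert np.abs(a - b).max() < 1e-9


class TestMeanPerJointDistance:
    def test_identity(self, rng):
        a = rng.normal(size=(N_JOINTS, 3))
        assert mean_per_joint_distance(a, a) == 0.0

    def test_uniform_offset(self):
        a = np.zeros((N_JOINTS, 3))
        b = a + np.array([3.0, 4.0, 0.0])  # per-joint norm 5
        assert mean_per_joint_distance(a, b) == pytest.approx(5.0)

    def test_two_joint_hand_computation(self):
        a = np.zeros((2, 3))
        b = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])  # (1 + 2) / 2
        assert mean_per_joint_distance(a, b) == pytest.approx(1.5)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(1000):
            a, b, c = rng.normal(size=(3, N_JOINTS, 3))
            dab = mean_per_joint_distance(a, b)
            assert dab >= 0
            assert dab == mean_per_joint_distance(b, a)
            assert mean_per_joint_distance(a, c) <= dab + mean_per_joint_distance(b, c) + 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            mean_per_joint_distance(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ShapeError):
            mean_per_joint_distance(np.zeros((3, 2)), np.zeros((3, 3)))


class TestBuildModelRDM:
    def test_identical_poses_give_zero_rdm(self, rng):
        joints = rng.normal(size=(N_JOINTS, 3))
        poses = [make_pose("a", joints), make_pose("b", joints)]
        for model in ("view_dep_3d", "view_dep_2d", "view_indep_3d", "viewpoint"):
            assert np.allclose(build_model_rdm(poses, model).values, 0.0)

    def test_structure(self, poses60):
        records, _ = poses60
        rdm = build_model_rdm(records, "view_dep_3d")
        n = len(records)
        assert rdm.values.shape == (n, n)
        assert np.allclose(rdm.values, rdm.values.T)
        assert np.all(np.diag(rdm.values) == 0)
        assert rdm.item_ids == [p.image_id for p in records]

    def test_view_independent_vs_dependent_under_rotation(self, rng):
        # same canonical poses, different viewpoints: only the aligned RDM is zero
        P = rng.normal(size=(N_JOINTS, 3))
        poses = []
        for i in range(4):
            R = pl.random_rotation_matrix(rng)
            poses.append(make_pose(f"p{i}", P @ R.T, R=R))
        vi = build_model_rdm(poses, "view_indep_3d")
        vd = build_model_rdm(poses, "view_dep_3d")
        assert np.abs(vi.values).max() < 1e-9
        assert lower_triangle(vd.values).min() > 0

    def test_projection_consistency(self, poses60):
        # the 2D model RDM equals MPJPE on the first two coordinates
        records, _ = poses60
        rdm2d = build_model_rdm(records[:10], "view_dep_2d")
        expected = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                expected[i, j] = np.linalg.norm(
                    records[i].joints3d[:, :2] - records[j].joints3d[:, :2], axis=1
                ).mean()
        assert np.array_equal(rdm2d.values, (expected + expected.T) / 2)

    def test_duplicate_ids_rejected(self, rng):
        joints = rng.normal(size=(N_JOINTS, 3))
        with pytest.raises(InvalidInputError, match="duplicate"):
            build_model_rdm([make_pose("a", joints), make_pose("a", joints)], "view_dep_3d")

    def test_joint_rotation_model_requires_rotations(self, rng):
        joints = rng.normal(size=(N_JOINTS, 3))
        poses = [make_pose("a", joints), make_pose("b", joints)]
        with pytest.raises(ConfigurationError, match="joint_rotation"):
            build_model_rdm(poses, "joint_rotation")

    def test_joint_rotation_rdm_matches_pairwise_metric(self, poses60):
        records, _ = poses60
        sub = records[:6]
        rdm = build_model_rdm(sub, "joint_rotation")
        d01 = pl.joint_rotation_distance(sub[0].joint_rotations, sub[1].joint_rotations)
        assert rdm.values[0, 1] == pytest.approx(d01, abs=1e-12)


class TestNormalizeRDM:
    def _rdm_from_offdiag(self, tri_vals):
        # 3-item RDM with given lower-triangle values
        v = np.zeros((3, 3))
        v[1, 0], v[2, 0], v[2, 1] = tri_vals
        return RDM(item_ids=["a", "b", "c"], values=v + v.T)

    def test_linear_map(self):
        out = normalize_rdm(self._rdm_from_offdiag([0.0, 2.0, 4.0]))
        assert sorted(lower_triangle(out.values)) == [0.0, 0.5, 1.0]
        assert out.normalized

    def test_idempotent_on_attained_bounds(self):
        rdm = self._rdm_from_offdiag([0.0, 0.5, 1.0])
        out = normalize_rdm(rdm)
        assert np.allclose(out.values, rdm.values)

    def test_constant_offdiagonal_raises(self):
        with pytest.raises(DegenerateRDMError):
            normalize_rdm(self._rdm_from_offdiag([1.0, 1.0, 1.0]))

    def test_order_preserving(self, model_rdms):
        raw = model_rdms["view_dep_3d"]
        again = normalize_rdm(raw)
        a, b = lower_triangle(raw.values), lower_triangle(again.values)
        assert np.array_equal(np.argsort(a), np.argsort(b))


class TestPoseIO:
    def test_json_round_trip(self, poses60, tmp_path):
        records, _ = poses60
        path = tmp_path / "poses.json"
        pl.save_poses_json(records[:8], path)
        back = pl.load_poses_json(path)
        for a, b in zip(records[:8], back):
            assert a.image_id == b.image_id
            assert np.allclose(a.joints3d, b.joints3d)
            assert np.allclose(a.global_rotation, b.global_rotation)
            for qa, qb in zip(a.joint_rotations, b.joint_rotations):
                assert pl.viewpoint_distance(qa, qb) < 1e-9

    def test_csv_round_trip(self, poses60, tmp_path):
        records, _ = poses60
        path = tmp_path / "poses.csv"
        pl.save_poses_csv(records[:5], path)
        back = pl.load_poses_csv(path)
        for a, b in zip(records[:5], back):
            assert np.allclose(a.joints3d, b.joints3d)
            assert np.allclose(a.global_rotation, b.global_rotation)


class TestRDMIO:
    def test_tsv_round_trip(self, model_rdms, tmp_path):
        rdm = model_rdms["viewpoint"]
        path = tmp_path / "rdm.tsv"
        rdm.to_tsv(path)
        back = RDM.from_tsv(path)
        assert back.item_ids == rdm.item_ids
        assert np.allclose(back.values, rdm.values)
        assert back.model == "viewpoint"
        assert back.normalized
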