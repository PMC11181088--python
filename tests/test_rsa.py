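"""Pattern preparation, neural RDMs, RSA and partial correlation."""

import numpy as np
import pytest

import poselight as pl
from poselight import (
    AlignmentError,
    CollinearityError,
    DegenerateItemError,
    InsufficientDataError,
    InvalidInputError,
    NeuralDataset,
    RDM,
    fisher_z,
    neural_rdm,
    partial_rsa,
    prepare_patterns,
    rsa_correlation,
)
from poselight.rsa import PatternMatrix


def flat_dataset(betas, trial_ids):
    betas = np.asarray(betas, dtype=float)
    V = betas.shape[1]
    mask = np.ones((1, 1, V), dtype=bool)
    idx = np.column_stack([np.zeros(V, int), np.zeros(V, int), np.arange(V)])
    return NeuralDataset(
        betas=betas, trial_image_ids=trial_ids, voxel_index=idx, voxel_size_mm=1.0, mask=mask
    )


def rdm_from_matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    return RDM(item_ids=ids, values=values)


class TestPreparePatterns:
    def test_repeats_are_averaged(self):
        betas = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 2.0], [5.0, 4.0], [6.0, 5.0], [7.0, 9.0]])
        ids = ["a", "a", "a", "b", "c", "d"]
        pm = prepare_patterns(flat_dataset(betas, ids))
        # image "a" shown 3x with betas 1, 2, 3 at voxel 0: mean 2 before z-scoring
        means = np.array([[2.0, 1.0], [5.0, 4.0], [6.0, 5.0], [7.0, 9.0]])
        expected = (means - means.mean(0)) / means.std(0, ddof=1)
        assert pm.item_ids == ["a", "b", "c", "d"]
        assert np.allclose(pm.patterns, expected)

    def test_columns_standardized(self, rng):
        betas = rng.normal(size=(12, 7))
        ids = [f"img{k % 6}" for k in range(12)]
        pm = prepare_patterns(flat_dataset(betas, ids))
        assert np.abs(pm.patterns.mean(axis=0)).max() < 1e-6
        assert np.abs(pm.patterns.std(axis=0, ddof=1) - 1).max() < 1e-6

    def test_constant_voxel_excluded(self, rng):
        betas = rng.normal(size=(4, 3))
        betas[:, 1] = 5.0
        pm = prepare_patterns(flat_dataset(betas, ["a", "b", "c", "d"]))
        assert list(pm.excluded_voxels) == [1]
        assert pm.patterns.shape == (4, 2)

    def test_too_few_images(self, rng):
        with pytest.raises(InsufficientDataError):
            prepare_patterns(flat_dataset(rng.normal(size=(4, 3)), ["a", "b", "a", "b"]))


class TestNeuralRDM:
    def test_identical_and_anticorrelated_patterns(self):
        pm = PatternMatrix(
            item_ids=["a", "b", "c"],
            patterns=np.array([[1.0, -1.0, 2.0], [1.0, -1.0, 2.0], [-1.0, 1.0, -2.0]]),
        )
        rdm = neural_rdm(pm)
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.values[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_uncorrelated_patterns(self):
        pm = PatternMatrix(
            item_ids=["a", "b"], patterns=np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        )
        assert neural_rdm(pm).values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_flat_item_pattern_rejected(self):
        pm = PatternMatrix(item_ids=["a", "b"], patterns=np.array([[1.0, 1.0], [0.0, 1.0]]))
        with pytest.raises(DegenerateItemError, match="a"):
            neural_rdm(pm)

    def test_voxel_order_invariance(self, rng):
        X = rng.normal(size=(5, 30))
        pm1 = PatternMatrix(item_ids=list("abcde"), patterns=X)
        perm = rng.permutation(30)
        pm2 = PatternMatrix(item_ids=list("abcde"), patterns=X[:, perm])
        assert np.allclose(neural_rdm(pm1).values, neural_rdm(pm2).values)


class TestRsaCorrelation:
    def test_self_correlation(self, model_rdms):
        rdm = model_rdms["view_dep_3d"]
        assert rsa_correlation(rdm, rdm) == pytest.approx(1.0)

    def test_affine_invariance(self, model_rdms):
        rdm = model_rdms["view_dep_3d"]
        scaled = RDM(item_ids=rdm.item_ids, values=rdm.values * 3.0)
        assert rsa_correlation(rdm, scaled) == pytest.approx(1.0)

    def test_four_item_hand_computed_oracle(self):
        # two fixed 6-vectors; expected value from the covariance formula
        x = np.array([0.2, 0.5, 0.1, 0.9, 0.4, 0.7])
        y = np.array([0.3, 0.4, 0.2, 0.8, 0.1, 0.9])
        expected = ((x - x.mean()) @ (y - y.mean())) / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        def rdm_from_tri(t):
            v = np.zeros((4, 4))
            v[np.tril_indices(4, -1)] = t
            return rdm_from_matrix(v + v.T)
        assert rsa_correlation(rdm_from_tri(x), rdm_from_tri(y)) == pytest.approx(expected, abs=1e-12)

    def test_item_order_permutation_invariance(self, model_rdms, rng):
        a, b = model_rdms["view_dep_3d"], model_rdms["viewpoint"]
        r0 = rsa_correlation(a, b)
        perm = list(rng.permutation(a.item_ids))
        assert rsa_correlation(a.subset(perm), b) == pytest.approx(r0, abs=1e-12)

    def test_mismatched_items(self, model_rdms):
        a = model_rdms["view_dep_3d"]
        b = a.subset(a.item_ids[:10])
        with pytest.raises(AlignmentError):
            rsa_correlation(a, b)


class TestPartialRSA:
    def test_empty_controls_equal_standard(self, model_rdms):
        a, b = model_rdms["view_dep_3d"], model_rdms["viewpoint"]
        assert partial_rsa(a, b, []) == rsa_correlation(a, b)

    def test_three_variable_closed_form(self, rng):
        # partial r_xy.z == (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))
        n = 15
        m = n * (n - 1) // 2
        for _ in range(20):
            x, y, z = rng.normal(size=(3, m))
            def to_rdm(t):
                v = np.zeros((n, n))
                v[np.tril_indices(n, -1)] = t - t.min() + 0.1
                return rdm_from_matrix(v + v.T)
            rx, ry, rz = to_rdm(x), to_rdm(y), to_rdm(z)
            r_xy = rsa_correlation(rx, ry)
            r_xz = rsa_correlation(rx, rz)
            r_yz = rsa_correlation(ry, rz)
            expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            assert partial_rsa(rx, ry, [rz]) == pytest.approx(expected, abs=1e-10)

    def test_orthogonal_controls_leave_r_unchanged(self, rng):
        # controls orthogonal (in triangle space) to both variables
        n = 20
        m = n * (n - 1) // 2
        x, y = rng.normal(size=(2, m))
        q, _ = np.linalg.qr(np.column_stack([np.ones(m), x, y, rng.normal(size=m)]))
        z = q[:, 3]  # orthogonal to 1, x, y
        def to_rdm(t):
            v = np.zeros((n, n))
            v[np.tril_indices(n, -1)] = t - t.min() + 0.1
            return rdm_from_matrix(v + v.T)
        rx, ry, rz = to_rdm(x), to_rdm(y), to_rdm(z)
        assert partial_rsa(rx, ry, [rz]) == pytest.approx(rsa_correlation(rx, ry), abs=1e-9)

    def test_target_in_controls_collinear(self, model_rdms):
        a, b = model_rdms["view_dep_3d"], model_rdms["viewpoint"]
        with pytest.raises(CollinearityError):
            partial_rsa(a, b, [b])


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_symmetry(self, rng):
        for r in rng.uniform(-0.99, 0.99, size=20):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_clipping_at_one(self):
        assert np.isfinite(fisher_z(1.0))

    def test_domain_error(self):
        with pytest.raises(InvalidInputError):
            fisher_z(1.5)


class TestNiftiRoundTrip:
    def test_dataset_io(self, tmp_path, rng):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        idx = np.argwhere(mask)
        ds = NeuralDataset(
            betas=rng.normal(size=(6, len(idx))),
            trial_image_ids=["a", "b", "c", "a", "b", "c"],
            voxel_index=idx,
            voxel_size_mm=1.8,
            mask=mask,
        )
        ds.to_nifti(tmp_path / "b.nii.gz", tmp_path / "m.nii.gz", tmp_path / "t.tsv")
        back = NeuralDataset.from_nifti(tmp_path / "b.nii.gz", tmp_path / "m.nii.gz", tmp_path / "t.tsv")
        assert np.allclose(back.betas, ds.betas, atol=1e-6)
        assert back.trial_image_ids == ds.trial_image_ids
        assert np.array_equal(back.voxel_index, ds.voxel_index)
        assert back.voxel_size_mm == pytest.approx(1.8)
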