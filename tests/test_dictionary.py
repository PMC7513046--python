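import numpy as np
import pytest

from nssfuse.dictionary import (
    build_dictionary,
    extract_patches,
    joint_cluster,
    learn_dictionary,
    load_dictionary,
    pca_subdictionary,
    save_dictionary,
)


class TestExtractPatches:
    def test_patch_count_formula(self, rng):
        band = rng.random((16, 16))
        ps = extract_patches(band, 8, 1)
        assert ps.n_patches == 81  # (16-8+1)^2
        band = rng.random((20, 31))
        ps = extract_patches(band, 8, 3)
        assert ps.n_patches == ((20 - 8) // 3 + 1) * ((31 - 8) // 3 + 1)

    def test_columns_are_zero_mean_with_means_stored(self, rng):
        band = rng.random((16, 16))
        ps = extract_patches(band, 8, 2)
        assert np.abs(ps.vectors.mean(axis=0)).max() < 1e-12
        first = band[:8, :8]
        assert ps.means[0] == pytest.approx(first.mean())
        # column-major vectorisation within the patch
        np.testing.assert_allclose(
            ps.vectors[:, 0] + ps.means[0], first.T.ravel()
        )

    def test_constant_band(self):
        ps = extract_patches(np.full((12, 12), 0.4), 8, 1)
        assert np.abs(ps.vectors).max() < 1e-14
        np.testing.assert_allclose(ps.means, 0.4, atol=1e-14)

    def test_patch_larger_than_band_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((6, 6)), 8, 1)


class TestJointCluster:
    def _populations(self, rng):
        flat = rng.normal(0.0, 0.01, size=(16, 40))
        stripes = np.sign(np.sin(np.arange(16) * 2.5))[:, None] + rng.normal(
            0.0, 0.01, size=(16, 40)
        )
        flat -= flat.mean(axis=0)
        stripes -= stripes.mean(axis=0)
        return flat, stripes

    def test_single_cluster(self, rng):
        band = rng.random((16, 16))
        ps = extract_patches(band, 4, 4)
        labels = joint_cluster(ps, ps, k=1, seed=0)
        assert np.all(labels == 0)
        assert labels.size == 2 * ps.n_patches

    def test_separable_populations_split_perfectly(self, rng):
        flat, stripes = self._populations(rng)
        ps_a = extract_patches(np.zeros((4, 4)), 4, 1)
        ps_a.vectors, ps_a.means = flat, np.zeros(flat.shape[1])
        ps_b = extract_patches(np.zeros((4, 4)), 4, 1)
        ps_b.vectors, ps_b.means = stripes, np.zeros(stripes.shape[1])
        labels = joint_cluster(ps_a, ps_b, k=2, seed=0)
        la, lb = labels[:40], labels[40:]
        assert len(set(la.tolist())) == 1 and len(set(lb.tolist())) == 1
        assert la[0] != lb[0]

    def test_deterministic_for_fixed_seed(self, rng):
        band_a, band_b = rng.random((24, 24)), rng.random((24, 24))
        ps_a = extract_patches(band_a, 8, 4)
        ps_b = extract_patches(band_b, 8, 4)
        l1 = joint_cluster(ps_a, ps_b, k=4, seed=7)
        l2 = joint_cluster(ps_a, ps_b, k=4, seed=7)
        assert np.array_equal(l1, l2)

    def test_k_exceeding_patch_count_rejected(self, rng):
        ps = extract_patches(rng.random((8, 8)), 8, 1)  # single patch
        with pytest.raises(ValueError):
            joint_cluster(ps, ps, k=5, seed=0)


class TestPcaSubdictionary:
    def _cluster_with_spectrum(self, rng, variances, n=2000):
        dim = len(variances)
        basis = np.linalg.qr(rng.standard_normal((dim, dim)))[0]
        coords = rng.standard_normal((dim, n)) * np.sqrt(np.array(variances))[:, None]
        return basis @ coords, basis

    def test_cumulative_mass_rule(self, rng):
        # exact covariance spectrum proportional to [0.80, 0.15, 0.05]
        basis = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        x = basis @ np.diag(np.sqrt([0.80, 0.15, 0.05]))
        sub = pca_subdictionary(x, delta=0.95)
        assert sub.n_atoms == 2

    def test_full_retention_keeps_rank(self, rng):
        x, _ = self._cluster_with_spectrum(rng, [1.0, 0.5, 0.2, 0.1])
        sub = pca_subdictionary(x, delta=1.0)
        assert sub.n_atoms == 4

    def test_identical_vectors_give_single_atom(self):
        v = np.array([3.0, 0.0, -4.0])
        x = np.tile(v[:, None], (1, 10))
        sub = pca_subdictionary(x, delta=0.95)
        assert sub.n_atoms == 1
        np.testing.assert_allclose(np.abs(sub.atoms[:, 0]), np.abs(v) / 5.0, atol=1e-12)

    def test_zero_cluster_is_degenerate(self):
        sub = pca_subdictionary(np.zeros((4, 7)), delta=0.95)
        assert sub.degenerate and sub.n_atoms == 0

    def test_atoms_orthonormal_eigenvalues_descending(self, rng):
        x, _ = self._cluster_with_spectrum(rng, [2.0, 1.0, 0.5, 0.2, 0.1])
        sub = pca_subdictionary(x, delta=0.99)
        gram = sub.atoms.T @ sub.atoms
        np.testing.assert_allclose(gram, np.eye(sub.n_atoms), atol=1e-10)
        assert np.all(np.diff(sub.eigenvalues) <= 1e-12)


class TestBuildDictionary:
    def test_concatenation_and_offsets(self, rng):
        a = np.linalg.qr(rng.standard_normal((6, 6)))[0]
        from nssfuse.dictionary import SubDictionary

        s1 = SubDictionary(atoms=a[:, :2], eigenvalues=np.array([2.0, 1.0]), cluster_id=0)
        s2 = SubDictionary(atoms=a[:, 2:5], eigenvalues=np.array([3.0, 2.0, 1.0]), cluster_id=1)
        phi = build_dictionary([s1, s2])
        assert phi.n_atoms == 5
        assert phi.cluster_offsets.tolist() == [0, 2]
        np.testing.assert_allclose(
            np.linalg.norm(phi.atoms, axis=0), np.ones(5), atol=1e-10
        )

    def test_all_empty_rejected(self):
        from nssfuse.dictionary import SubDictionary

        empty = SubDictionary(
            atoms=np.empty((4, 0)), eigenvalues=np.empty(0), cluster_id=0, degenerate=True
        )
        with pytest.raises(ValueError):
            build_dictionary([empty])


class TestLearnDictionary:
    def test_reconstruction_adequacy(self, rng):
        from scipy import ndimage

        band_a = ndimage.gaussian_filter(rng.random((48, 48)), 1.5)
        band_b = ndimage.gaussian_filter(rng.random((48, 48)), 1.5)
        pa = extract_patches(band_a, 8, 2)
        pb = extract_patches(band_b, 8, 2)
        delta = 0.95
        phi = learn_dictionary(pa, pb, n_clusters=4, delta=delta, seed=0)
        pooled = np.hstack([pa.vectors, pb.vectors])
        proj = phi.atoms @ np.linalg.lstsq(phi.atoms, pooled, rcond=None)[0]
        residual = ((pooled - proj) ** 2).sum()
        total = (pooled**2).sum()
        assert residual <= (1.0 - delta) * total + 1e-9

    def test_compact_and_deterministic(self, rng):
        band = rng.random((40, 40))
        pa = extract_patches(band, 8, 2)
        phi1 = learn_dictionary(pa, pa, n_clusters=6, seed=3)
        phi2 = learn_dictionary(pa, pa, n_clusters=6, seed=3)
        assert np.array_equal(phi1.atoms, phi2.atoms)
        assert phi1.n_atoms < 2 * pa.n_patches  # compact vs the patch pool
        assert phi1.n_atoms <= 64 * 6

    def test_save_load_round_trip(self, rng, tmp_path):
        pa = extract_patches(rng.random((24, 24)), 8, 4)
        phi = learn_dictionary(pa, pa, n_clusters=2, seed=0)
        path = tmp_path / "dict.txt"
        save_dictionary(phi, path)
        loaded = load_dictionary(path)
        np.testing.assert_allclose(loaded.atoms, phi.atoms, atol=1e-12)
        assert loaded.patch_size == phi.patch_size
        assert loaded.cluster_offsets.tolist() == phi.cluster_offsets.tolist()
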