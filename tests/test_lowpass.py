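import numpy as np
import pytest
from scipy import ndimage

from nssfuse.config import FusionConfig
from nssfuse.dictionary import Dictionary, extract_patches, learn_dictionary
from nssfuse.lowpass import (
    SparseCode,
    fuse_lowpass,
    max_l1_fuse,
    overlap_counts,
    reconstruct_fused_patch,
    somp_encode,
)


def _ortho_dict(rng, n=64):
    q = np.linalg.qr(rng.standard_normal((n, n)))[0]
    return Dictionary(atoms=q, cluster_offsets=np.zeros(1, dtype=int), patch_size=8)


class TestSompEncode:
    def test_single_atom_signal(self, rng):
        phi = _ortho_dict(rng)
        y = 3.0 * phi.atoms[:, 5]
        code_a, code_b = somp_encode(y, y, phi, eps=1e-10)
        for code in (code_a, code_b):
            assert code.support.tolist() == [5]
            assert code.coefficients[5] == pytest.approx(3.0)
            assert code.residual_norm < 1e-9

    def test_zero_signals_give_empty_support(self, rng):
        phi = _ortho_dict(rng)
        code_a, _ = somp_encode(np.zeros(64), np.zeros(64), phi, eps=1e-8)
        assert code_a.support.size == 0
        assert code_a.residual_norm == 0.0
        assert np.all(code_a.coefficients == 0.0)

    def test_exact_support_recovery_over_orthonormal_dictionary(self):
        hits = 0
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            phi = _ortho_dict(rng, 32)
            support = np.sort(rng.choice(32, size=3, replace=False))
            coefs_a = rng.uniform(0.25, 1.5, 3) * rng.choice([-1.0, 1.0], 3)
            coefs_b = rng.uniform(0.25, 1.5, 3) * rng.choice([-1.0, 1.0], 3)
            ya = phi.atoms[:, support] @ coefs_a
            yb = phi.atoms[:, support] @ coefs_b
            code_a, _ = somp_encode(ya, yb, phi, eps=1e-8)
            hits += set(code_a.support.tolist()) == set(support.tolist())
        assert hits == 100

    def test_shared_support(self, rng):
        phi = _ortho_dict(rng, 16)
        ya = phi.atoms[:, 2] * 1.0
        yb = phi.atoms[:, 9] * 1.0
        code_a, code_b = somp_encode(ya, yb, phi, eps=1e-8)
        assert code_a.support.tolist() == code_b.support.tolist()
        assert set(code_a.support.tolist()) == {2, 9}

    def test_errors(self, rng):
        phi = _ortho_dict(rng, 16)
        with pytest.raises(ValueError):
            somp_encode(np.zeros(8), np.zeros(8), phi, eps=1e-3)
        empty = Dictionary(atoms=np.empty((16, 0)), cluster_offsets=np.zeros(1, int))
        with pytest.raises(ValueError):
            somp_encode(np.zeros(16), np.zeros(16), empty, eps=1e-3)


class TestMaxL1:
    def _code(self, coeffs):
        c = np.asarray(coeffs, dtype=float)
        return SparseCode(coefficients=c, support=np.nonzero(c)[0], residual_norm=0.0)

    def test_larger_l1_wins(self):
        fused, winner = max_l1_fuse(self._code([0.5, 0.0]), self._code([0.3, 0.0]))
        assert winner == "A"
        assert fused.coefficients[0] == 0.5

    def test_tie_goes_to_b(self):
        a, b = self._code([0.4, -0.1]), self._code([0.0, 0.5])
        fused, winner = max_l1_fuse(a, b)
        assert winner == "B"
        assert fused is b

    def test_identical_codes_select_b_label(self):
        a = self._code([0.2, 0.7])
        fused, winner = max_l1_fuse(a, self._code([0.2, 0.7]))
        assert winner == "B"
        np.testing.assert_array_equal(fused.coefficients, a.coefficients)


class TestReconstructFusedPatch:
    def test_zero_code_gives_constant_patch(self, rng):
        phi = _ortho_dict(rng, 16)
        code = SparseCode(np.zeros(16), np.empty(0, int), 0.0)
        patch = reconstruct_fused_patch(code, "A", 0.7, 0.1, phi)
        np.testing.assert_allclose(patch, 0.7)

    def test_one_atom_code(self, rng):
        phi = _ortho_dict(rng, 16)
        coeffs = np.zeros(16)
        coeffs[4] = 2.5
        code = SparseCode(coeffs, np.array([4]), 0.0)
        patch = reconstruct_fused_patch(code, "B", 0.0, 0.3, phi)
        np.testing.assert_allclose(patch, 2.5 * phi.atoms[:, 4] + 0.3)

    def test_winner_mean_selection(self, rng):
        phi = _ortho_dict(rng, 16)
        code = SparseCode(np.zeros(16), np.empty(0, int), 0.0)
        assert reconstruct_fused_patch(code, "A", 0.6, 0.2, phi)[0] == 0.6
        assert reconstruct_fused_patch(code, "B", 0.6, 0.2, phi)[0] == 0.2
        with pytest.raises(ValueError):
            reconstruct_fused_patch(code, "C", 0.6, 0.2, phi)


class TestOverlapCounts:
    def test_corner_and_center_coverage(self):
        counts = overlap_counts((64, 64), 8, 1)
        assert counts[0, 0] == 1
        assert counts[32, 32] == 64
        assert counts[0, 32] == 8

    def test_matches_brute_force(self):
        shape, ps, stride = (13, 11), 4, 2
        brute = np.zeros(shape)
        for r in range(0, shape[0] - ps + 1, stride):
            for c in range(0, shape[1] - ps + 1, stride):
                brute[r : r + ps, c : c + ps] += 1
        np.testing.assert_array_equal(overlap_counts(shape, ps, stride), brute)


class TestFuseLowpass:
    def _smooth_band(self, rng, shape=(48, 48)):
        return ndimage.gaussian_filter(rng.random(shape), 2.0)

    def test_identity_fusion_close_to_input(self, rng):
        band = self._smooth_band(rng)
        patches = extract_patches(band, 8, 1)
        phi = learn_dictionary(patches, patches, n_clusters=4, seed=0)
        cfg = FusionConfig()
        fused = fuse_lowpass(band, band, phi, cfg)
        # residual of every patch is bounded by eps
        assert np.abs(fused - band).max() <= cfg.resolved_eps * 8

    def test_constant_bands_follow_tie_rule(self):
        c1, c2 = 0.8, 0.3
        band_a = np.full((24, 24), c1)
        band_b = np.full((24, 24), c2)
        phi = Dictionary(
            atoms=np.eye(64), cluster_offsets=np.zeros(1, int), patch_size=8
        )
        fused = fuse_lowpass(band_a, band_b, phi)
        # all codes are zero -> tie -> B wins everywhere -> constant c2
        np.testing.assert_allclose(fused, c2, atol=1e-12)

    def test_selection_never_blends(self, rng):
        band_a = self._smooth_band(rng, (32, 32))
        band_b = self._smooth_band(np.random.default_rng(99), (32, 32))
        pa = extract_patches(band_a, 8, 1)
        pb = extract_patches(band_b, 8, 1)
        phi = learn_dictionary(pa, pb, n_clusters=4, seed=0)
        from nssfuse.lowpass import _somp_batch

        ca, cb, *_ = _somp_batch(pa.vectors, pb.vectors, phi.atoms, 0.08, 16)
        l1a = np.abs(ca).sum(1)
        l1b = np.abs(cb).sum(1)
        fused_codes = np.where((l1a > l1b)[:, None], ca, cb)
        same_as_a = np.all(fused_codes == ca, axis=1)
        same_as_b = np.all(fused_codes == cb, axis=1)
        assert np.all(same_as_a | same_as_b)

    def test_deterministic(self, rng):
        band_a = self._smooth_band(rng, (32, 32))
        band_b = self._smooth_band(np.random.default_rng(5), (32, 32))
        pa = extract_patches(band_a, 8, 1)
        pb = extract_patches(band_b, 8, 1)
        phi = learn_dictionary(pa, pb, n_clusters=3, seed=1)
        f1 = fuse_lowpass(band_a, band_b, phi)
        f2 = fuse_lowpass(band_a, band_b, phi)
        np.testing.assert_array_equal(f1, f2)

    def test_shape_mismatch_rejected(self, rng):
        phi = Dictionary(np.eye(64), np.zeros(1, int), patch_size=8)
        with pytest.raises(ValueError):
            fuse_lowpass(np.zeros((16, 16)), np.zeros((16, 18)), phi)

    def test_bounded_by_input_range(self, rng):
        band_a = self._smooth_band(rng, (32, 32))
        band_b = self._smooth_band(np.random.default_rng(7), (32, 32))
        pa = extract_patches(band_a, 8, 1)
        pb = extract_patches(band_b, 8, 1)
        cfg = FusionConfig()
        phi = learn_dictionary(pa, pb, n_clusters=4, seed=0)
        fused = fuse_lowpass(band_a, band_b, phi, cfg)
        lo = min(band_a.min(), band_b.min()) - cfg.resolved_eps
        hi = max(band_a.max(), band_b.max()) + cfg.resolved_eps
        assert fused.min() >= lo and fused.max() <= hi
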