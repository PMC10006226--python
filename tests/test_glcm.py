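"""Co-occurrence matrices and the six texture features."""

import numpy as np
import pytest

from conftest import brute_force_features, brute_force_glcm, random_masked_patch
from nucleotexture.glcm import (
    GLCMatrix,
    GLCMFeatureConfig,
    compute_glcm,
    glcm_features,
    patch_glcm_features,
)
from nucleotexture.ingest import GrayPatch


def _patch(values, levels, mask=None):
    arr = np.asarray(values)
    if mask is None:
        mask = np.ones(arr.shape, bool)
    return GrayPatch(intensities=arr, mask=mask, levels=levels)


class TestComputeGlcm:
    def test_constant_patch_single_cell(self):
        m = compute_glcm(_patch(np.zeros((3, 3), int), 4), GLCMFeatureConfig(angles=(0,)))[0]
        assert m.p[0, 0] == 1.0
        assert m.p.sum() == 1.0

    def test_vertical_stripes_symmetric(self):
        m = compute_glcm(_patch([[0, 1], [0, 1]] * 2, 2), GLCMFeatureConfig(angles=(0,)))[0]
        assert m.p[0, 1] == 0.5 and m.p[1, 0] == 0.5
        assert m.p[0, 0] == 0.0 and m.p[1, 1] == 0.0

    def test_masked_pairs_excluded(self):
        # right column masked out: only the left two columns pair up
        img = np.array([[0, 1, 3]] * 4)
        mask = np.array([[True, True, False]] * 4)
        m = compute_glcm(_patch(img, 4, mask), GLCMFeatureConfig(angles=(0,)))[0]
        assert m.p[0, 1] == 0.5 and m.p[1, 0] == 0.5
        assert m.p[:, 3].sum() == 0 and m.p[3, :].sum() == 0

    def test_no_valid_pairs_names_offset(self):
        mask = np.zeros((3, 8), bool)
        mask[0] = True  # single row: no vertical pairs
        with pytest.raises(ValueError, match=r"dy=-1"):
            compute_glcm(_patch(np.ones((3, 8), int) * 2, 4, mask), GLCMFeatureConfig(angles=(90,)))

    def test_matches_brute_force_on_random_masked_patches(self, rng):
        from nucleotexture.glcm import angle_to_offset

        for _ in range(10):
            patch = random_masked_patch(rng)
            matrices = compute_glcm(patch, GLCMFeatureConfig())
            for m, angle in zip(matrices, (0, 45, 90, 135)):
                dy, dx = angle_to_offset(angle)
                oracle = brute_force_glcm(patch.intensities, patch.mask, dy, dx, patch.levels)
                assert np.abs(m.p - oracle).max() <= 1e-12


class TestFeatures:
    def test_single_entry_matrix(self):
        a = 3
        p = np.zeros((8, 8))
        p[a, a] = 1.0
        m = GLCMatrix(p=p, levels=8, offsets=((0, 1),), symmetric=True, pair_count=10)
        f = glcm_features(m)
        assert f.asm == 1.0 and f.idm == 1.0 and f.con == 0.0
        assert f.sa == 2 * a and f.svar == 0.0
        assert np.isnan(f.cor)

    def test_checkerboard_closed_form(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        m = compute_glcm(_patch(board, 2), GLCMFeatureConfig(angles=(0,)))[0]
        f = glcm_features(m)
        assert f.asm == pytest.approx(0.5)
        assert f.idm == pytest.approx(0.5)
        assert f.con == pytest.approx(1.0)
        assert f.cor == pytest.approx(-1.0)
        assert f.sa == pytest.approx(1.0)
        assert f.svar == pytest.approx(0.0)

    def test_contrast_exponents(self):
        # p(0,2) = p(2,0) = 0.5 → CON = (0−2)^k summed with weight p^n
        p = np.zeros((3, 3))
        p[0, 2] = p[2, 0] = 0.5
        m = GLCMatrix(p=p, levels=3, offsets=((0, 1),), symmetric=True, pair_count=2)
        f_k4 = glcm_features(m, GLCMFeatureConfig(contrast_k=4, contrast_n=1))
        assert f_k4.con == pytest.approx(16.0)
        f_n2 = glcm_features(m, GLCMFeatureConfig(contrast_k=2, contrast_n=2))
        assert f_n2.con == pytest.approx(4 * 0.25 + 4 * 0.25)

    def test_feature_bounds_and_ranges(self, rng):
        for _ in range(20):
            patch = random_masked_patch(rng)
            f = patch_glcm_features(patch)
            g = patch.levels
            assert 0 < f.asm <= 1 and 0 < f.idm <= 1
            assert f.con >= 0 and f.svar >= 0
            assert 0 <= f.sa <= 2 * (g - 1)
            if not np.isnan(f.cor):
                assert -1 - 1e-12 <= f.cor <= 1 + 1e-12

    def test_transpose_invariance(self, rng):
        patch = random_masked_patch(rng)
        m = compute_glcm(patch, GLCMFeatureConfig(angles=(45,)))[0]
        f = glcm_features(m)
        mt = GLCMatrix(p=m.p.T, levels=m.levels, offsets=m.offsets,
                       symmetric=m.symmetric, pair_count=m.pair_count)
        ft = glcm_features(mt)
        for a, b in zip(f.as_dict().values(), ft.as_dict().values()):
            assert a == pytest.approx(b, abs=1e-12)

    def test_pair_order_irrelevant(self, rng):
        """Features depend only on the pair multiset, not accumulation order."""
        patch = random_masked_patch(rng)
        m = compute_glcm(patch, GLCMFeatureConfig(angles=(0,)))[0]
        pairs = []
        g = patch.levels
        counts = (m.p * m.pair_count).round().astype(int)
        for i in range(g):
            for j in range(g):
                pairs += [(i, j)] * counts[i, j]
        perm = rng.permutation(len(pairs))
        shuffled = np.zeros((g, g))
        for k in perm:
            i, j = pairs[k]
            shuffled[i, j] += 1
        m2 = GLCMatrix(p=shuffled / shuffled.sum(), levels=g, offsets=m.offsets,
                       symmetric=True, pair_count=m.pair_count)
        for a, b in zip(glcm_features(m).as_dict().values(),
                        glcm_features(m2).as_dict().values()):
            assert a == pytest.approx(b, abs=1e-9)

    def test_direction_averaging_is_feature_mean(self, rng):
        patch = random_masked_patch(rng)
        cfg = GLCMFeatureConfig()
        matrices = compute_glcm(patch, cfg)
        avg = glcm_features(matrices, cfg)
        per = [glcm_features(m, GLCMFeatureConfig(angles=(a,))) for m, a in
               zip(matrices, cfg.angles)]
        assert avg.asm == pytest.approx(np.mean([f.asm for f in per]))
        assert avg.con == pytest.approx(np.mean([f.con for f in per]))

    def test_skimage_cross_check_full_mask(self, rng):
        """Independent library oracle on unmasked patches (skimage mirrors
        the diagonal angle convention; symmetric matrices make 45°/135°
        swap irrelevant for the set of matrices)."""
        skimage = pytest.importorskip("skimage.feature")
        img = rng.integers(0, 8, (12, 12))
        ours = compute_glcm(_patch(img, 8), GLCMFeatureConfig())
        sk = skimage.graycomatrix(
            img.astype(np.uint8), [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=8, symmetric=True, normed=True,
        )
        for m, k in zip(ours, (0, 3, 2, 1)):  # our 45° == skimage 135°
            np.testing.assert_allclose(m.p, sk[:, :, 0, k], atol=1e-12)
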