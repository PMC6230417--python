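import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepavol.errors import ContractError
from hepavol.io import BinaryMask, CTVolume
from hepavol.texture import (
    FEATURE_NAMES,
    UNIT_OFFSETS_13,
    feature_map,
    feature_vector,
    glcm_3d,
    haralick_features,
    quantize,
    statistical_features,
)


def brute_force_glcm(patch, offsets, symmetric, levels):
    """Independent double-loop pair enumeration."""
    counts = np.zeros((levels, levels))
    shape = patch.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                for oz, oy, ox in offsets:
                    z2, y2, x2 = z + oz, y + oy, x + ox
                    if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]:
                        counts[patch[z, y, x], patch[z2, y2, x2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def naive_haralick(p):
    """Plain-sum reference for the five GLCM features."""
    L = p.shape[0]
    contrast = sum(p[i, j] * (i - j) ** 2 for i in range(L) for j in range(L))
    energy = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    homog = sum(p[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L))
    entropy = -sum(
        p[i, j] * np.log2(p[i, j]) for i in range(L) for j in range(L) if p[i, j] > 0
    )
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mi = sum(i * pi[i] for i in range(L))
    mj = sum(j * pj[j] for j in range(L))
    si = np.sqrt(sum((i - mi) ** 2 * pi[i] for i in range(L)))
    sj = np.sqrt(sum((j - mj) ** 2 * pj[j] for j in range(L)))
    if si * sj > 0:
        corr = sum(
            (i - mi) * (j - mj) * p[i, j] for i in range(L) for j in range(L)
        ) / (si * sj)
    else:
        corr = 0.0
    return dict(contrast=contrast, correlation=corr, entropy=entropy, energy=energy,
                homogeneity=homog)


class TestQuantize:
    def test_boundary_bins(self):
        assert quantize(np.array([[[-100.0]]]), 32, (-100, 300))[0, 0, 0] == 0
        assert quantize(np.array([[[300.0]]]), 32, (-100, 300))[0, 0, 0] == 31
        assert quantize(np.array([[[999.0]]]), 32, (-100, 300))[0, 0, 0] == 31

    def test_midpoint_example(self):
        assert quantize(np.array([[[100.0]]]), 32, (-100, 300))[0, 0, 0] == 16

    def test_monotone_in_hu(self, rng):
        hu = np.sort(rng.uniform(-200, 400, 100)).reshape(1, 1, 100)
        q = quantize(hu)
        assert np.all(np.diff(q.ravel()) >= 0)

    def test_constant_volume_constant_levels(self):
        q = quantize(np.full((3, 3, 3), 42.0))
        assert np.unique(q).size == 1


class TestGLCM:
    def test_constant_patch_point_mass(self):
        g = glcm_3d(np.zeros((4, 4, 4), dtype=int), levels=8)
        assert g.probabilities[0, 0] == pytest.approx(1.0)
        assert g.probabilities.sum() == pytest.approx(1.0)

    def test_alternating_strip(self):
        strip = np.array([[[0, 1, 0, 1, 0, 1]]])
        g = glcm_3d(strip, offsets=np.array([[0, 0, 1]]), symmetric=True, levels=2)
        assert g.probabilities[0, 1] == pytest.approx(0.5)
        assert g.probabilities[1, 0] == pytest.approx(0.5)
        assert g.probabilities[0, 0] == 0 and g.probabilities[1, 1] == 0

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force(self, seed, symmetric):
        r = np.random.default_rng(seed)
        patch = r.integers(0, 5, size=(4, 5, 3))
        g = glcm_3d(patch, symmetric=symmetric, levels=5)
        expected = brute_force_glcm(patch, UNIT_OFFSETS_13, symmetric, 5)
        np.testing.assert_allclose(g.probabilities, expected, atol=1e-15)

    def test_zero_offset_rejected(self):
        with pytest.raises(ContractError):
            glcm_3d(np.zeros((3, 3, 3), int), offsets=np.array([[0, 0, 0]]))

    def test_oversized_offset_rejected(self):
        with pytest.raises(ContractError):
            glcm_3d(np.zeros((3, 3, 3), int), offsets=np.array([[0, 0, 5]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_normalization_and_symmetry_property(self, seed):
        r = np.random.default_rng(seed)
        patch = r.integers(0, 6, size=tuple(r.integers(2, 6, 3)))
        g = glcm_3d(patch, symmetric=True, levels=6)
        assert g.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(g.probabilities >= 0)
        np.testing.assert_allclose(g.probabilities, g.probabilities.T, atol=1e-15)

    def test_reversed_offsets_equal_symmetric(self, rng):
        patch = rng.integers(0, 4, size=(4, 4, 4))
        sym = glcm_3d(patch, symmetric=True, levels=4)
        both = np.vstack([UNIT_OFFSETS_13, -UNIT_OFFSETS_13])
        asym = glcm_3d(patch, offsets=both, symmetric=False, levels=4)
        np.testing.assert_allclose(sym.probabilities, asym.probabilities, atol=1e-15)

    def test_offset_order_irrelevant(self, rng):
        patch = rng.integers(0, 4, size=(5, 4, 4))
        a = glcm_3d(patch, offsets=UNIT_OFFSETS_13, levels=4)
        b = glcm_3d(patch, offsets=UNIT_OFFSETS_13[::-1].copy(), levels=4)
        np.testing.assert_allclose(a.probabilities, b.probabilities, atol=1e-15)


class TestHaralick:
    def test_point_mass_degenerate(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        g = glcm_3d(np.full((3, 3, 3), 2), levels=4)
        f = haralick_features(g)
        assert f["entropy"] == 0
        assert f["contrast"] == 0
        assert f["energy"] == pytest.approx(1.0)
        assert f["correlation"] == 0  # zero-variance convention

    def test_checkerboard_closed_form(self):
        from hepavol.texture import GLCM

        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        g = GLCM(p, levels=2, offsets=np.array([[0, 0, 1]]), symmetric=True)
        f = haralick_features(g)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)
        assert f["entropy"] == pytest.approx(1.0)  # one bit

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_sums(self, seed):
        r = np.random.default_rng(seed)
        patch = r.integers(0, 6, size=(4, 4, 4))
        g = glcm_3d(patch, levels=6)
        f = haralick_features(g)
        ref = naive_haralick(g.probabilities)
        for k, v in ref.items():
            assert f[k] == pytest.approx(v, abs=1e-12), k


class TestStatisticalFeatures:
    def test_constant_patch(self):
        f = statistical_features(np.full((3, 3, 3), 5.0))
        assert f == {"mean": 5.0, "std": 0.0, "skewness": 0.0, "kurtosis": 0.0,
                     "median": 5.0}

    def test_against_scipy(self, rng):
        from scipy import stats

        x = rng.normal(0, 1, 500)
        f = statistical_features(x)
        assert f["skewness"] == pytest.approx(stats.skew(x), abs=1e-12)
        assert f["kurtosis"] == pytest.approx(stats.kurtosis(x), abs=1e-12)
        assert f["std"] == pytest.approx(np.std(x), abs=1e-12)


class TestFeatureMap:
    def test_constant_volume(self):
        vol = CTVolume(np.full((8, 8, 8), 70.0), (1, 1, 1))
        roi = BinaryMask(np.ones((8, 8, 8), bool), (1, 1, 1))
        coords, feats = feature_map(vol, roi, window=5)
        assert len(coords) == 512
        names = dict(zip(FEATURE_NAMES, feats.T))
        assert np.all(names["mean"] == 70.0)
        assert np.all(names["std"] == 0.0)
        assert np.all(names["energy"] == 1.0)

    def test_corner_voxel_clipped_without_error(self, rng):
        vol = CTVolume(rng.normal(0, 50, (10, 10, 10)), (1, 1, 1))
        roi = np.zeros((10, 10, 10), bool)
        roi[0, 0, 0] = True
        coords, feats = feature_map(vol, BinaryMask(roi, (1, 1, 1)), window=11)
        assert np.all(np.isfinite(feats))
        # clipped neighborhood is the 6x6x6 corner block
        expected = feature_vector(vol.data[:6, :6, :6])
        np.testing.assert_allclose(feats[0], expected, rtol=1e-9, atol=1e-9)

    def test_sampled_voxels_match_naive_oracle(self, rng):
        vol = CTVolume(rng.normal(80, 30, (32, 32, 32)), (1.5, 1.5, 1.5))
        roi = np.zeros((32, 32, 32), bool)
        pts = rng.integers(0, 32, size=(50, 3))
        roi[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        coords, feats = feature_map(vol, BinaryMask(roi, vol.spacing), window=11)
        h = 5
        for c, f in zip(coords, feats):
            z, y, x = c
            patch = vol.data[
                max(0, z - h) : z + h + 1,
                max(0, y - h) : y + h + 1,
                max(0, x - h) : x + h + 1,
            ]
            np.testing.assert_allclose(f, feature_vector(patch), rtol=1e-9, atol=1e-9)

    def test_even_window_rejected(self, rng):
        vol = CTVolume(rng.normal(0, 1, (5, 5, 5)), (1, 1, 1))
        roi = BinaryMask(np.ones((5, 5, 5), bool), (1, 1, 1))
        with pytest.raises(ContractError):
            feature_map(vol, roi, window=10)

    def test_hu_shift_invariance(self, rng):
        """Adding a constant shifts the mean/median; GLCM features follow the
        window, so shifting both HU and the window leaves them unchanged."""
        patch = rng.normal(80, 30, (9, 9, 9))
        base = feature_vector(patch, hu_window=(-100, 300))
        shifted = feature_vector(patch + 50, hu_window=(-50, 350))
        np.testing.assert_allclose(shifted[:2], base[:2] + [50, 0], rtol=1e-9)
        np.testing.assert_allclose(shifted[4], base[4] + 50, rtol=1e-9)
        np.testing.assert_allclose(shifted[5:], base[5:], rtol=1e-9)
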