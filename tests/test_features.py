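"""The 60-feature panel: hand-derived oracles, brute-force matrix checks,
and invariances (permutation, translation, monotone intensity shift)."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tsradiomics import (
    FeatureConfig,
    ImageVolume,
    LesionRecord,
    LesionType,
    ROIMask,
    extract_all,
    feature_categories,
    feature_names,
    glcm_features,
    glcm_matrix,
    glcm_offsets,
    histogram_features,
    iszm,
    iszm_features,
    partition_features,
    partition_roi,
    shape_features,
)
from tsradiomics.features import EmptyGLCMError, GLCMatrix
from tests.conftest import make_lesion, make_sphere_mask, random_phantom


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

class TestHistogramFeatures:
    def test_three_point_symmetric_set(self):
        f = histogram_features([1, 2, 3])
        assert f["mean"] == pytest.approx(2)
        assert f["median"] == pytest.approx(2)
        assert f["range"] == pytest.approx(2)
        assert f["energy"] == pytest.approx(14)
        assert f["rms"] == pytest.approx(math.sqrt(14 / 3))
        assert f["skewness"] == pytest.approx(0, abs=1e-12)
        # m4/m2^2 = (2/3)/(4/9) by hand
        assert f["kurtosis"] == pytest.approx(1.5)

    def test_constant_input_returns_17_defined_features(self):
        f = histogram_features([5, 5, 5, 5])
        assert f["sd"] == 0
        assert f["mean"] == 5
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])
        assert set(f.missing) == {"skewness", "kurtosis"}
        defined = [k for k, v in f.items() if not np.isnan(v)]
        assert len(defined) == 17

    def test_entropy_of_two_equal_masses_is_one_bit(self):
        f = histogram_features([0.0] * 10 + [100.0] * 10)
        assert f["entropy"] == pytest.approx(1.0)

    def test_upp_counts_only_positive_bins(self):
        # all mass at -50 and +50: only the +50 bin's p^2 = 0.25 counts
        f = histogram_features([-50.0] * 10 + [50.0] * 10)
        assert f["upp"] == pytest.approx(0.25)

    @given(st.lists(st.floats(-1000, 1000), min_size=2, max_size=60), st.floats(-200, 200))
    def test_shift_moves_location_only(self, xs, c):
        base = histogram_features(xs)
        shifted = histogram_features([x + c for x in xs])
        assert shifted["mean"] == pytest.approx(base["mean"] + c, abs=1e-6)
        assert shifted["median"] == pytest.approx(base["median"] + c, abs=1e-6)
        assert shifted["p25"] == pytest.approx(base["p25"] + c, abs=1e-6)
        assert shifted["sd"] == pytest.approx(base["sd"], abs=1e-6)
        assert shifted["entropy"] == pytest.approx(base["entropy"], abs=1e-9)
        if not np.isnan(base["skewness"]):
            assert shifted["skewness"] == pytest.approx(base["skewness"], abs=1e-5)

    @given(st.permutations(list(range(12))))
    def test_permutation_invariance(self, perm):
        ref = histogram_features(list(range(12)))
        assert histogram_features(perm) == ref


# ---------------------------------------------------------------------------
# partition (outer/delta) features
# ---------------------------------------------------------------------------

class TestPartitionFeatures:
    def test_constant_lesion_all_defined_deltas_zero(self):
        mask = make_sphere_mask(7)
        image = ImageVolume(np.full(mask.voxels.shape, 40.0), mask.spacing)
        part = partition_roi(mask)
        f = partition_features(image, part)
        for k in ("mean", "median", "minimum", "maximum", "energy", "entropy", "sd"):
            if f"{k}_delta" not in f.missing:
                # energy differs between unequal-size sub-ROIs; others are 0
                if k != "energy":
                    assert f[f"{k}_delta"] == pytest.approx(0, abs=1e-9)
        assert "skewness_delta" in f.missing  # constant sub-ROIs

    def test_two_valued_core_rim_sphere(self):
        # core HU 60 on the inner 2/3 volume, rim HU 20 on the outer 1/3
        mask = make_sphere_mask(9)
        part = partition_roi(mask)
        vox = np.zeros(mask.voxels.shape)
        vox[part.inner.voxels] = 60.0
        vox[part.outer.voxels] = 20.0
        f = partition_features(ImageVolume(vox, mask.spacing), part)
        assert f["mean_outer"] == pytest.approx(20.0)
        assert f["mean_delta"] == pytest.approx(40.0)
        assert f["maximum_delta"] == pytest.approx(40.0)
        assert f["minimum_delta"] == pytest.approx(40.0)

    def test_emits_the_table_names(self):
        names = feature_names()
        assert "maximum_delta" in names and "mean_outer" in names
        assert "median_outer" in names and "maximum_outer" in names


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

class TestShapeFeatures:
    def test_digital_sphere_volume_matches_analytic(self):
        mask = make_sphere_mask(10)
        image = ImageVolume(np.zeros(mask.voxels.shape), mask.spacing)
        f = shape_features(mask, image)
        assert f["volume"] == pytest.approx(4 / 3 * math.pi * 1000, rel=0.02)
        # voxel-count oracle is exact by definition
        assert f["volume"] == mask.n_foreground * 1.0

    def test_sphere_is_convex_round_and_isotropic(self):
        mask = make_sphere_mask(10)
        image = ImageVolume(np.zeros(mask.voxels.shape), mask.spacing)
        f = shape_features(mask, image)
        assert 0.95 <= f["convexity"] <= 1.0
        assert f["elongation"] == pytest.approx(1.0, abs=0.02)
        assert 0.9 <= f["sphericity"] <= 1.05
        assert f["max_3d_diameter"] == pytest.approx(2 * 10, rel=0.1)

    def test_density_and_mass_closed_form(self):
        mask = make_sphere_mask(8)
        image = ImageVolume(np.zeros(mask.voxels.shape), mask.spacing)
        f = shape_features(mask, image)
        assert f["density"] == pytest.approx(1000.0)
        assert f["mass"] == pytest.approx(1000.0 * f["volume"])

    def test_anisotropic_spacing_scales_volume(self):
        mask_iso = make_sphere_mask(8)
        mask = ROIMask(mask_iso.voxels, (0.5, 0.5, 2.0))
        image = ImageVolume(np.zeros(mask.voxels.shape), mask.spacing)
        f = shape_features(mask, image)
        assert f["volume"] == pytest.approx(mask.n_foreground * 0.5 * 0.5 * 2.0)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def brute_force_glcm(image, mask, levels):
    """Oracle: nested-loop co-occurrence enumeration, symmetrized,
    normalized per direction, averaged over directions with >= 1 pair."""
    vox, fg = image.voxels, mask.voxels
    vals = vox[fg]
    lo, hi = vals.min(), vals.max()
    disc = np.zeros(vox.shape, dtype=int)
    if hi > lo:
        disc = np.clip(np.floor((vox - lo) / (hi - lo) * levels), 0, levels - 1).astype(int)
    mats = []
    for off in glcm_offsets():
        c = np.zeros((levels, levels))
        nx, ny, nz = vox.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    i2, j2, k2 = i + off[0], j + off[1], k + off[2]
                    if not (0 <= i2 < nx and 0 <= j2 < ny and 0 <= k2 < nz):
                        continue
                    if fg[i, j, k] and fg[i2, j2, k2]:
                        a, b = disc[i, j, k], disc[i2, j2, k2]
                        c[a, b] += 1
                        c[b, a] += 1
        if c.sum() > 0:
            mats.append(c / c.sum())
    return sum(mats) / len(mats)


class TestGLCM:
    def test_two_pair_line_example(self):
        # 1x1x3 ROI [10, 10, 20]: only offset (0,0,1) pairs; hand-enumerated
        image = ImageVolume(np.array([[[10.0, 10.0, 20.0]]]), (1, 1, 1))
        mask = ROIMask(np.ones((1, 1, 3)), (1, 1, 1))
        G = glcm_matrix(image, mask, levels=256)
        lo, hi = 0, 255
        assert G.matrix[lo, lo] == pytest.approx(0.5)
        assert G.matrix[lo, hi] == pytest.approx(0.25)
        assert G.matrix[hi, lo] == pytest.approx(0.25)

    def test_constant_roi_single_entry(self):
        image = ImageVolume(np.full((4, 4, 4), 7.0), (1, 1, 1))
        mask = ROIMask(np.ones((4, 4, 4)), (1, 1, 1))
        G = glcm_matrix(image, mask)
        assert G.matrix[0, 0] == pytest.approx(1.0)
        assert G.matrix.sum() == pytest.approx(1.0)

    def test_thirteen_directions_and_256_levels(self):
        offs = glcm_offsets()
        assert len(offs) == 13
        # modulo sign, the 13 offsets cover the full 26-neighborhood
        assert len({o for pair in ((o, tuple(-x for x in o)) for o in offs) for o in pair}) == 26
        image, mask = random_phantom(seed=5)
        G = glcm_matrix(image, mask)
        assert G.matrix.shape == (256, 256)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        image, mask = random_phantom(shape=(8, 8, 8), seed=seed)
        G = glcm_matrix(image, mask, levels=16)
        oracle = brute_force_glcm(image, mask, levels=16)
        np.testing.assert_allclose(G.matrix, oracle, atol=1e-12)

    def test_unit_sum_and_symmetry_on_random_phantom(self):
        image, mask = random_phantom(shape=(10, 10, 10), seed=9)
        G = glcm_matrix(image, mask)
        assert G.matrix.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(G.matrix, G.matrix.T, atol=1e-15)

    def test_isolated_voxel_raises_empty_glcm(self):
        vox = np.zeros((5, 5, 5))
        fg = np.zeros((5, 5, 5), bool)
        fg[2, 2, 2] = True
        with pytest.raises(EmptyGLCMError):
            glcm_matrix(ImageVolume(vox, (1, 1, 1)), ROIMask(fg, (1, 1, 1)))


class TestGLCMFeatures:
    def test_deterministic_texture_single_entry(self):
        m = np.zeros((4, 4))
        m[0, 0] = 1.0
        f = glcm_features(GLCMatrix(m, 4))
        assert f["glcm_entropy"] == 0
        assert f["glcm_dissimilarity"] == 0
        assert f["glcm_energy"] == 1
        assert f["glcm_homogeneity"] == 1
        assert "glcm_correlation" in f.missing

    def test_uniform_matrix_maximal_entropy(self):
        L = 8
        f = glcm_features(GLCMatrix(np.full((L, L), 1 / L**2), L))
        assert f["glcm_entropy"] == pytest.approx(2 * math.log2(L))

    def test_two_level_matrix_hand_sums(self):
        m = np.array([[0.5, 0.25], [0.25, 0.0]])
        f = glcm_features(GLCMatrix(m, 2))
        assert f["glcm_dissimilarity"] == pytest.approx(0.5)
        assert f["glcm_entropy"] == pytest.approx(1.5)
        # hand sums with 1-based labels
        assert f["glcm_autocorrelation"] == pytest.approx(0.5 * 1 + 0.25 * 2 * 2)
        assert f["glcm_sum_average"] == pytest.approx(0.5 * 2 + 0.5 * 3)


# ---------------------------------------------------------------------------
# ISZ
# ---------------------------------------------------------------------------

def brute_force_zones(image, mask, levels):
    """Oracle: BFS flood fill of 26-connected equal-level zones."""
    vox, fg = image.voxels, mask.voxels
    vals = vox[fg]
    lo, hi = vals.min(), vals.max()
    disc = np.zeros(vox.shape, dtype=int)
    if hi > lo:
        disc = np.clip(np.floor((vox - lo) / (hi - lo) * levels), 0, levels - 1).astype(int)
    seen = np.zeros(vox.shape, bool)
    zones = []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(fg)):
        if seen[start]:
            continue
        level = disc[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[d] < vox.shape[d] for d in range(3)):
                    if fg[w] and not seen[w] and disc[w] == level:
                        seen[w] = True
                        stack.append(w)
        zones.append((level, size))
    return zones


class TestISZ:
    def test_constant_roi_single_zone(self):
        image = ImageVolume(np.full((4, 4, 4), 3.0), (1, 1, 1))
        mask = ROIMask(np.ones((4, 4, 4)), (1, 1, 1))
        f = iszm_features(image, mask)
        assert f["intensity_variability"] == 1
        assert f["size_zone_variability"] == 1

    def test_two_zones_distinct_levels(self):
        # zones of sizes 3 and 5 at two levels -> IV = SZV = (1+1)/2 = 1
        vox = np.zeros((1, 1, 8))
        vox[0, 0, :3] = 0.0
        vox[0, 0, 3:] = 100.0
        image = ImageVolume(vox, (1, 1, 1))
        mask = ROIMask(np.ones((1, 1, 8)), (1, 1, 1))
        m = iszm(image, mask, levels=32)
        assert m.n_zones == 2
        f = iszm_features(image, mask)
        assert f["intensity_variability"] == pytest.approx(1.0)
        assert f["size_zone_variability"] == pytest.approx(1.0)

    def test_three_zones_hand_counts(self):
        # levels (g1, g1, g2), sizes (2, 2, 7): IV = (4+1)/3, SZV = (4+1)/3
        vox = np.zeros((1, 1, 11))
        vox[0, 0, :2] = 0.0        # zone 1: g1, size 2
        vox[0, 0, 2:9] = 100.0     # zone 2: g2, size 7
        vox[0, 0, 9:] = 0.0        # zone 3: g1, size 2
        image = ImageVolume(vox, (1, 1, 1))
        mask = ROIMask(np.ones((1, 1, 11)), (1, 1, 1))
        f = iszm_features(image, mask)
        assert f["intensity_variability"] == pytest.approx(5 / 3)
        assert f["size_zone_variability"] == pytest.approx(5 / 3)

    def test_single_voxel_roi(self):
        vox = np.zeros((3, 3, 3))
        fg = np.zeros((3, 3, 3), bool)
        fg[1, 1, 1] = True
        f = iszm_features(ImageVolume(vox, (1, 1, 1)), ROIMask(fg, (1, 1, 1)))
        assert f["intensity_variability"] == 1
        assert f["size_zone_variability"] == 1

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_brute_force_flood_fill(self, seed):
        image, mask = random_phantom(shape=(8, 8, 8), seed=seed)
        m = iszm(image, mask, levels=8)
        oracle = brute_force_zones(image, mask, levels=8)
        assert m.n_zones == len(oracle)
        from collections import Counter

        expect = Counter(oracle)
        for (g, s), cnt in expect.items():
            assert m.matrix[g, s - 1] == cnt
        assert m.matrix.sum() == len(oracle)


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_panel_cardinalities(self):
        cats = feature_categories()
        sizes = {k: len(v) for k, v in cats.items()}
        assert sizes == {
            "histogram": 19, "outer": 9, "delta": 9,
            "shape": 10, "glcm": 11, "isz": 2,
        }
        assert len(feature_names()) == 60

    def test_valid_lesion_yields_60_keys_deterministically(self, lesion):
        v1 = extract_all(lesion)
        v2 = extract_all(lesion)
        assert len(v1.values) == 60
        assert v1.values == v2.values  # bitwise identical

    def test_translation_invariance(self):
        les = make_lesion(radius=6, noise_sd=8.0, seed=11)
        shape = np.array(les.image.voxels.shape)
        big = np.full(tuple(shape + 10), -1000.0)
        bigm = np.zeros(tuple(shape + 10), bool)
        big[1:1+shape[0], 2:2+shape[1], 3:3+shape[2]] = les.image.voxels
        bigm[1:1+shape[0], 2:2+shape[1], 3:3+shape[2]] = les.mask.voxels
        big2 = np.full(tuple(shape + 10), -1000.0)
        bigm2 = np.zeros(tuple(shape + 10), bool)
        big2[4:4+shape[0], 6:6+shape[1], 8:8+shape[2]] = les.image.voxels
        bigm2[4:4+shape[0], 6:6+shape[1], 8:8+shape[2]] = les.mask.voxels
        from tsradiomics import ImageVolume as IV, ROIMask as RM

        l1 = LesionRecord("P", "a", LesionType.PRIMARY, 1,
                          IV(big, (1, 1, 1)), RM(bigm, (1, 1, 1)))
        l2 = LesionRecord("P", "b", LesionType.PRIMARY, 1,
                          IV(big2, (1, 1, 1)), RM(bigm2, (1, 1, 1)))
        v1, v2 = extract_all(l1), extract_all(l2)
        for k in feature_names():
            if not (np.isnan(v1.values[k]) and np.isnan(v2.values[k])):
                assert v1.values[k] == pytest.approx(v2.values[k], rel=1e-9), k

    def test_intensity_shift_moves_location_features_only(self):
        les = make_lesion(radius=6, noise_sd=8.0, seed=13)
        shifted_img = ImageVolume(les.image.voxels + 55.0, les.image.spacing)
        les2 = LesionRecord("P", "s", LesionType.PRIMARY, 1, shifted_img, les.mask)
        v1, v2 = extract_all(les), extract_all(les2)
        assert v2.values["mean"] == pytest.approx(v1.values["mean"] + 55.0)
        assert v2.values["p25"] == pytest.approx(v1.values["p25"] + 55.0)
        assert v2.values["sd"] == pytest.approx(v1.values["sd"])
        assert v2.values["skewness"] == pytest.approx(v1.values["skewness"], rel=1e-9)
        assert v2.values["glcm_entropy"] == pytest.approx(v1.values["glcm_entropy"], rel=1e-12)

    def test_config_from_yaml(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("glcm_levels: 64\nisz_levels: 16\n")
        cfg = FeatureConfig.from_yaml(p)
        assert cfg.glcm_levels == 64 and cfg.isz_levels == 16 and cfg.hist_bins == 256
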