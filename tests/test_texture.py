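import numpy as np
import pytest

from adctexture import (
    FEATURE_NAMES,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
    extract_all,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from adctexture.texture import OFFSETS_13
from conftest import make_voi
from oracles import glcm_oracle, glrlm_oracle, glszm_oracle, ngtdm_oracle


class TestGLCM:
    def test_constant_voi_single_entry(self):
        q = make_voi(np.ones((3, 3, 3), int), n_bins=4)
        m = compute_glcm(q)
        assert m.P[0, 0] == pytest.approx(1.0)
        assert m.P.sum() == pytest.approx(1.0)
        f = glcm_features(m)
        assert f["contrast"] == 0
        assert f["dissimilarity"] == 0
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(1.0)
        assert f["entropy"] == 0

    def test_checkerboard_strip_contrast_one(self):
        levels = np.array([1, 2, 1, 2, 1, 2]).reshape(1, 1, 6)
        q = make_voi(levels, n_bins=2)
        m = compute_glcm(q, offsets=((0, 0, 1),))
        # all mass on the off-diagonal (1,2)/(2,1)
        assert m.P[0, 1] + m.P[1, 0] == pytest.approx(1.0)
        assert glcm_features(m)["contrast"] == pytest.approx(1.0)

    def test_single_offset_matches_pair_enumeration(self):
        rng = np.random.default_rng(7)
        levels = np.zeros((5, 5, 1), dtype=np.int32)
        levels[:, :, 0] = rng.integers(1, 5, size=(5, 5))
        q = make_voi(levels, n_bins=4)
        m = compute_glcm(q, offsets=((1, 0, 0),))
        P_oracle = glcm_oracle(q.levels, q.mask.data, [(1, 0, 0)])
        np.testing.assert_allclose(m.P[:4, :4], P_oracle, atol=1e-12)

    def test_rotation_invariance_all_offsets(self, random_voi_factory):
        rng = np.random.default_rng(3)
        q = random_voi_factory(rng, shape=(5, 5, 5))
        rot_levels = np.rot90(q.levels, k=1, axes=(0, 1)).copy()
        q_rot = make_voi(rot_levels, n_bins=q.n_bins)
        np.testing.assert_allclose(compute_glcm(q).P, compute_glcm(q_rot).P, atol=1e-12)

    def test_gray_level_reversal_symmetry(self, random_voi_factory):
        rng = np.random.default_rng(11)
        q = random_voi_factory(rng)
        rev = np.where(q.mask.data, q.n_bins + 1 - q.levels, 0)
        q_rev = make_voi(rev, n_bins=q.n_bins, mask=q.mask.data)
        f = glcm_features(compute_glcm(q))
        g = glcm_features(compute_glcm(q_rev))
        for name in ("contrast", "dissimilarity", "homogeneity", "energy", "entropy"):
            assert f[name] == pytest.approx(g[name], abs=1e-12)

    def test_features_match_direct_formula_evaluation(self, random_voi_factory):
        rng = np.random.default_rng(5)
        q = random_voi_factory(rng)
        P = compute_glcm(q).P
        f = glcm_features(compute_glcm(q))
        ng = P.shape[0]
        i, j = np.mgrid[1 : ng + 1, 1 : ng + 1]
        assert f["contrast"] == pytest.approx(np.sum(P * (i - j) ** 2))
        assert f["dissimilarity"] == pytest.approx(np.sum(P * np.abs(i - j)))
        assert f["homogeneity"] == pytest.approx(np.sum(P / (1 + (i - j) ** 2)))
        assert f["energy"] == pytest.approx(np.sum(P**2))
        assert f["maximum_probability"] == pytest.approx(P.max())
        nz = P[P > 0]
        assert f["entropy"] == pytest.approx(-np.sum(nz * np.log2(nz)))


class TestGLRLM:
    def test_constant_line_closed_form(self):
        n = 6
        q = make_voi(np.ones((1, 1, n), int), n_bins=2)
        m = compute_glrlm(q, directions=((0, 0, 1),))
        assert m.R[0, n - 1] == 1 and m.R.sum() == 1
        f = glrlm_features(m)
        assert f["sre"] == pytest.approx(1 / n**2)
        assert f["lre"] == pytest.approx(n**2)
        assert f["gln"] == pytest.approx(1.0)
        assert f["rln"] == pytest.approx(1.0)
        assert f["rp"] == pytest.approx(1 / n)

    def test_matrix_matches_run_scanner(self, random_voi_factory):
        rng = np.random.default_rng(21)
        for _ in range(5):
            q = random_voi_factory(rng, shape=(4, 4, 1))
            R = compute_glrlm(q).R
            R_oracle = glrlm_oracle(q.levels, q.mask.data, OFFSETS_13)
            np.testing.assert_array_equal(R, R_oracle[:, : R.shape[1]])
            assert R_oracle[:, R.shape[1] :].sum() == 0

    def test_voxel_conservation(self, random_voi_factory):
        rng = np.random.default_rng(22)
        q = random_voi_factory(rng, shape=(6, 5, 4))
        m = compute_glrlm(q)
        j = np.arange(1, m.R.shape[1] + 1)
        assert (m.R * j).sum() == q.voxel_count * 13


class TestGLSZM:
    def test_constant_voi_closed_form(self):
        q = make_voi(np.ones((3, 3, 2), int), n_bins=2)
        n = q.voxel_count
        m = compute_glszm(q)
        f = glszm_features(m)
        assert f["lze"] == pytest.approx(n**2)
        assert f["zp"] == pytest.approx(1 / n)
        assert f["gln"] == pytest.approx(1.0)
        assert f["zsn"] == pytest.approx(1.0)

    def test_two_disjoint_blobs(self):
        levels = np.zeros((9, 1, 1), dtype=int)
        levels[:3, 0, 0] = 2  # size-3 zone of level 2
        levels[4:9, 0, 0] = 2  # size-5 zone of level 2 (gap keeps them apart)
        q = make_voi(levels, n_bins=2)
        Z = compute_glszm(q).Z
        assert Z[1, 2] == 1 and Z[1, 4] == 1 and Z.sum() == 2

    def test_zone_flood_fill_oracle(self, random_voi_factory):
        rng = np.random.default_rng(31)
        for _ in range(5):
            q = random_voi_factory(rng, shape=(5, 4, 4))
            Z = compute_glszm(q).Z
            Z_oracle = glszm_oracle(q.levels, q.mask.data)
            assert Z.shape == Z_oracle.shape
            np.testing.assert_array_equal(Z, Z_oracle)

    def test_size_conservation(self, random_voi_factory):
        rng = np.random.default_rng(32)
        q = random_voi_factory(rng, shape=(6, 6, 3))
        m = compute_glszm(q)
        s = np.arange(1, m.Z.shape[1] + 1)
        assert (m.Z * s).sum() == q.voxel_count


class TestNGTDM:
    def test_constant_voi_degenerate_zero(self):
        q = make_voi(np.ones((3, 3, 3), int), n_bins=4)
        f = ngtdm_features(compute_ngtdm(q))
        assert f["contrast"] == 0
        assert f["busyness"] == 0
        assert f["complexity"] == 0

    def test_three_voxel_strip_components(self):
        q = make_voi(np.array([1, 2, 1]).reshape(1, 1, 3), n_bins=2)
        m = compute_ngtdm(q)
        # middle voxel: |2 - 1| = 1; each edge voxel's sole neighbor is the
        # middle voxel, so |1 - 2| = 1 twice
        np.testing.assert_allclose(m.s, [2.0, 1.0])
        np.testing.assert_allclose(m.p, [2 / 3, 1 / 3])

    def test_components_match_oracle(self, random_voi_factory):
        rng = np.random.default_rng(41)
        q = random_voi_factory(rng, shape=(4, 4, 4))
        m = compute_ngtdm(q)
        s, p, n, nv = ngtdm_oracle(q.levels, q.mask.data)
        ng = s.size
        np.testing.assert_allclose(m.s[:ng], s, atol=1e-9)
        np.testing.assert_allclose(m.p[:ng], p, atol=1e-12)
        assert m.n_valid == nv

    def test_probabilities_sum_to_one(self, random_voi_factory):
        rng = np.random.default_rng(42)
        q = random_voi_factory(rng)
        assert compute_ngtdm(q).p.sum() == pytest.approx(1.0, abs=1e-9)


class TestExtractAll:
    def test_cardinalities_and_order(self, random_voi_factory):
        rng = np.random.default_rng(51)
        fv = extract_all(random_voi_factory(rng))
        assert len(fv) == 39
        assert fv.names == FEATURE_NAMES
        prefixes = [n.split("_")[0] for n in fv.names]
        assert prefixes.count("glcm") == 8
        assert prefixes.count("glrlm") == 13
        assert prefixes.count("glszm") == 13
        assert prefixes.count("ngtdm") == 5
        assert not fv.quality_flag

    def test_single_voxel_flagged_but_finite(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        levels[1, 1, 1] = 1
        fv = extract_all(make_voi(levels, n_bins=4))
        assert fv.quality_flag
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, random_voi_factory):
        rng = np.random.default_rng(52)
        q = random_voi_factory(rng)
        np.testing.assert_array_equal(extract_all(q).values, extract_all(q).values)

    def test_translation_invariance(self, random_voi_factory):
        rng = np.random.default_rng(53)
        q = random_voi_factory(rng, shape=(4, 4, 3))
        big_levels = np.zeros((8, 8, 7), dtype=np.int32)
        big_levels[1:5, 2:6, 3:6] = q.levels
        shifted = np.zeros((8, 8, 7), dtype=np.int32)
        shifted[3:7, 1:5, 1:4] = q.levels
        fv1 = extract_all(make_voi(big_levels, n_bins=q.n_bins))
        fv2 = extract_all(make_voi(shifted, n_bins=q.n_bins))
        np.testing.assert_allclose(fv1.values, fv2.values, rtol=1e-12)
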