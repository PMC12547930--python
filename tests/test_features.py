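"""Feature catalogue, discretisation and texture-matrix correctness."""

import numpy as np
import pytest

from rwradiomics.catalogue import (
    FAMILY_SIZES,
    FEATURE_CODES,
    FEATURE_IDENTIFIERS,
    N_FEATURES,
    catalogue_table,
)
from rwradiomics.features import (
    DiscretisedSubimage,
    discretise,
    discretise_batch,
    extract_feature_vector,
    extract_features_batch,
    fos_features,
    glcm_features_from_matrix,
    texture_features,
    texture_matrix,
)

from conftest import (
    oracle_glcm,
    oracle_gldzm,
    oracle_glrlm,
    oracle_glszm,
    oracle_ngldm,
    oracle_ngtdm,
)

FAMILIES = ["GLCM", "GLRLM", "GLSZM", "GLDZM", "NGTDM", "NGLDM"]


def _random_levels(rng, max_side=5, max_ng=4):
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    ng = int(rng.integers(2, max_ng + 1))
    return rng.integers(1, ng + 1, size=(h, w)), ng


class TestCatalogue:
    def test_118_features_with_standard_family_sizes(self):
        assert N_FEATURES == 118
        assert FAMILY_SIZES == {
            "FOS": 23, "GLCM": 25, "GLRLM": 16, "GLSZM": 16, "GLDZM": 16,
            "NGTDM": 5, "NGLDM": 17,
        }

    def test_referenced_catalogue_indices_exist(self):
        # codes used in the reported best models must resolve
        for code in ["FOS1", "FOS11", "FOS13", "FOS22", "FOS23", "GLCM25",
                     "GLRLM7", "GLSZM16", "GLDZM14", "NGTDM5", "NGLDM17",
                     "NGLDM3"]:
            assert code in FEATURE_IDENTIFIERS
        tab = catalogue_table()
        assert len(tab) == 118 and tab["code"].is_unique


class TestDiscretise:
    def test_constant_grid_maps_to_level_one(self):
        d = discretise(np.full((8, 8), 3.7), ng=8)
        assert (d.levels == 1).all()

    def test_uniform_range_splits_into_equal_bins(self):
        grid = np.arange(64, dtype=float).reshape(8, 8)
        d = discretise(grid, ng=8)
        counts = np.bincount(d.levels.ravel(), minlength=9)[1:]
        assert (counts == 8).all()
        assert d.levels.min() == 1 and d.levels.max() == 8

    def test_affine_rescaling_invariance(self, rng):
        grid = rng.normal(size=(8, 8))
        a = discretise(grid, ng=6).levels
        b = discretise(2.5 * grid + 100.0, ng=6).levels
        np.testing.assert_array_equal(a, b)

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            discretise(np.zeros((4, 4)), ng=1)


class TestFos:
    def test_constant_grid_degenerate_conventions(self):
        f = fos_features(np.full((8, 8), 5.0))
        assert f["variance"] == 0
        assert f["skewness"] == 0 and f["kurtosis"] == 0
        assert f["histogram_entropy"] == 0
        assert f["uniformity"] == 1.0
        assert f["coefficient_of_variation"] == 0

    def test_uniform_four_level_histogram(self):
        # one pixel each of 1..4: uniform histogram at Ng=4
        grid = np.array([[1.0, 2.0], [3.0, 4.0]])
        f = fos_features(grid, disc=discretise(grid, ng=4))
        assert f["uniformity"] == pytest.approx(0.25)
        assert f["histogram_entropy"] == pytest.approx(2.0)  # bits

    def test_order_statistics_match_sort_based_oracle(self, rng):
        for _ in range(20):
            grid = rng.normal(size=(8, 8))
            f = fos_features(grid)
            x = np.sort(grid.ravel())
            n = x.size
            assert f["mean"] == pytest.approx(x.mean())
            assert f["minimum"] == x[0] and f["maximum"] == x[-1]

            def pct(q):  # sort-based linear interpolation
                pos = q / 100 * (n - 1)
                lo = int(np.floor(pos))
                hi = min(lo + 1, n - 1)
                return x[lo] + (pos - lo) * (x[hi] - x[lo])

            assert f["median"] == pytest.approx(pct(50))
            assert f["percentile10"] == pytest.approx(pct(10))
            assert f["percentile90"] == pytest.approx(pct(90))
            assert f["interquartile_range"] == pytest.approx(pct(75) - pct(25))


class TestTextureMatrices:
    def test_glcm_two_row_example(self):
        d = DiscretisedSubimage(np.array([[1, 1], [2, 2]]), ng=2)
        P = texture_matrix(d, "GLCM")
        # 0 degrees: only (1,1) and (2,2) pairs
        assert P[0, 0, 0] == pytest.approx(0.5)
        assert P[0, 1, 1] == pytest.approx(0.5)
        assert P[0, 0, 1] == 0

    def test_glszm_examples(self):
        const = DiscretisedSubimage(np.ones((8, 8), dtype=int), ng=2)
        szm = texture_matrix(const, "GLSZM")
        assert szm[0, 63] == 1 and szm.sum() == 1  # single zone of size 64
        d = DiscretisedSubimage(np.array([[1, 1], [2, 2]]), ng=2)
        szm = texture_matrix(d, "GLSZM")
        assert szm[0, 1] == 1 and szm[1, 1] == 1 and szm.sum() == 2

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matrices_match_bruteforce_on_random_small_images(self, family, rng):
        for _ in range(50):
            levels, ng = _random_levels(rng)
            d = DiscretisedSubimage(levels, ng=ng)
            got = texture_matrix(d, family)
            if family == "GLCM":
                np.testing.assert_allclose(got, oracle_glcm(levels, ng),
                                           atol=1e-12)
            elif family == "GLRLM":
                np.testing.assert_array_equal(got, oracle_glrlm(levels, ng))
            elif family == "GLSZM":
                np.testing.assert_array_equal(got, oracle_glszm(levels, ng))
            elif family == "GLDZM":
                np.testing.assert_array_equal(got, oracle_gldzm(levels, ng))
            elif family == "NGTDM":
                ni, si = got
                oni, osi = oracle_ngtdm(levels, ng)
                np.testing.assert_array_equal(ni, oni)
                np.testing.assert_allclose(si, osi, atol=1e-10)
            else:
                np.testing.assert_array_equal(got, oracle_ngldm(levels, ng))

    def test_glcm_matrices_symmetric_and_normalised(self, rng):
        levels = rng.integers(1, 9, size=(8, 8))
        P = texture_matrix(DiscretisedSubimage(levels, ng=8), "GLCM")
        for d in range(4):
            np.testing.assert_allclose(P[d], P[d].T, atol=1e-14)
            assert P[d].sum() == pytest.approx(1.0)


class TestTextureFeatures:
    def test_constant_image_degenerate_values(self):
        d = DiscretisedSubimage(np.ones((8, 8), dtype=int), ng=8)
        g = texture_features(texture_matrix(d, "GLCM"), "GLCM")
        assert g["contrast"] == 0
        assert g["dissimilarity"] == 0
        assert g["angular_second_moment"] == pytest.approx(1.0)
        assert g["correlation"] == 0
        t = texture_features(texture_matrix(d, "NGTDM"), "NGTDM")
        assert t["contrast"] == 0
        # hand evaluation for a single level: dependence counts split into
        # corner (4 px, j=4), edge (24 px, j=6) and interior (36 px, j=9)
        n = texture_features(texture_matrix(d, "NGLDM"), "NGLDM", nv=64)
        expected = (4**2 + 24**2 + 36**2) / 64**2
        assert n["dependence_count_energy"] == pytest.approx(expected)

    def test_glszm_small_zone_emphasis_two_zones(self):
        d = DiscretisedSubimage(np.array([[1, 1], [2, 2]]), ng=2)
        f = texture_features(texture_matrix(d, "GLSZM"), "GLSZM", nv=4)
        # two zones of size 2: SZE = (1/2) * (1/4 + 1/4)
        assert f["small_zone_emphasis"] == pytest.approx(0.25)
        assert f["zone_percentage"] == pytest.approx(0.5)


class TestFeatureVector:
    def test_always_118_finite_named_values(self, rng):
        for grid in [rng.normal(size=(8, 8)), np.zeros((8, 8)),
                     np.outer(np.arange(8), np.ones(8))]:
            fv = extract_feature_vector(grid)
            assert len(fv.values) == 118
            assert np.isfinite(fv.values).all()
            assert fv.names == FEATURE_CODES

    def test_affine_intensity_rescaling(self, rng):
        grid = rng.normal(size=(8, 8))
        a = extract_feature_vector(grid).as_dict()
        b = extract_feature_vector(3.0 * grid + 10.0).as_dict()
        # discretised families are invariant
        for code in FEATURE_CODES:
            fam = code.rstrip("0123456789")
            if fam != "FOS":
                assert a[code] == pytest.approx(b[code], abs=1e-9), code
        # raw-intensity statistics transform accordingly
        assert b["FOS1"] == pytest.approx(3.0 * a["FOS1"] + 10.0)
        assert b["FOS2"] == pytest.approx(9.0 * a["FOS2"])

    def test_rotation_invariance_of_direction_averaged_families(self, rng):
        grid = rng.normal(size=(8, 8))
        a = extract_feature_vector(grid).as_dict()
        b = extract_feature_vector(np.rot90(grid)).as_dict()
        for fam in ("GLCM", "GLRLM"):
            for k in range(1, FAMILY_SIZES[fam] + 1):
                assert a[f"{fam}{k}"] == pytest.approx(
                    b[f"{fam}{k}"], rel=1e-9, abs=1e-9
                ), f"{fam}{k}"

    def test_batch_matches_single_subimage_path(self, rng):
        subs = rng.normal(size=(16, 8, 8))
        batch = extract_features_batch(subs)
        for k in range(16):
            single = extract_feature_vector(subs[k]).values
            np.testing.assert_allclose(batch[k], single, rtol=1e-12, atol=1e-12)

    def test_order_stable_across_runs(self, rng):
        sub = rng.normal(size=(8, 8))
        a = extract_feature_vector(sub).values
        b = extract_feature_vector(sub.copy()).values
        np.testing.assert_array_equal(a, b)


def test_counts_and_normalised_glcm_paths_agree(rng):
    levels = discretise_batch(rng.normal(size=(50, 8, 8)), 8)
    from rwradiomics.features import (
        _glcm_features_counts,
        glcm_counts_batch,
        glcm_matrices_batch,
    )

    a = _glcm_features_counts(glcm_counts_batch(levels, 8))
    b = glcm_features_from_matrix(glcm_matrices_batch(levels, 8))
    np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)
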