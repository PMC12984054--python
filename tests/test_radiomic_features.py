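import itertools

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from stas_habitat.ct_preprocess import CTVolume, RegionMask
from stas_habitat.radiomic_features import (
    ALL_FEATURE_NAMES,
    DiscretizationSpec,
    extract_all,
    extract_region_features,
    knn_impute,
)
from stas_habitat.radiomic_features.discretize import discretize
from stas_habitat.radiomic_features.texture import (
    DIRECTIONS,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
)


def _ball(n=25, radius=10):
    g = np.indices((n, n, n)).astype(float) - (n - 1) / 2
    return ((g**2).sum(axis=0) <= radius**2).astype(np.int16)


class TestShapeFeatures:
    def test_digital_ball_is_nearly_spherical(self, rng):
        ct = CTVolume(rng.normal(size=(25, 25, 25)).astype(np.float32))
        f = extract_region_features(ct, RegionMask(_ball()))
        assert 0.95 <= f["shape_Sphericity"] <= 1.0
        assert abs(f["shape_Elongation"] - 1.0) <= 0.05
        assert f["shape_Maximum3DDiameter"] == pytest.approx(20.0, abs=1.0)

    def test_doubling_intensities_leaves_shape_unchanged(self, rng):
        vals = rng.random((15, 15, 15)).astype(np.float32)
        mask = RegionMask(_ball(15, 5))
        f1 = extract_region_features(CTVolume(vals), mask)
        f2 = extract_region_features(CTVolume(2 * vals), mask)
        for name in ALL_FEATURE_NAMES:
            if name.startswith("shape_"):
                assert f1[name] == f2[name], name

    def test_voxel_volume_is_count_times_spacing(self, rng):
        mask = RegionMask(_ball(15, 5), spacing_mm=(1.0, 1.0, 2.0))
        ct = CTVolume(rng.random((15, 15, 15)).astype(np.float32), spacing_mm=(1, 1, 2))
        f = extract_region_features(ct, mask)
        assert f["shape_VoxelVolume"] == pytest.approx(mask.binary().sum() * 2.0)


class TestFirstOrder:
    def test_constant_region_has_degenerate_texture(self):
        ct = CTVolume(np.full((10, 10, 10), 5.0, dtype=np.float32))
        m = np.zeros((10, 10, 10), dtype=np.int16)
        m[2:8, 2:8, 2:8] = 1
        f = extract_region_features(ct, RegionMask(m))
        assert f["firstorder_Entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["firstorder_Uniformity"] == pytest.approx(1.0)
        assert f["glcm_Contrast"] == pytest.approx(0.0)
        assert f["glcm_JointEnergy"] == pytest.approx(1.0)

    def test_printed_toy_region_mean_and_variance(self):
        # 3x3x1 region with intensities 1..9
        vals = np.zeros((5, 5, 3), dtype=np.float32)
        vals[1:4, 1:4, 1] = np.arange(1, 10).reshape(3, 3)
        m = (vals > 0).astype(np.int16)
        f = extract_region_features(CTVolume(vals), RegionMask(m))
        assert f["firstorder_Mean"] == pytest.approx(5.0)
        assert f["firstorder_Variance"] == pytest.approx(20.0 / 3.0)

    def test_mean_variance_match_direct_arithmetic(self, rng):
        vals = rng.random((12, 12, 12)).astype(np.float32)
        m = (rng.random((12, 12, 12)) < 0.4).astype(np.int16)
        m[5, 5, 5] = 1
        f = extract_region_features(CTVolume(vals), RegionMask(m))
        listed = vals[m > 0].astype(np.float64)
        npt.assert_allclose(f["firstorder_Mean"], listed.mean(), atol=1e-10)
        npt.assert_allclose(f["firstorder_Variance"], listed.var(), atol=1e-10)

    def test_tiny_region_yields_missing_vector(self):
        ct = CTVolume(np.zeros((5, 5, 5), dtype=np.float32))
        m = np.zeros((5, 5, 5), dtype=np.int16)
        m[2, 2, 2] = 1
        f = extract_region_features(ct, RegionMask(m))
        assert len(f) == 88
        assert all(np.isnan(v) for v in f.values())


class TestTextureMatrices:
    """Brute-force oracles for the three gray-level matrices."""

    @pytest.fixture()
    def instance(self, rng):
        levels = rng.integers(1, 5, size=(6, 5, 4))
        mask = rng.random((6, 5, 4)) < 0.7
        mask[3, 2, 2] = True
        return levels, mask

    def test_glcm_matches_pair_enumeration(self, instance):
        levels, mask = instance
        for off in DIRECTIONS:
            expected = np.zeros((4, 4))
            for idx in np.ndindex(levels.shape):
                nbr = tuple(i + d for i, d in zip(idx, off))
                if all(0 <= i < s for i, s in zip(nbr, levels.shape)):
                    if mask[idx] and mask[nbr]:
                        expected[levels[idx] - 1, levels[nbr] - 1] += 1
            expected = expected + expected.T
            npt.assert_array_equal(glcm_matrix(levels, mask, 4, off), expected)

    def test_glrlm_matches_run_enumeration(self, instance):
        levels, mask = instance
        for off in DIRECTIONS:
            runs = {}
            visited = set()
            for idx in np.ndindex(levels.shape):
                prev = tuple(i - d for i, d in zip(idx, off))
                starts = not (
                    all(0 <= i < s for i, s in zip(prev, levels.shape))
                    and mask[prev]
                    and levels[prev] == levels[idx]
                )
                if not mask[idx] or not starts:
                    continue
                length = 0
                cur = idx
                while (
                    all(0 <= i < s for i, s in zip(cur, levels.shape))
                    and mask[cur]
                    and levels[cur] == levels[idx]
                ):
                    length += 1
                    cur = tuple(i + d for i, d in zip(cur, off))
                runs[(levels[idx], length)] = runs.get((levels[idx], length), 0) + 1
            R = glrlm_matrix(levels, mask, 4, off)
            expected = np.zeros_like(R)
            for (g, length), count in runs.items():
                expected[g - 1, length - 1] = count
            npt.assert_array_equal(R, expected)

    def test_glszm_zone_count_equals_connected_components(self, instance):
        from scipy import ndimage

        levels, mask = instance
        Z = glszm_matrix(levels, mask, 4)
        total_zones = 0
        total_voxels = 0
        for g in (1, 2, 3, 4):
            region = mask & (levels == g)
            _, n = ndimage.label(region, structure=np.ones((3, 3, 3)))
            total_zones += n
            total_voxels += region.sum()
        assert Z.sum() == total_zones
        j = np.arange(1, Z.shape[1] + 1)
        assert (Z * j).sum() == total_voxels

    def test_direction_set_is_complete_and_unique(self):
        assert len(DIRECTIONS) == 13
        assert len({tuple(np.abs(d)) + tuple(d) for d in DIRECTIONS}) == 13
        for d in DIRECTIONS:
            assert tuple(-x for x in d) not in DIRECTIONS


class TestInvariances:
    def test_axis_permutation_invariance_for_symmetric_region(self, rng):
        vals = rng.random((15, 15, 15)).astype(np.float32)
        mask = _ball(15, 5)
        f1 = extract_region_features(CTVolume(vals), RegionMask(mask))
        perm = (2, 0, 1)
        f2 = extract_region_features(
            CTVolume(vals.transpose(perm)), RegionMask(mask.transpose(perm))
        )
        for name in ALL_FEATURE_NAMES:
            if name.startswith("firstorder_"):
                npt.assert_allclose(f1[name], f2[name], rtol=1e-6, err_msg=name)
            elif name.startswith(("glcm_", "glrlm_", "glszm_")):
                npt.assert_allclose(f1[name], f2[name], rtol=1e-3, err_msg=name)

    def test_discretization_requires_enough_bins(self):
        with pytest.raises(ValueError):
            DiscretizationSpec(bins=4)
        vals = np.array([1.0, 1.0, 1.0])
        assert (discretize(vals, DiscretizationSpec()) == 1).all()


class TestExtractAllAndImputation:
    @pytest.fixture()
    def cohort_cases(self, rng):
        cases = []
        for pid in ("A", "B", "C", "D", "E", "F"):
            vals = rng.normal(0.5, 0.1, size=(12, 12, 12)).astype(np.float32)
            regions = {}
            m = np.zeros((12, 12, 12), dtype=np.int16)
            m[3:9, 3:9, 3:9] = 1
            regions["intra"] = RegionMask(m)
            for j, tag in enumerate(["hab1", "hab2", "hab3"]):
                hm = np.zeros((12, 12, 12), dtype=np.int16)
                hm[3:9, 3:9, 3 + 2 * j : 5 + 2 * j] = 1
                regions[tag] = RegionMask(hm)
            cases.append((pid, CTVolume(vals), regions))
        return cases

    def test_block_structure_seven_blocks_gives_616_columns(self, rng):
        vals = CTVolume(rng.random((10, 10, 10)).astype(np.float32))
        m = np.zeros((10, 10, 10), dtype=np.int16)
        m[2:8, 2:8, 2:8] = 1
        regions = {
            tag: RegionMask(m)
            for tag in ("intra", "peri1", "peri3", "peri5", "hab1", "hab2", "hab3")
        }
        table = extract_all([("P1", vals, regions)])
        assert table.shape == (1, 7 * 88)

    def test_missing_region_leaves_88_missing_cells(self, cohort_cases):
        pid, ct, regions = cohort_cases[0]
        del regions["hab2"]
        table = extract_all(cohort_cases)
        assert int(table.loc[pid].isna().sum()) == 88
        assert table.drop(index=pid).notna().all().all()

    def test_row_order_independence(self, cohort_cases):
        t1 = extract_all(cohort_cases)
        t2 = extract_all(list(reversed(cohort_cases)))
        pd.testing.assert_frame_equal(t1, t2.loc[t1.index])

    def test_impute_identity_when_complete(self, rng):
        table = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
        out = knn_impute(table, train_index=list("abcd"))
        pd.testing.assert_frame_equal(out, table)

    def test_impute_exact_among_identical_rows(self):
        base = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0], (6, 1)), index=list("abcdef"), columns=list("xyz")
        )
        base.loc["f", "y"] = np.nan
        out = knn_impute(base, train_index=list("abcde"))
        assert out.loc["f", "y"] == pytest.approx(2.0)

    def test_planted_missingness_recovered_within_iqr(self, rng):
        n = 40
        latent = rng.normal(size=(n, 2))
        table = pd.DataFrame(
            latent @ rng.normal(size=(2, 8)) + 0.05 * rng.normal(size=(n, 8)),
            index=[f"p{i}" for i in range(n)],
        )
        truth = table.copy()
        holes = [(f"p{i}", c) for i, c in zip(range(8, 20), rng.integers(0, 8, 12))]
        for r, c in holes:
            table.loc[r, table.columns[c]] = np.nan
        out = knn_impute(table, train_index=[f"p{i}" for i in range(n)])
        errors = [
            abs(out.loc[r, table.columns[c]] - truth.loc[r, truth.columns[c]])
            for r, c in holes
        ]
        iqr = (truth.quantile(0.75) - truth.quantile(0.25)).median()
        assert np.median(errors) < iqr

    def test_fully_missing_column_is_an_error(self):
        table = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="y"):
            knn_impute(table, train_index=table.index)
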