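import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from steatoscope.tissue_mask import TissueMask
from steatoscope.white_regions import (WhiteMask, extract_white_regions,
                                       gamma_correct, kmeans_binarize,
                                       smooth_3x3)

from .oracles import mean3x3_oracle, two_means_split_oracle, union_find_components


class TestSmooth:
    def test_constant_unchanged(self):
        plane = np.full((10, 10), 0.42)
        np.testing.assert_allclose(smooth_3x3(plane), plane)

    def test_impulse_response(self):
        plane = np.zeros((9, 9))
        plane[4, 4] = 0.9
        out = smooth_3x3(plane)
        np.testing.assert_allclose(out[3:6, 3:6], 0.1)
        assert out[0, 0] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        plane = rng.uniform(size=(32, 32))
        np.testing.assert_allclose(smooth_3x3(plane), mean3x3_oracle(plane),
                                   atol=1e-12)

    def test_too_small_plane(self):
        with pytest.raises(ValueError):
            smooth_3x3(np.zeros((2, 5)))


class TestGamma:
    def test_fixed_points_and_midpoint(self):
        plane = np.array([[0.0, 0.5, 1.0]])
        out = gamma_correct(plane, 6)
        np.testing.assert_allclose(out, [[0.0, 0.015625, 1.0]])

    def test_identity_at_gamma_one(self, rng):
        plane = rng.uniform(size=(8, 8))
        np.testing.assert_allclose(gamma_correct(plane, 1.0), plane)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            gamma_correct(np.zeros((3, 3)), 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(a=hs.floats(0.001, 0.999), b=hs.floats(0.001, 0.999),
           g=hs.floats(0.5, 10))
    def test_strictly_monotone(self, a, b, g):
        if a == b:
            return
        lo, hi = sorted((a, b))
        out = gamma_correct(np.array([[lo, hi]]), g)
        assert out[0, 0] < out[0, 1]


class TestKMeans:
    def _tissue(self, shape):
        return TissueMask(np.ones(shape, dtype=bool))

    def test_two_populations_vs_exhaustive_oracle(self, rng):
        vals = np.concatenate([rng.normal(0.1, 0.01, 500),
                               rng.normal(0.9, 0.01, 500)])
        plane = vals.reshape(25, 40).clip(0, 1)
        wm = kmeans_binarize(plane, self._tissue(plane.shape))
        oracle_thr = two_means_split_oracle(plane.ravel())
        assert abs(wm.kmeans_threshold - 0.5) < 0.05
        np.testing.assert_array_equal(wm.mask, plane > oracle_thr)

    def test_deterministic(self, rng):
        plane = rng.uniform(size=(20, 20))
        t = self._tissue(plane.shape)
        m1 = kmeans_binarize(plane, t)
        m2 = kmeans_binarize(plane, t)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        assert m1.kmeans_threshold == m2.kmeans_threshold

    def test_constant_tissue_raises(self):
        with pytest.raises(ValueError):
            kmeans_binarize(np.full((10, 10), 0.5), self._tissue((10, 10)))

    def test_restricted_to_tissue(self, rng):
        plane = rng.uniform(size=(20, 20))
        tissue = np.zeros((20, 20), dtype=bool)
        tissue[5:15, 5:15] = True
        wm = kmeans_binarize(plane, TissueMask(tissue))
        assert not wm.mask[~tissue].any()

    def test_gamma_invariant_split_on_two_level_image(self):
        """Monotone darkening must not change which pixels are white."""
        plane = np.where(np.indices((12, 12)).sum(axis=0) % 3 == 0, 0.9, 0.3)
        t = self._tissue(plane.shape)
        base = kmeans_binarize(plane, t).mask
        dark = kmeans_binarize(gamma_correct(plane, 6), t).mask
        np.testing.assert_array_equal(base, dark)


class TestComponents:
    def test_min_area_filter(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:10, 2:10] = True        # 64 px
        mask[20:25, 20:25] = True      # 25 px
        regions = extract_white_regions(WhiteMask(mask), min_area=60)
        assert len(regions) == 1
        assert regions[0].pixel_count == 64

    def test_max_area_cap(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:10, 2:10] = True
        regions = extract_white_regions(WhiteMask(mask), min_area=1, max_area=50)
        assert regions == []

    def test_empty_mask(self):
        assert extract_white_regions(WhiteMask(np.zeros((5, 5), bool))) == []

    def test_diagonal_touch_connectivity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches only diagonally
        assert len(extract_white_regions(WhiteMask(mask), min_area=1,
                                         connectivity=8)) == 1
        assert len(extract_white_regions(WhiteMask(mask), min_area=1,
                                         connectivity=4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_count_matches_union_find_oracle(self, rng, connectivity):
        for _ in range(10):
            mask = rng.uniform(size=(15, 15)) > 0.6
            regions = extract_white_regions(WhiteMask(mask), min_area=1,
                                            connectivity=connectivity)
            assert len(regions) == union_find_components(mask, connectivity)

    def test_raster_order_and_bbox(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10:14, 1:5] = True
        mask[1:5, 10:14] = True
        regions = extract_white_regions(WhiteMask(mask), min_area=1)
        assert [r.region_id for r in regions] == [1, 2]
        assert regions[0].bbox == (1, 10, 5, 14)  # first in raster order
        for r in regions:
            rows, cols = np.nonzero(r.mask())
            assert rows.min() == r.bbox[0] and rows.max() == r.bbox[2] - 1
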