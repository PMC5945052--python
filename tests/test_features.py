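import numpy as np
import pytest

import steatoscope as st
from steatoscope.features import (MACRO_FEATURE_COUNT, MICRO_FEATURE_COUNT,
                                  macro_feature_matrix, macro_feature_names,
                                  macro_features, micro_feature_matrix,
                                  micro_features, region_context)
from steatoscope.gabor_bank import apply_bank, micro_bank
from steatoscope.tissue_mask import TissueMask
from steatoscope.white_regions import WhiteMask, extract_white_regions


def _regions_from_mask(mask, min_area=1):
    return extract_white_regions(WhiteMask(mask), min_area=min_area)


class TestRegionContext:
    def test_single_pixel_chebyshev_disk(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50, 50] = True
        reg = _regions_from_mask(mask)[0]
        ctx = region_context(reg, (200, 200), margin=20)
        assert ctx.dilated_mask.sum() == (2 * 20 + 1) ** 2  # 1681

    def test_rect25_clipping(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:20, 10:20] = True
        reg = _regions_from_mask(mask)[0]
        ctx = region_context(reg, (100, 100))
        assert ctx.rect_bbox == (0, 0, 45, 45)

    def test_corner_region_clipped_in_bounds(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[0:5, 0:5] = True
        ctx = region_context(_regions_from_mask(mask)[0], (60, 60))
        dr0, dc0, dr1, dc1 = ctx.dilated_bbox
        assert dr0 >= 0 and dc0 >= 0 and dr1 <= 60 and dc1 <= 60
        assert ctx.dilated_mask.shape == (dr1 - dr0, dc1 - dc0)


def _toy_scene(shift=0):
    """Two identical droplets in identical flat contexts, 160x320."""
    px = np.full((160, 320, 3), 160, dtype=np.uint8)
    img = st.SlideImage(px)
    channels = st.channel_stack(img)
    mask = np.zeros((160, 320), dtype=bool)
    yy, xx = np.mgrid[0:160, 0:320]
    mask |= (yy - 80) ** 2 + (xx - (80 + shift)) ** 2 <= 15 ** 2
    mask |= (yy - 80) ** 2 + (xx - (240 + shift)) ** 2 <= 15 ** 2
    tissue = TissueMask(np.ones((160, 320), dtype=bool))
    return channels, _regions_from_mask(mask, min_area=60), tissue


class TestMacroFeatures:
    def test_dimensionality_and_names(self, macro_bank20):
        channels, regions, tissue = _toy_scene()
        vec = macro_features(channels, regions[0], macro_bank20, tissue, regions)
        assert len(vec.values) == MACRO_FEATURE_COUNT == 554
        assert len(vec.names) == 554
        assert sum(n.startswith("gabor_") for n in vec.names) == 140
        assert len(set(vec.names)) == 554

    def test_identical_contexts_identical_vectors(self, macro_bank20):
        channels, regions, tissue = _toy_scene()
        df = macro_feature_matrix(channels, regions, macro_bank20, tissue)
        np.testing.assert_allclose(df.iloc[0].to_numpy(),
                                   df.iloc[1].to_numpy(), atol=1e-9)

    def test_morphology_translation_invariance(self, macro_bank20):
        channels, regions, tissue = _toy_scene()
        channels2, regions2, _ = _toy_scene(shift=10)
        morph = [n for n in macro_feature_names(macro_bank20)
                 if n.startswith("morph_")]
        a = macro_feature_matrix(channels, regions, macro_bank20, tissue)
        b = macro_feature_matrix(channels2, regions2, macro_bank20, tissue)
        np.testing.assert_allclose(a[morph].iloc[0], b[morph].iloc[0],
                                   atol=1e-9)

    def test_gabor_features_nonnegative(self, macro_bank20):
        channels, regions, tissue = _toy_scene()
        df = macro_feature_matrix(channels, regions, macro_bank20, tissue)
        gab = [n for n in df.columns if n.startswith("gabor_")]
        assert (df[gab].to_numpy() >= 0).all()

    def test_circularity_disk_vs_bar(self, macro_bank20):
        mask = np.zeros((200, 200), dtype=bool)
        yy, xx = np.mgrid[0:200, 0:200]
        mask |= (yy - 50) ** 2 + (xx - 50) ** 2 <= 20 ** 2
        mask[150:152, 50:110] = True  # 2x60 bar
        channels = st.channel_stack(
            st.SlideImage(np.full((200, 200, 3), 160, dtype=np.uint8)))
        tissue = TissueMask(np.ones((200, 200), dtype=bool))
        regions = _regions_from_mask(mask, min_area=60)
        df = macro_feature_matrix(channels, regions, macro_bank20, tissue)
        disk_row = df.loc[df["morph_log_area"].idxmax()]
        bar_row = df.loc[df["morph_log_area"].idxmin()]
        assert 0.85 <= disk_row["morph_circularity"] <= 1.05
        assert bar_row["morph_circularity"] < 0.5

    def test_wrong_bank_size_rejected(self, macro_bank20):
        channels, regions, tissue = _toy_scene()
        bad = st.build_bank(4, 3)
        with pytest.raises(ValueError):
            macro_feature_matrix(channels, regions, bad, tissue)


@pytest.fixture(scope="module")
def bank40():
    return micro_bank((128, 128))


class TestMicroFeatures:
    def test_vector_length(self, bank40, rng):
        gray = rng.uniform(size=(128, 128))
        vecs = micro_features(gray, [(10, 10), (64, 64)], bank40)
        assert all(len(v.values) == MICRO_FEATURE_COUNT == 40 for v in vecs)
        assert (vecs[0].values >= 0).all()

    def test_constant_image_zero_vectors(self, bank40):
        gray = np.full((128, 128), 0.6)
        mat = micro_feature_matrix(gray, [(5, 5), (100, 30)], bank40)
        assert np.abs(mat).max() < 1e-9

    def test_matches_full_response_stack(self, bank40, rng):
        gray = rng.uniform(size=(128, 128))
        coords = [(7, 9), (64, 100), (120, 3)]
        stack = apply_bank(gray, bank40)
        mat = micro_feature_matrix(gray, coords, bank40)
        for i, (r, c) in enumerate(coords):
            np.testing.assert_allclose(mat[i], stack[:, r, c], atol=1e-12)

    def test_out_of_bounds_coordinate(self, bank40):
        with pytest.raises(ValueError):
            micro_feature_matrix(np.zeros((128, 128)), [(200, 5)], bank40)
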