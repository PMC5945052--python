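import numpy as np
import pytest

from steatoscope.annotations import (Annotation, match_regions,
                                     parse_annotations, polygon_pixels,
                                     subsample_pixels, write_annotations)
from steatoscope.white_regions import WhiteMask, extract_white_regions

from .oracles import point_in_polygon_oracle


def _regions(mask):
    return extract_white_regions(WhiteMask(mask), min_area=1)


class TestParsing:
    def test_point_round_trip(self, tmp_path):
        anns = [Annotation("macro_fat", (10.0, 20.0), slide_id="s1")
                for _ in range(3)]
        path = tmp_path / "a.geojson"
        write_annotations(anns, path)
        back = parse_annotations(path)
        assert len(back) == 3
        assert all(a.label == "macro_fat" for a in back)
        assert back[0].geometry == (10.0, 20.0)

    def test_polygon_round_trip_exact(self, tmp_path):
        poly = [(1.5, 2.25), (10.0, 3.0), (6.125, 12.0)]
        write_annotations([Annotation("micro_fat", poly)], tmp_path / "p.geojson")
        back = parse_annotations(tmp_path / "p.geojson")
        assert back[0].geometry == poly

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown annotation label"):
            Annotation("blood_vessel", (1.0, 1.0))

    def test_two_vertex_polygon_rejected(self):
        with pytest.raises(ValueError):
            Annotation("micro_fat", [(0.0, 0.0), (1.0, 1.0)])

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0.0, 0.0), (10.0, 10.0), (0.0, 10.0), (10.0, 0.0)]
        with pytest.raises(ValueError):
            Annotation("micro_fat", bowtie)


class TestMatchRegions:
    def setup_method(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:20, 10:20] = True   # region 1
        mask[10:18, 40:48] = True   # region 2
        mask[60:70, 60:70] = True   # region 3
        self.regions = _regions(mask)

    def test_point_hits_containing_region(self):
        hits = match_regions(Annotation("macro_fat", (15.0, 15.0)), self.regions)
        assert [r.region_id for r in hits] == [1]

    def test_point_on_plain_tissue_no_match(self):
        assert match_regions(Annotation("macro_fat", (50.0, 50.0)),
                             self.regions) == []

    def test_polygon_collects_enclosed_regions(self):
        poly = [(5.0, 5.0), (5.0, 55.0), (25.0, 55.0), (25.0, 5.0)]
        hits = match_regions(Annotation("central_vein", poly), self.regions)
        assert sorted(r.region_id for r in hits) == [1, 2]

    def test_partial_overlap_not_matched_in_full_mode(self):
        poly = [(5.0, 5.0), (5.0, 15.0), (25.0, 15.0), (25.0, 5.0)]
        assert match_regions(Annotation("central_vein", poly),
                             self.regions) == []

    def test_centroid_mode_matches_partial(self):
        poly = [(5.0, 5.0), (5.0, 16.0), (25.0, 16.0), (25.0, 5.0)]
        hits = match_regions(Annotation("central_vein", poly), self.regions,
                             mode="centroid")
        assert [r.region_id for r in hits] == [1]

    def test_polygon_monotone_under_enlargement(self):
        small = [(5.0, 5.0), (5.0, 25.0), (25.0, 25.0), (25.0, 5.0)]
        big = [(0.0, 0.0), (0.0, 99.0), (99.0, 99.0), (99.0, 0.0)]
        hit_small = {r.region_id for r in
                     match_regions(Annotation("sinusoid", small), self.regions)}
        hit_big = {r.region_id for r in
                   match_regions(Annotation("sinusoid", big), self.regions)}
        assert hit_small <= hit_big


class TestPolygonPixels:
    def test_rectangle_raster(self):
        rect = [(10.0, 10.0), (10.0, 19.0), (19.0, 19.0), (19.0, 10.0)]
        px = polygon_pixels(Annotation("micro_fat", rect), (50, 50))
        assert len(px) == 100

    def test_triangle_matches_ray_casting_oracle(self):
        tri = [(3.3, 4.7), (27.6, 9.2), (14.1, 28.9)]
        px = set(polygon_pixels(Annotation("micro_fat", tri), (40, 40)))
        oracle = {(r, c) for r in range(40) for c in range(40)
                  if point_in_polygon_oracle((r, c), tri)}
        assert px == oracle

    def test_thin_sliver_empty(self):
        sliver = [(5.2, 5.2), (5.8, 25.2), (5.4, 25.2)]
        assert polygon_pixels(Annotation("micro_fat", sliver), (40, 40)) == []

    def test_polygon_outside_image(self):
        far = [(200.0, 200.0), (200.0, 210.0), (210.0, 205.0)]
        assert polygon_pixels(Annotation("micro_fat", far), (50, 50)) == []


class TestSubsample:
    def test_paper_rate_example(self):
        px = [(i, 0) for i in range(100_000)]
        assert len(subsample_pixels(px, 0.0002, seed=1)) == 20

    def test_minimum_one_rule(self):
        px = [(i, 0) for i in range(10)]
        assert len(subsample_pixels(px, 0.00001, seed=1)) == 1

    def test_deterministic_and_seed_sensitive(self):
        px = [(i, i) for i in range(1000)]
        a = subsample_pixels(px, 0.05, seed=3)
        b = subsample_pixels(px, 0.05, seed=3)
        c = subsample_pixels(px, 0.05, seed=4)
        assert a == b
        assert a != c

    def test_subset_without_replacement(self):
        px = [(i, 2 * i) for i in range(500)]
        out = subsample_pixels(px, 0.2, seed=7)
        assert len(out) == len(set(out))
        assert set(out) <= set(px)

    def test_empty_and_bad_rate(self):
        assert subsample_pixels([], 0.5, seed=0) == []
        with pytest.raises(ValueError):
            subsample_pixels([(0, 0)], 0.0, seed=0)
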