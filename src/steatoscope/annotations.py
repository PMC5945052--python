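"""Pathologist-style labels: GeoJSON parsing, region matching, pixel labeling.

Two annotation geometries exist.  A *point* marks the single candidate white
region it falls on; a *polygon* collects every candidate region falling
within it (macro training) or labels every enclosed pixel (micro training).
GeoJSON stores coordinates as (x, y) = (col, row); this module converts to
(row, col) pixel indices, 0-based, origin top-left, at the boundary.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .white_regions import WhiteRegion

logger = logging.getLogger(__name__)

LABELS = frozenset({
    "macro_fat", "micro_fat", "bile_duct", "portal_artery", "portal_vein",
    "central_vein", "lobular_inflammation", "portal_inflammation", "sinusoid",
})


@dataclass
class Annotation:
    """A labeled point (row, col) or closed polygon (vertex list) on a slide."""

    label: str
    geometry: tuple[float, float] | list[tuple[float, float]]
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"unknown annotation label {self.label!r}; "
                f"expected one of {sorted(LABELS)}")
        if self.is_polygon:
            if len(self.geometry) < 3:
                raise ValueError("polygon needs at least 3 vertices")
            poly = Polygon([(c, r) for r, c in self.geometry])
            if not poly.is_valid:
                raise ValueError(f"invalid (self-intersecting?) polygon "
                                 f"for label {self.label!r}")
            if poly.area == 0:
                raise ValueError("polygon has zero area")

    @property
    def is_polygon(self) -> bool:
        return isinstance(self.geometry, list)

    def shapely(self) -> Point | Polygon:
        """Geometry in (x, y) = (col, row) convention."""
        if self.is_polygon:
            return Polygon([(c, r) for r, c in self.geometry])
        r, c = self.geometry
        return Point(c, r)


def parse_annotations(path: str | os.PathLike) -> list[Annotation]:
    """Read a GeoJSON FeatureCollection of labeled Points/Polygons."""
    path = os.fspath(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out: list[Annotation] = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        label = props.get("label")
        if label is None:
            raise ValueError(f"{path}: feature missing 'label' property")
        geom = feat["geometry"]
        slide_id = props.get("slide_id", "")
        if geom["type"] == "Point":
            x, y = geom["coordinates"]
            out.append(Annotation(label=label, geometry=(float(y), float(x)),
                                  slide_id=slide_id))
        elif geom["type"] == "Polygon":
            ring = geom["coordinates"][0]
            verts = [(float(y), float(x)) for x, y in ring]
            if len(verts) > 1 and verts[0] == verts[-1]:
                verts = verts[:-1]  # drop GeoJSON closing vertex
            out.append(Annotation(label=label, geometry=verts,
                                  slide_id=slide_id))
        else:
            raise ValueError(f"{path}: unsupported geometry {geom['type']}")
    return out


def write_annotations(anns: list[Annotation], path: str | os.PathLike) -> None:
    """Write annotations as a GeoJSON FeatureCollection ((x, y) = (col, row))."""
    feats = []
    for ann in anns:
        if ann.is_polygon:
            ring = [[c, r] for r, c in ann.geometry]
            ring.append(ring[0])
            geom = {"type": "Polygon", "coordinates": [ring]}
        else:
            r, c = ann.geometry
            geom = {"type": "Point", "coordinates": [c, r]}
        feats.append({"type": "Feature", "geometry": geom,
                      "properties": {"label": ann.label,
                                     "slide_id": ann.slide_id}})
    with open(os.fspath(path), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def match_regions(ann: Annotation, regions: list[WhiteRegion],
                  mode: str = "full") -> list[WhiteRegion]:
    """Candidate regions selected by one annotation.

    Point: the unique region containing that pixel (empty if none).
    Polygon: regions falling within the boundary — ``mode='full'`` requires
    every member pixel inside, ``mode='centroid'`` only the centroid.
    """
    if not ann.is_polygon:
        r, c = (int(round(v)) for v in ann.geometry)
        hits = []
        for reg in regions:
            r0, c0, r1, c1 = reg.bbox
            if r0 <= r < r1 and c0 <= c < c1 and reg.label_map[r, c] == reg.label_value:
                hits.append(reg)
        if not hits:
            logger.debug("point annotation %s at (%d, %d) hits no region",
                         ann.label, r, c)
        return hits
    poly = ann.shapely()
    out = []
    for reg in regions:
        if mode == "centroid":
            if shapely.intersects_xy(poly, reg.centroid[1], reg.centroid[0]):
                out.append(reg)
            continue
        r0, c0, *_ = reg.bbox
        rows, cols = np.nonzero(reg.local_mask())
        inside = shapely.intersects_xy(poly, cols + c0, rows + r0)
        if inside.all():
            out.append(reg)
    return out


def polygon_pixels(ann: Annotation,
                   shape: tuple[int, int]) -> list[tuple[int, int]]:
    """All pixels whose integer centers fall inside the polygon.

    Centers on the boundary are included (shapely ``covers``).  A polygon
    fully outside the image yields an empty list with a warning.
    """
    if not ann.is_polygon:
        raise ValueError("polygon_pixels requires a polygon annotation")
    poly = ann.shapely()
    minx, miny, maxx, maxy = poly.bounds
    h, w = shape
    c0 = max(0, int(np.floor(minx)))
    c1 = min(w - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(h - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        logger.warning("polygon %s lies outside the image", ann.label)
        return []
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
    return [(int(r), int(c))
            for r, c in zip(rr.ravel()[inside], cc.ravel()[inside])]


def subsample_pixels(pixels: list[tuple[int, int]], rate: float,
                     seed: int) -> list[tuple[int, int]]:
    """Uniform sample without replacement of max(1, round(rate * n)) pixels.

    The annotation-subsampling rule for micro training pixels; rounding is
    half-up with a minimum of one so tiny annotations still contribute.
    """
    if not (0 < rate <= 1):
        raise ValueError(f"rate must lie in (0, 1], got {rate}")
    n = len(pixels)
    if n == 0:
        return []
    size = max(1, int(np.floor(rate * n + 0.5)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(size, n), replace=False)
    return [pixels[i] for i in sorted(idx)]
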