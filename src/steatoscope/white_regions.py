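"""Candidate white-region detection inside tissue.

Fig-style pipeline: 3x3 mean smoothing of the green plane, gamma darkening
(gamma = 6), 1-D 2-means binarization of tissue intensities into white/black,
connected-component labeling, and an area filter.  Surviving components are
the candidate regions passed to feature extraction and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

from .tissue_mask import TissueMask

DEFAULT_GAMMA = 6.0
DEFAULT_MIN_AREA = 60


@dataclass
class WhiteMask:
    mask: np.ndarray  # H x W bool, True = white candidate pixel (tissue only)
    kmeans_threshold: float = float("nan")


@dataclass
class WhiteRegion:
    """One connected candidate component, backed by a shared label map."""

    region_id: int
    pixel_count: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]
    label_map: np.ndarray = field(repr=False)
    label_value: int = 0

    def mask(self) -> np.ndarray:
        """Full-frame boolean mask of this component."""
        return self.label_map == self.label_value

    def local_mask(self) -> np.ndarray:
        """Boolean mask restricted to the bounding box."""
        r0, c0, r1, c1 = self.bbox
        return self.label_map[r0:r1, c0:c1] == self.label_value


def smooth_3x3(plane: np.ndarray) -> np.ndarray:
    """3x3 averaging mask with edge replication at the borders."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2 or plane.shape[0] < 3 or plane.shape[1] < 3:
        raise ValueError("plane must be 2-D with both dimensions >= 3")
    return ndimage.uniform_filter(plane, size=3, mode="nearest")


def gamma_correct(plane: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Element-wise power law ``out = in**gamma`` (gamma > 1 darkens)."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    plane = np.asarray(plane, dtype=np.float64)
    return np.power(plane, gamma)


def _lloyd_1d(values: np.ndarray, k: int, seed: int | None,
              random_init: bool, max_iter: int = 300,
              tol: float = 1e-9) -> np.ndarray:
    """Deterministic 1-D k-means: percentile init + Lloyd iterations."""
    if random_init:
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.choice(values, size=k, replace=False))
    else:
        qs = (np.arange(k) + 0.5) / k * 100.0 if k != 2 else np.array([25.0, 75.0])
        centers = np.percentile(values, qs)
    for _ in range(max_iter):
        # nearest-center assignment via midpoints between sorted centers
        edges = (centers[:-1] + centers[1:]) / 2.0
        assign = np.searchsorted(edges, values)
        new = np.array([values[assign == j].mean() if np.any(assign == j)
                        else centers[j] for j in range(k)])
        shift = np.abs(new - centers).max()
        centers = np.sort(new)
        if shift < tol:
            break
    return centers


def kmeans_binarize(plane: np.ndarray, tissue: TissueMask, k: int = 2,
                    seed: int | None = None,
                    random_init: bool = False) -> WhiteMask:
    """2-means split of tissue intensities; the brighter cluster is white.

    The threshold is the midpoint between the two converged cluster centers.
    Initialization is the 25th/75th intensity percentile (deterministic); a
    seeded random init is available via ``random_init``.
    """
    plane = np.asarray(plane, dtype=np.float64)
    vals = plane[tissue.mask]
    if vals.size == 0 or np.unique(vals).size < k:
        raise ValueError(
            "degenerate clustering: tissue needs at least "
            f"{k} distinct intensity values")
    centers = _lloyd_1d(vals, k, seed, random_init)
    threshold = float((centers[-2] + centers[-1]) / 2.0)
    mask = (plane > threshold) & tissue.mask
    return WhiteMask(mask=mask, kmeans_threshold=threshold)


def extract_white_regions(white: WhiteMask, min_area: int = DEFAULT_MIN_AREA,
                          max_area: int | None = None,
                          connectivity: int = 8) -> list[WhiteRegion]:
    """Label connected white components and apply the area filter.

    Components smaller than ``min_area`` are dropped (noise); an optional
    ``max_area`` cap reproduces the alternative literal reading of the
    size rule.  Regions come back in raster order of their first pixel.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = cc_label(white.mask, connectivity=1 if connectivity == 4 else 2)
    regions: list[WhiteRegion] = []
    keep_values = []
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        if max_area is not None and prop.area > max_area:
            continue
        keep_values.append((prop.label, prop))
    # relabel kept components 1..n in raster order of first pixel
    relabeled = np.zeros_like(labels)
    out_props = []
    order = sorted(keep_values,
                   key=lambda lp: (lp[1].coords[0][0], lp[1].coords[0][1]))
    for new_id, (old, prop) in enumerate(order, start=1):
        relabeled[labels == old] = new_id
        out_props.append((new_id, prop))
    for new_id, prop in out_props:
        r0, c0, r1, c1 = prop.bbox
        regions.append(WhiteRegion(
            region_id=new_id, pixel_count=int(prop.area),
            bbox=(r0, c0, r1, c1),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            label_map=relabeled, label_value=new_id))
    return regions


def detect_white_regions(green: np.ndarray, tissue: TissueMask,
                         gamma: float = DEFAULT_GAMMA,
                         min_area: int = DEFAULT_MIN_AREA,
                         max_area: int | None = None,
                         connectivity: int = 8,
                         seed: int | None = None) -> tuple[WhiteMask, list[WhiteRegion]]:
    """Full candidate pipeline: smooth -> gamma -> 2-means -> components."""
    smoothed = smooth_3x3(green)
    dark = gamma_correct(smoothed, gamma)
    white = kmeans_binarize(dark, tissue, seed=seed)
    regions = extract_white_regions(white, min_area=min_area,
                                    max_area=max_area,
                                    connectivity=connectivity)
    return white, regions


def regions_table(regions: list[WhiteRegion]) -> pd.DataFrame:
    """Region summary table (region_id, area, bbox, centroid) for CSV export."""
    rows = [{
        "region_id": r.region_id, "area": r.pixel_count,
        "bbox_row0": r.bbox[0], "bbox_col0": r.bbox[1],
        "bbox_row1": r.bbox[2], "bbox_col1": r.bbox[3],
        "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
    } for r in regions]
    return pd.DataFrame(rows, columns=[
        "region_id", "area", "bbox_row0", "bbox_col0", "bbox_row1",
        "bbox_col1", "centroid_row", "centroid_col"])
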