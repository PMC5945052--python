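"""Region and pixel feature vectors.

Macro candidate regions are described by 554 features in three fixed blocks:

* Block A (140): mean Gabor response magnitude over the region dilated by
  20 px (Chebyshev), for each of the 20 bank kernels applied to each of the
  7 channel planes (plane-major, bank order within a plane).
* Block B (385): 11 window statistics of each of the 7 planes pre-smoothed
  at Gaussian scales sigma = 0, 1, 2, 4, 8, computed over the region's
  bounding box expanded by 25 px (scale-major, then plane, then statistic).
* Block C (29): morphology and context descriptors of the region itself.

Microsteatosis is classified pixel-wise from the 40 response magnitudes of
the 4-orientation x 10-octave grayscale Gabor bank at that pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import kurtosis as _kurtosis, skew as _skew
from skimage.measure import perimeter as _perimeter, regionprops

from .gabor_bank import GaborBank, apply_kernel
from .image_io import CHANNEL_ORDER, ChannelStack
from .tissue_mask import TissueMask
from .white_regions import WhiteRegion

SCALES = (0, 1, 2, 4, 8)
WINDOW_STATS = (
    "mean", "var", "skew", "kurt", "min", "max", "median", "entropy32",
    "gradmag_mean", "gradmag_var", "laplacian_mean",
)
MORPH_FEATURES = (
    # size/length descriptors are log1p-scaled: region areas span four
    # orders of magnitude (a 60 px droplet to a merged severe-grade sheet)
    # and raw values would dominate a z-scored linear model
    "log_area", "log_perimeter", "circularity", "eccentricity", "solidity",
    "extent", "log_major_axis", "log_minor_axis", "aspect_ratio",
    "log_convex_area", "log_convex_perimeter", "log_equivalent_diameter",
    "euler_number", "boundary_roughness", "centroid_bbox_offset",
    "log_bbox_height", "log_bbox_width",
    "rect25_white_fraction", "surround20_white_fraction",
    "green_mean_inside", "green_std_inside", "green_mean_surround",
    "green_std_surround", "green_contrast", "log_nearest_region_distance",
    "regions_within_50px", "log_nearest_region_area",
    "hu_moment_1_log", "hu_moment_2_log",
)
MACRO_FEATURE_COUNT = 554
MICRO_FEATURE_COUNT = 40


@dataclass
class RegionFeatureVector:
    region_id: int
    values: np.ndarray          # length 554
    names: list[str]


@dataclass
class PixelFeatureVector:
    coords: tuple[int, int]
    values: np.ndarray          # length 40


@dataclass
class ContextWindow:
    """The two feature-extraction windows around a candidate region."""

    dilated_bbox: tuple[int, int, int, int]   # bbox of the 20-px dilation
    dilated_mask: np.ndarray                  # bool, local to dilated_bbox
    rect_bbox: tuple[int, int, int, int]      # bbox expanded by 25, clipped


def region_context(region: WhiteRegion, shape: tuple[int, int],
                   margin: int = 20, rect_margin: int = 25) -> ContextWindow:
    """Dilate the region by ``margin`` (Chebyshev) and expand its bbox by
    ``rect_margin``; both windows are clipped to the image."""
    h, w = shape
    r0, c0, r1, c1 = region.bbox
    dr0, dc0 = max(0, r0 - margin), max(0, c0 - margin)
    dr1, dc1 = min(h, r1 + margin), min(w, c1 + margin)
    local = np.zeros((dr1 - dr0, dc1 - dc0), dtype=bool)
    local[r0 - dr0:r1 - dr0, c0 - dc0:c1 - dc0] = region.local_mask()
    if margin > 0:
        dist = ndimage.distance_transform_cdt(~local, metric="chessboard")
        dilated = dist <= margin
    else:
        dilated = local
    rr0, rc0 = max(0, r0 - rect_margin), max(0, c0 - rect_margin)
    rr1, rc1 = min(h, r1 + rect_margin), min(w, c1 + rect_margin)
    return ContextWindow(dilated_bbox=(dr0, dc0, dr1, dc1),
                         dilated_mask=dilated,
                         rect_bbox=(rr0, rc0, rr1, rc1))


def _bank_feature_names(bank: GaborBank, plane: str) -> list[str]:
    return [
        f"gabor_{plane}_t{round(math.degrees(k.orientation)):03d}_l{k.wavelength:g}"
        for k in bank.kernels
    ]


def macro_feature_names(bank: GaborBank) -> list[str]:
    """The stable 554-name layout for a 20-kernel bank."""
    names: list[str] = []
    for plane in CHANNEL_ORDER:
        names.extend(_bank_feature_names(bank, plane))
    for s in SCALES:
        for plane in CHANNEL_ORDER:
            for stat in WINDOW_STATS:
                names.append(f"win_s{s}_{plane}_{stat}")
    names.extend(f"morph_{m}" for m in MORPH_FEATURES)
    return names


def micro_feature_names(bank: GaborBank) -> list[str]:
    return _bank_feature_names(bank, "gray")


def _window_stats(window: np.ndarray, expanded: np.ndarray,
                  crop: tuple[slice, slice]) -> list[float]:
    """The 11 statistics of one rect25 window.

    ``expanded`` is the window padded by one image pixel on each available
    side so derivative stencils at the window edge use true neighbors.
    """
    vals = window.ravel()
    var = float(np.var(vals))
    # degenerate-window tie-break: constant (or numerically constant)
    # windows get zero skewness/kurtosis
    if np.ptp(vals) > 0 and var > 1e-24:
        with np.errstate(all="ignore"):
            sk = float(_skew(vals))
            ku = float(_kurtosis(vals))
        if not np.isfinite(sk):
            sk = 0.0
        if not np.isfinite(ku):
            ku = 0.0
    else:
        sk = ku = 0.0
    counts, _ = np.histogram(vals, bins=32, range=(0.0, 1.0))
    p = counts[counts > 0] / vals.size
    entropy = float(-(p * np.log2(p)).sum())
    gy, gx = np.gradient(expanded)
    gm = np.hypot(gy, gx)[crop]
    lap = ndimage.laplace(expanded)[crop]
    return [float(np.mean(vals)), var, sk, ku, float(vals.min()),
            float(vals.max()), float(np.median(vals)), entropy,
            float(gm.mean()), float(gm.var()), float(lap.mean())]


def _morphology_features(region: WhiteRegion, ctx: ContextWindow,
                         white_mask: np.ndarray, green: np.ndarray,
                         all_regions: list[WhiteRegion]) -> list[float]:
    local = region.local_mask()
    prop = regionprops(local.astype(np.uint8))[0]
    area = float(prop.area)
    perim = float(prop.perimeter)
    circularity = 4.0 * np.pi * area / perim ** 2 if perim > 0 else 0.0
    convex = prop.image_convex
    convex_perim = float(_perimeter(convex))
    roughness = perim / convex_perim if convex_perim > 0 else 1.0
    minor = float(prop.axis_minor_length)
    major = float(prop.axis_major_length)
    aspect = major / minor if minor > 0 else 0.0
    r0, c0, r1, c1 = region.bbox
    bbox_center = ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
    offset = math.hypot(region.centroid[0] - bbox_center[0],
                        region.centroid[1] - bbox_center[1])

    rr0, rc0, rr1, rc1 = ctx.rect_bbox
    rect_white = float(white_mask[rr0:rr1, rc0:rc1].mean())
    dr0, dc0, dr1, dc1 = ctx.dilated_bbox
    surround = ctx.dilated_mask.copy()
    surround[r0 - dr0:r1 - dr0, c0 - dc0:c1 - dc0] &= ~local
    wm_local = white_mask[dr0:dr1, dc0:dc1]
    n_surround = int(surround.sum())
    surround_white = float(wm_local[surround].mean()) if n_surround else 0.0

    g_local = green[dr0:dr1, dc0:dc1]
    reg_local = np.zeros_like(surround)
    reg_local[r0 - dr0:r1 - dr0, c0 - dc0:c1 - dc0] = local
    g_in = g_local[reg_local]
    g_out = g_local[surround]
    gmi, gsi = float(g_in.mean()), float(g_in.std())
    gmo = float(g_out.mean()) if n_surround else 0.0
    gso = float(g_out.std()) if n_surround else 0.0

    others = [r for r in all_regions if r.region_id != region.region_id]
    if others:
        d = np.array([math.hypot(region.centroid[0] - o.centroid[0],
                                 region.centroid[1] - o.centroid[1])
                      for o in others])
        nearest = int(np.argmin(d))
        nearest_dist = float(d[nearest])
        within50 = int((d <= 50.0).sum())
        nearest_area = float(others[nearest].pixel_count)
    else:
        nearest_dist = math.hypot(*white_mask.shape)  # no neighbor: image diagonal
        within50 = 0
        nearest_area = 0.0

    hu = prop.moments_hu

    def log1p(v):
        return float(np.log1p(v))

    def hu_log(h):  # signed log10 compression of Hu invariants
        return float(-np.sign(h) * np.log10(abs(h))) if h != 0 else 0.0

    return [log1p(area), log1p(perim), circularity, float(prop.eccentricity),
            float(prop.solidity), float(prop.extent), log1p(major),
            log1p(minor), aspect,
            log1p(float(prop.area_convex)), log1p(convex_perim),
            log1p(float(prop.equivalent_diameter_area)),
            float(prop.euler_number),
            roughness, offset, log1p(float(r1 - r0)), log1p(float(c1 - c0)),
            rect_white, surround_white, gmi, gsi, gmo, gso, gmi - gmo,
            log1p(nearest_dist), within50, log1p(nearest_area),
            hu_log(float(hu[0])), hu_log(float(hu[1]))]


def macro_feature_matrix(channels: ChannelStack, regions: list[WhiteRegion],
                         bank: GaborBank, tissue: TissueMask,
                         all_regions: list[WhiteRegion] | None = None,
                         ) -> pd.DataFrame:
    """554-column feature table for a batch of regions on one slide.

    Gabor responses and smoothed planes are computed once per slide and
    shared across regions, so batch extraction is the efficient path.
    """
    if len(bank) != 20:
        raise ValueError(f"macro features need a 20-kernel bank, got {len(bank)}")
    if all_regions is None:
        all_regions = regions
    names = macro_feature_names(bank)
    shape = channels.shape
    contexts = {r.region_id: region_context(r, shape) for r in regions}
    n = len(regions)
    out = np.empty((n, MACRO_FEATURE_COUNT), dtype=np.float64)

    col = 0
    for _, plane in channels.ordered():
        for kern in bank.kernels:
            resp = apply_kernel(plane, kern)
            for i, reg in enumerate(regions):
                ctx = contexts[reg.region_id]
                dr0, dc0, dr1, dc1 = ctx.dilated_bbox
                out[i, col] = resp[dr0:dr1, dc0:dc1][ctx.dilated_mask].mean()
            col += 1

    for s in SCALES:
        for _, plane in channels.ordered():
            sm = plane if s == 0 else ndimage.gaussian_filter(
                plane, sigma=s, mode="nearest")
            for i, reg in enumerate(regions):
                rr0, rc0, rr1, rc1 = contexts[reg.region_id].rect_bbox
                er0, ec0 = max(0, rr0 - 1), max(0, rc0 - 1)
                er1, ec1 = min(shape[0], rr1 + 1), min(shape[1], rc1 + 1)
                expanded = sm[er0:er1, ec0:ec1]
                crop = (slice(rr0 - er0, rr1 - er0),
                        slice(rc0 - ec0, rc1 - ec0))
                stats = _window_stats(sm[rr0:rr1, rc0:rc1], expanded, crop)
                out[i, col:col + len(WINDOW_STATS)] = stats
            col += len(WINDOW_STATS)

    white_mask = regions[0].label_map > 0 if regions else None
    green = channels["G"]
    for i, reg in enumerate(regions):
        out[i, col:] = _morphology_features(
            reg, contexts[reg.region_id], white_mask, green, all_regions)

    if not np.isfinite(out).all():
        bad = np.argwhere(~np.isfinite(out))
        raise FloatingPointError(
            f"non-finite feature {names[bad[0][1]]} for region "
            f"{regions[bad[0][0]].region_id}")
    return pd.DataFrame(out, columns=names,
                        index=pd.Index([r.region_id for r in regions],
                                       name="region_id"))


def macro_features(channels: ChannelStack, region: WhiteRegion,
                   bank: GaborBank, tissue: TissueMask,
                   all_regions: list[WhiteRegion]) -> RegionFeatureVector:
    """Single-region convenience wrapper around the batch extractor."""
    df = macro_feature_matrix(channels, [region], bank, tissue,
                              all_regions=all_regions)
    return RegionFeatureVector(region_id=region.region_id,
                               values=df.to_numpy()[0],
                               names=list(df.columns))


def micro_feature_matrix(gray: np.ndarray, coords, bank: GaborBank) -> np.ndarray:
    """(n_coords, 40) matrix of response magnitudes at the given pixels."""
    if len(bank) != 40:
        raise ValueError(f"micro features need a 40-kernel bank, got {len(bank)}")
    gray = np.asarray(gray, dtype=np.float64)
    coords = [(int(r), int(c)) for r, c in coords]
    h, w = gray.shape
    for r, c in coords:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"coordinate ({r}, {c}) outside {h}x{w} image")
    rows = np.array([r for r, _ in coords], dtype=np.intp)
    cols = np.array([c for _, c in coords], dtype=np.intp)
    out = np.empty((len(coords), len(bank)), dtype=np.float64)
    for j, kern in enumerate(bank.kernels):
        resp = apply_kernel(gray, kern)
        out[:, j] = resp[rows, cols]
    return out


def micro_features(gray: np.ndarray, coords,
                   bank: GaborBank) -> list[PixelFeatureVector]:
    mat = micro_feature_matrix(gray, coords, bank)
    return [PixelFeatureVector(coords=(int(r), int(c)), values=mat[i])
            for i, (r, c) in enumerate(coords)]
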