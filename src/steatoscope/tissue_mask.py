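"""Tissue/background separation by region growing on the green channel.

The slide background is bright and touches the image border; tissue is the
complement of the background region grown from border seeds.  Because growth
is border-connected, white lumina enclosed by tissue (fat droplets, vessel
lumina) are never absorbed into the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, remove_small_holes
from PIL import Image

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class TissueMask:
    mask: np.ndarray  # H x W bool, True = tissue

    @property
    def tissue_area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def background(self) -> np.ndarray:
        return ~self.mask


def _seed_mask(shape: tuple[int, int], seed_policy: str) -> np.ndarray:
    seeds = np.zeros(shape, dtype=bool)
    if seed_policy == "border":
        seeds[0, :] = seeds[-1, :] = True
        seeds[:, 0] = seeds[:, -1] = True
    elif seed_policy == "corners":
        seeds[0, 0] = seeds[0, -1] = seeds[-1, 0] = seeds[-1, -1] = True
    else:
        raise ValueError(f"unknown seed_policy {seed_policy!r}")
    return seeds


def grow_background(green: np.ndarray, tolerance: float = 0.12,
                    seed_policy: str = "border",
                    postprocess: bool = True) -> TissueMask:
    """Grow the background from border seeds; tissue is the complement.

    A pixel joins the background if it is 4-connected to a seed through
    pixels whose intensity differs from the initial seed-region mean by at
    most ``tolerance``.  The reference mean is frozen at the seed mean so
    growth is monotone in the tolerance.

    ``postprocess`` fills background holes smaller than 9 px and closes
    1-px gaps (scanner noise); disable for exact flood-fill semantics.
    """
    green = np.asarray(green, dtype=np.float64)
    if green.ndim != 2:
        raise ValueError("green plane must be 2-D")
    if not (0.0 <= tolerance <= 1.0):
        raise ValueError(f"tolerance must lie in [0, 1], got {tolerance}")
    seeds = _seed_mask(green.shape, seed_policy)
    seed_mean = green[seeds].mean()
    within = np.abs(green - seed_mean) <= tolerance
    labels, _ = ndimage.label(within, structure=_CROSS)
    border_labels = np.unique(labels[seeds & within])
    border_labels = border_labels[border_labels > 0]
    background = np.isin(labels, border_labels)
    if postprocess and background.any():
        background = remove_small_holes(background, max_size=8)
        background = closing(background, footprint=_CROSS)
    return TissueMask(mask=~background)


def tissue_area(mask: TissueMask) -> int:
    """Number of tissue pixels (the quantification denominator)."""
    return mask.tissue_area_px


def save_mask(mask: TissueMask, path: str) -> None:
    """Write the tissue mask as an 8-bit PNG (tissue=255, background=0)."""
    Image.fromarray(mask.mask.astype(np.uint8) * 255).save(path)
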