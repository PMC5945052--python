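"""Raster loading, half-resolution reduction and channel-plane derivation.

The pipeline operates on the half-resolution rendering of a 20X scan.  All
downstream stages consume either the RGB working image or one of seven
normalized channel planes (R, G, B, H, S, V, gray) derived from it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2hsv

CHANNEL_ORDER = ("R", "G", "B", "H", "S", "V", "gray")

#: ITU-R 601 luma weights used for the gray plane.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SlideImage:
    """An RGB slide raster plus its scale relative to the loaded resolution."""

    pixels: np.ndarray  # H x W x 3 uint8
    scale_factor: float = 1.0
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ChannelStack:
    """Seven named planes in [0, 1]: R, G, B, H, S, V, gray (fixed order)."""

    planes: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.planes[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def ordered(self) -> list[tuple[str, np.ndarray]]:
        return [(name, self.planes[name]) for name in CHANNEL_ORDER]


def _read_png(path: str) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except UnidentifiedImageError as exc:
        raise IOError(f"cannot decode raster image: {path}") from exc


def _read_tiff(path: str) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"cannot decode TIFF image: {path}") from exc
    return arr


_READERS = {".png": _read_png, ".tif": _read_tiff, ".tiff": _read_tiff}


def load_image(path: str | os.PathLike) -> SlideImage:
    """Load a PNG or TIFF raster as a :class:`SlideImage` (scale_factor 1.0).

    Grayscale inputs are replicated to three channels; alpha is dropped.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such image file: {path}")
    reader = _READERS.get(os.path.splitext(path)[1].lower(), _read_png)
    arr = reader(path)
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise IOError(f"unsupported raster layout {arr.shape}: {path}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return SlideImage(pixels=arr, scale_factor=1.0, source_path=path)


def save_image(img: SlideImage, path: str | os.PathLike) -> None:
    """Write the RGB raster as PNG or TIFF depending on the extension."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        Image.fromarray(img.pixels).save(path)


def downsample_half(img: SlideImage) -> SlideImage:
    """Reduce the image to 50% per side by 2x2 block averaging.

    Odd dimensions round up (edge rows/columns are replicated so no pixels
    are dropped).  Block means round half away from zero back to uint8.
    """
    h, w = img.shape
    if h < 2 or w < 2:
        raise ValueError("cannot halve an image with a 1-pixel dimension")
    px = img.pixels.astype(np.float64)
    if h % 2:
        px = np.concatenate([px, px[-1:]], axis=0)
    if w % 2:
        px = np.concatenate([px, px[:, -1:]], axis=1)
    hh, ww = px.shape[0] // 2, px.shape[1] // 2
    blocks = px.reshape(hh, 2, ww, 2, 3).mean(axis=(1, 3))
    out = np.floor(blocks + 0.5).astype(np.uint8)
    return SlideImage(pixels=out, scale_factor=img.scale_factor * 0.5,
                      source_path=img.source_path)


def channel_stack(img: SlideImage) -> ChannelStack:
    """Derive the seven working planes, each normalized to [0, 1].

    HSV follows the standard hexcone conversion with hue scaled to [0, 1]
    (achromatic pixels get hue 0); gray is the ITU-R 601 luma.
    """
    rgb = img.pixels.astype(np.float64) / 255.0
    hsv = rgb2hsv(rgb)
    planes = {
        "R": rgb[:, :, 0],
        "G": rgb[:, :, 1],
        "B": rgb[:, :, 2],
        "H": hsv[:, :, 0],
        "S": hsv[:, :, 1],
        "V": hsv[:, :, 2],
        "gray": rgb @ _LUMA,
    }
    return ChannelStack(planes=planes)
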