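"""Gabor filter banks and frequency-domain filtering.

A Gabor kernel is a complex sinusoid at wavelength lambda and orientation
theta under a Gaussian envelope of width sigma:

    g(x, y) = exp(-(x'^2 + y'^2) / (2 sigma^2)) * exp(i (2 pi x'/lambda + psi))
    x' =  x cos(theta) + y sin(theta)
    y' = -x sin(theta) + y cos(theta)

Kernels are sampled on a centered integer grid and DC-corrected (complex mean
subtracted) so that constant regions give exactly zero response, making the
magnitude features illumination-invariant.  Banks are laid out
orientation-major: theta is the outer loop, wavelength the inner one, with
wavelengths spaced one octave apart (each twice the previous).

Filtering runs in the frequency domain (FFT-based convolution with symmetric
boundary padding); responses are complex magnitudes, hence >= 0 and invariant
to the phase offset psi.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_MIN = 4.0
DEFAULT_SIGMA_RULE = 0.56  # sigma = 0.56 * lambda ~ one-octave half-amplitude bandwidth


@dataclass
class GaborKernel:
    wavelength: float          # px per cycle
    orientation: float         # radians
    phase: float               # radians
    sigma: float               # px
    kernel: np.ndarray = field(repr=False)  # complex, odd side length
    truncated: bool = False

    @property
    def side(self) -> int:
        return self.kernel.shape[0]


@dataclass
class GaborBank:
    kernels: list[GaborKernel]
    orientations: list[float]  # radians
    wavelengths: list[float]   # px

    def __len__(self) -> int:
        return len(self.kernels)

    def to_json(self) -> str:
        return json.dumps({
            "orientations_deg": [math.degrees(t) for t in self.orientations],
            "wavelengths_px": list(self.wavelengths),
            "sigma_rule": (self.kernels[0].sigma / self.kernels[0].wavelength
                           if self.kernels else DEFAULT_SIGMA_RULE),
            "psi": self.kernels[0].phase if self.kernels else 0.0,
            "n_kernels": len(self.kernels),
        })


def gabor_kernel(wavelength: float, orientation: float, phase: float = 0.0,
                 sigma: float | None = None,
                 max_side: int | None = None) -> GaborKernel:
    """Sample one DC-free complex Gabor kernel on an odd centered grid.

    Support is +/- ceil(3 sigma); kernels wider than ``max_side`` are
    truncated to that (odd) support and flagged.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if sigma is None:
        sigma = DEFAULT_SIGMA_RULE * wavelength
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    side = 2 * math.ceil(3 * sigma) + 1
    truncated = False
    if max_side is not None and side > max_side:
        side = max_side if max_side % 2 == 1 else max_side - 1
        side = max(side, 3)
        truncated = True
        logger.info("Gabor kernel lambda=%.1f truncated to side %d",
                    wavelength, side)
    r = side // 2
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(np.float64)
    xp = x * math.cos(orientation) + y * math.sin(orientation)
    yp = -x * math.sin(orientation) + y * math.cos(orientation)
    envelope = np.exp(-(xp ** 2 + yp ** 2) / (2.0 * sigma ** 2))
    carrier = np.exp(1j * (2.0 * np.pi * xp / wavelength + phase))
    g = envelope * carrier
    g -= g.mean()  # DC correction
    return GaborKernel(wavelength=wavelength, orientation=orientation,
                       phase=phase, sigma=sigma, kernel=g,
                       truncated=truncated)


def build_bank(n_orientations: int, n_frequencies: int,
               lambda_min: float = DEFAULT_LAMBDA_MIN, psi: float = 0.0,
               sigma_rule: float = DEFAULT_SIGMA_RULE,
               max_kernel_side: int | None = None) -> GaborBank:
    """Build an orientation-major bank of n_orientations x n_frequencies kernels.

    Orientations are theta_j = j * 180 / n_orientations degrees; wavelengths
    are octave-spaced, lambda_k = lambda_min * 2**k.
    """
    if n_orientations < 1 or n_frequencies < 1:
        raise ValueError("bank needs at least one orientation and one frequency")
    if lambda_min < 2:
        raise ValueError("lambda_min below 2 px is sub-Nyquist")
    orientations = [j * math.pi / n_orientations for j in range(n_orientations)]
    wavelengths = [lambda_min * (2.0 ** k) for k in range(n_frequencies)]
    kernels = [
        gabor_kernel(lam, theta, psi, sigma_rule * lam, max_kernel_side)
        for theta in orientations for lam in wavelengths
    ]
    return GaborBank(kernels=kernels, orientations=orientations,
                     wavelengths=wavelengths)


def macro_bank(**kw) -> GaborBank:
    """The 20-kernel bank (4 orientations x 5 octave-spaced frequencies)."""
    return build_bank(4, 5, **kw)


def micro_bank(image_shape: tuple[int, int] | None = None, **kw) -> GaborBank:
    """The 40-kernel grayscale bank (4 orientations x 10 frequencies).

    With ten octaves the largest kernels exceed any working image; kernel
    support is capped at min(H, W) // 2 when ``image_shape`` is given, and
    at 255 px otherwise (the top octaves are envelope-truncated either way).
    """
    if "max_kernel_side" not in kw:
        kw["max_kernel_side"] = (max(3, min(image_shape) // 2)
                                 if image_shape is not None else 255)
    return build_bank(4, 10, **kw)


def apply_kernel(plane: np.ndarray, kern: GaborKernel) -> np.ndarray:
    """Magnitude response of one kernel (FFT convolution, symmetric padding)."""
    plane = np.asarray(plane, dtype=np.float64)
    r = kern.side // 2
    if r > 2 * min(plane.shape):
        raise ValueError(
            f"kernel side {kern.side} too large for a {plane.shape} plane; "
            "build the bank with max_kernel_side capped")
    padded = np.pad(plane, r, mode="symmetric")
    resp = fftconvolve(padded, kern.kernel, mode="same")
    resp = resp[r:r + plane.shape[0], r:r + plane.shape[1]]
    return np.abs(resp)


def apply_bank(plane: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Stack of magnitude responses, one H x W plane per kernel (bank order)."""
    return np.stack([apply_kernel(plane, k) for k in bank.kernels], axis=0)
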