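"""S1 layer: Gabor filter bank and simple-cell response maps.

An S1 unit is a Gabor filter

    G(x, y) = exp(-(x0^2 + gamma^2 y0^2) / (2 sigma^2)) * cos(2 pi x0 / lambda)

with x0 = x cos(theta) + y sin(theta) and y0 = -x sin(theta) + y cos(theta),
evaluated on a centered integer grid, zero-meaned and L2-normalized.  The S1
response of a channel is the absolute value of its convolution with each
kernel; symmetric border padding keeps every map the size of the input, which
the saliency stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .config import GaborConfig
from .exceptions import ParameterError, SizeError


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single Gabor kernel.

    ``theta`` is the orientation in degrees, ``scale_index`` the 1-based scale,
    ``filter_size`` the (odd) kernel side in pixels, ``sigma`` the Gaussian
    envelope width, ``wavelength`` the cosine period, and ``aspect_ratio`` the
    envelope ellipticity gamma.
    """

    theta: float
    scale_index: int
    filter_size: int
    sigma: float
    wavelength: float
    aspect_ratio: float = 0.3

    def __post_init__(self):
        if self.filter_size % 2 == 0 or self.filter_size < 1:
            raise ParameterError(f"filter_size must be odd, got {self.filter_size}")
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ParameterError("sigma and wavelength must be positive")
        if not 0 < self.aspect_ratio <= 1:
            raise ParameterError("aspect_ratio must satisfy 0 < gamma <= 1")


def gabor_kernel(params: GaborParams, normalize: bool = True) -> np.ndarray:
    """Evaluate a Gabor kernel on its centered integer grid.

    With ``normalize`` the kernel is zero-meaned then scaled to unit L2 norm
    (the raw analytic values are kept otherwise).  Rows index y, columns x.
    """
    half = params.filter_size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    th = np.deg2rad(params.theta)
    x0 = x * np.cos(th) + y * np.sin(th)
    y0 = -x * np.sin(th) + y * np.cos(th)
    g = np.exp(-(x0 ** 2 + (params.aspect_ratio ** 2) * (y0 ** 2))
               / (2.0 * params.sigma ** 2)) * np.cos(2.0 * np.pi * x0 / params.wavelength)
    if normalize:
        g = g - g.mean()
        norm = np.linalg.norm(g)
        if norm > 0:
            g = g / norm
    return g


@dataclass
class FilterBank:
    """Gabor kernels indexed by (scale_index, theta)."""

    filters: dict
    orientations: list
    scales: list
    params: dict

    @property
    def max_filter_size(self) -> int:
        return max(p.filter_size for p in self.params.values())


def evenly_spaced_orientations(n: int) -> list:
    """n orientations covering [0, 180): 4 -> 0,45,90,135; 12 -> 0,15,...,165."""
    return [180.0 * i / n for i in range(n)]


def build_gabor_bank(orientations=None, scales=None,
                     param_table=None, aspect_ratio: float = 0.3,
                     config: GaborConfig | None = None) -> FilterBank:
    """Build the (scale, orientation) Gabor bank.

    ``param_table`` supplies one ``(filter_size, sigma, wavelength)`` row per
    scale; by default the standard 16-scale table from :mod:`ehmax.config` is
    used.  ``config`` is a convenience overriding all of the above.
    """
    if config is not None:
        orientations = evenly_spaced_orientations(config.n_orientations)
        scales = list(range(1, config.n_scales + 1))
        param_table = list(zip(config.filter_sizes, config.sigmas, config.wavelengths))
        aspect_ratio = config.aspect_ratio
    if param_table is None:
        cfg = GaborConfig()
        param_table = list(zip(cfg.filter_sizes, cfg.sigmas, cfg.wavelengths))
    if orientations is None:
        orientations = evenly_spaced_orientations(12)
    if scales is None:
        scales = list(range(1, len(param_table) + 1))

    filters, params = {}, {}
    for s in scales:
        size, sigma, lam = param_table[s - 1]
        for theta in orientations:
            p = GaborParams(theta=float(theta), scale_index=int(s),
                            filter_size=int(size), sigma=float(sigma),
                            wavelength=float(lam), aspect_ratio=float(aspect_ratio))
            filters[(int(s), float(theta))] = gabor_kernel(p)
            params[(int(s), float(theta))] = p
    return FilterBank(filters=filters, orientations=[float(t) for t in orientations],
                      scales=[int(s) for s in scales], params=params)


@dataclass
class S1Maps:
    """Simple-cell response rasters indexed by (scale_index, theta); every map
    has the shape of the input channel."""

    maps: dict

    @property
    def scales(self) -> list:
        return sorted({k[0] for k in self.maps})

    @property
    def orientations(self) -> list:
        return sorted({k[1] for k in self.maps})

    def __len__(self) -> int:
        return len(self.maps)


def apply_s1(channel: np.ndarray, bank: FilterBank) -> S1Maps:
    """Convolve a single channel with every kernel of the bank.

    The response is the absolute value of the filter output; symmetric padding
    makes each map the same size as the input.  Raises :class:`SizeError` when
    the channel is smaller than the largest kernel.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ParameterError(f"apply_s1: expected a 2-D channel, got {channel.shape}")
    biggest = bank.max_filter_size
    if channel.shape[0] < biggest or channel.shape[1] < biggest:
        raise SizeError(
            f"apply_s1: channel {channel.shape} smaller than largest "
            f"filter ({biggest}x{biggest})")
    maps = {}
    for key, kernel in bank.filters.items():
        pad = kernel.shape[0] // 2
        padded = np.pad(channel, pad, mode="symmetric")
        # Gabor kernels are point-symmetric, so convolution equals correlation.
        resp = fftconvolve(padded, kernel, mode="valid")
        maps[key] = np.abs(resp)
    return S1Maps(maps=maps)
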