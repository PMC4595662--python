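"""C1 layer: max-pooling of S1 maps into scale bands.

Each complex-cell (C1) unit takes the maximum S1 response over an L x L
neighborhood across the two adjacent scales of its band; windows advance by
the band's step and windows that would overhang the image border are dropped,
so a band's grid has floor((H - L) / step) + 1 rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from .config import BandSpec, default_band_table
from .exceptions import IncompleteInputError, ParameterError, SizeError
from .gabor import S1Maps


@dataclass
class C1Maps:
    """Pooled maps indexed by (band_index, theta), band indices 1-based."""

    maps: dict
    bands: list
    image_shape: tuple

    @property
    def band_indices(self) -> list:
        return sorted({k[0] for k in self.maps})

    @property
    def orientations(self) -> list:
        return sorted({k[1] for k in self.maps})

    def grid_shape(self, band_index: int) -> tuple:
        theta = self.orientations[0]
        return self.maps[(band_index, theta)].shape

    def band_stack(self, band_index: int) -> np.ndarray:
        """(rows, cols, O) stack of one band's maps, orientations ascending."""
        return np.stack([self.maps[(band_index, t)] for t in self.orientations],
                        axis=-1)


def grid_shape(image_shape: tuple, band: BandSpec) -> tuple:
    gh = (image_shape[0] - band.pool_size) // band.step + 1
    gw = (image_shape[1] - band.pool_size) // band.step + 1
    return gh, gw


def pool_c1(s1: S1Maps, bands: list | None = None,
            band_indices: list | None = None) -> C1Maps:
    """Max-pool an S1 stack into C1 scale bands.

    ``bands`` defaults to the standard 8-band table; ``band_indices`` (1-based)
    restricts pooling to a subset of bands, e.g. band 1 only during prototype
    learning.  Raises :class:`SizeError` when the image is smaller than the
    largest requested pooling neighborhood, and
    :class:`IncompleteInputError` when a member scale is missing from ``s1``.
    """
    bands = list(bands) if bands is not None else default_band_table()
    if band_indices is None:
        band_indices = list(range(1, len(bands) + 1))
    some_map = next(iter(s1.maps.values()))
    h, w = some_map.shape
    thetas = s1.orientations

    maps = {}
    for bi in band_indices:
        band = bands[bi - 1]
        if min(h, w) < band.pool_size:
            raise SizeError(
                f"pool_c1: image {h}x{w} smaller than pooling neighborhood "
                f"{band.pool_size} of band {bi}")
        gh, gw = grid_shape((h, w), band)
        rows = band.step * np.arange(gh) + band.pool_size // 2
        cols = band.step * np.arange(gw) + band.pool_size // 2
        for theta in thetas:
            for s in band.scales:
                if (s, theta) not in s1.maps:
                    raise IncompleteInputError(
                        f"pool_c1: missing S1 map (scale={s}, theta={theta})")
            combined = np.maximum(s1.maps[(band.scales[0], theta)],
                                  s1.maps[(band.scales[1], theta)])
            # maximum_filter of size L at center c covers [c - L//2, c - L//2 + L);
            # sampling at c = p + L//2 yields the window starting at p, which the
            # chosen p never lets touch the padded border.
            filtered = maximum_filter(combined, size=band.pool_size, mode="nearest")
            maps[(bi, theta)] = filtered[np.ix_(rows, cols)]
    return C1Maps(maps=maps, bands=bands, image_shape=(h, w))


def band_window_centers(image_extent: int, band: BandSpec) -> np.ndarray:
    """Image-coordinate centers of a band's pooling windows along one axis."""
    count = (image_extent - band.pool_size) // band.step + 1
    return band.step * np.arange(count) + (band.pool_size - 1) / 2.0


def map_to_band1(point: tuple, bands: list, image_shape: tuple) -> tuple:
    """Map an image-coordinate point (x, y) to its nearest band-1 C1 cell.

    Returns (cx, cy) grid indices; the nearest window center wins, with the
    lower index on exact ties.  Out-of-bounds points raise
    :class:`ParameterError`.
    """
    x, y = float(point[0]), float(point[1])
    h, w = image_shape
    if not (0 <= x < w and 0 <= y < h):
        raise ParameterError(f"map_to_band1: point ({x}, {y}) outside image {h}x{w}")
    band = bands[0]
    cx = int(np.abs(band_window_centers(w, band) - x).argmin())
    cy = int(np.abs(band_window_centers(h, band) - y).argmin())
    return cx, cy


def map_points_to_band1(points_xy: np.ndarray, bands: list,
                        image_shape: tuple) -> np.ndarray:
    """Vectorized :func:`map_to_band1` for an (N, 2) array of (x, y) points."""
    band = bands[0]
    centers_x = band_window_centers(image_shape[1], band)
    centers_y = band_window_centers(image_shape[0], band)
    pts = np.asarray(points_xy, dtype=float)
    cx = np.abs(pts[:, 0][:, None] - centers_x[None, :]).argmin(axis=1)
    cy = np.abs(pts[:, 1][:, None] - centers_y[None, :]).argmin(axis=1)
    return np.column_stack([cx, cy])
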