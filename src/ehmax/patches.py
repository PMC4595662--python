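"""Mid-level patches on band-1 C1 maps and their block-histogram descriptors.

A patch is an n x n x O crop of the band-1 C1 stack (n in C1 units, O
orientation channels).  Its descriptor divides the patch into 3 x 3
overlapping blocks (block side n/2, stride n/4), sums each orientation
channel over the block cells to form an O-bin histogram, L2-normalizes each
block and concatenates them row-major — 9 O values (108 for O = 12).  A 2 x 2
block RGB histogram over the patch's image footprint can be appended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BandSpec
from .exceptions import ParameterError, SizeError


@dataclass
class Patch:
    """An n x n x O crop of band-1 C1 maps centered at (cx, cy) grid units."""

    image_id: str
    center: tuple
    size: int
    tensor: np.ndarray
    source_set: str = "D"


@dataclass
class PatchDescriptor:
    vector: np.ndarray
    image_id: str = ""
    center: tuple = (0, 0)
    size: int = 0


def select_points_greedy(points, min_dist: float, max_count: int | None = None):
    """Greedy prefix scan keeping points at least ``min_dist`` apart.

    ``points`` are visited in their given (priority) order; a point is kept
    iff its Euclidean distance to every already-kept point is >= min_dist.
    Scanning stops once ``max_count`` points are kept.
    """
    if min_dist <= 0:
        raise ParameterError(f"select_points_greedy: min_dist must be > 0, got {min_dist}")
    kept = []
    limit = np.inf if max_count is None else max_count
    d2 = float(min_dist) ** 2
    for p in points:
        if len(kept) >= limit:
            break
        x, y = float(p[0]), float(p[1])
        if all((x - kx) ** 2 + (y - ky) ** 2 >= d2 for kx, ky in kept):
            kept.append((x, y))
    return kept


def valid_center_bounds(grid_shape: tuple, n: int) -> tuple:
    """Inclusive (lo, hi_row, hi_col) center bounds keeping an n-patch inside
    the grid; the patch footprint of center c spans [c - n//2, c - n//2 + n)."""
    gh, gw = grid_shape
    if gh < n or gw < n:
        raise SizeError(f"grid {grid_shape} too small for patch size {n}")
    lo = n // 2
    return lo, gh - n + lo, gw - n + lo


def sample_patch_centers(grid_shape: tuple, n: int, max_count: int,
                         sorted_points: np.ndarray | None = None,
                         rng: np.random.Generator | None = None,
                         min_dist: float | None = None):
    """Select patch centers on the band-1 grid under the overlap constraint.

    Discovery images pass ``sorted_points`` — (cx, cy) band-1 cells ordered by
    descending saliency; centers are clipped into the valid range, de-duplicated
    preserving order, and greedily kept with pairwise distance >= n/4.  Natural
    images pass ``rng`` instead: all valid centers are visited in a seeded
    random order under the same constraint.  Returns a list of (cx, cy) ints.
    """
    lo, hi_r, hi_c = valid_center_bounds(grid_shape, n)
    if min_dist is None:
        min_dist = n / 4.0
    if sorted_points is not None:
        pts = np.asarray(sorted_points, dtype=int)
        cx = np.clip(pts[:, 0], lo, hi_c)
        cy = np.clip(pts[:, 1], lo, hi_r)
        ordered = list(dict.fromkeys(zip(cx.tolist(), cy.tolist())))
    elif rng is not None:
        all_cx, all_cy = np.meshgrid(np.arange(lo, hi_c + 1), np.arange(lo, hi_r + 1))
        flat = np.column_stack([all_cx.ravel(), all_cy.ravel()])
        ordered = [tuple(p) for p in flat[rng.permutation(len(flat))]]
    else:
        raise ParameterError("sample_patch_centers: pass sorted_points or rng")
    kept = select_points_greedy(ordered, min_dist=min_dist, max_count=max_count)
    return [(int(x), int(y)) for x, y in kept]


def _block_offsets(n: int) -> list:
    if n % 4 != 0 or n < 4:
        raise ParameterError(f"patch size must be a positive multiple of 4, got {n}")
    q = n // 4
    return [0, q, 2 * q]


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.divide(v, norm, out=np.zeros_like(v), where=norm > 0)


def color_block_histogram(rgb_crop: np.ndarray, bins: int = 8) -> np.ndarray:
    """2 x 2 spatial blocks of per-channel RGB histograms, each block (3*bins
    values) L2-normalized, concatenated row-major."""
    crop = np.asarray(rgb_crop)
    if crop.ndim != 3 or crop.shape[2] != 3:
        raise ParameterError(f"color crop must be HxWx3, got {crop.shape}")
    hh, hw = crop.shape[0] // 2, crop.shape[1] // 2
    edges = np.linspace(0, 256, bins + 1)
    parts = []
    for by in (0, hh):
        for bx in (0, hw):
            block = crop[by:by + hh, bx:bx + hw]
            hist = np.concatenate([
                np.histogram(block[..., c].ravel(), bins=edges)[0].astype(float)
                for c in range(3)])
            parts.append(_normalize_rows(hist))
    return np.concatenate(parts)


def describe_patch(patch: Patch | np.ndarray, color_crop: np.ndarray | None = None,
                   use_color: bool = False, color_bins: int = 8) -> PatchDescriptor:
    """Reduce a patch tensor to its block-histogram descriptor (direct loops).

    The orientation part has length 9*O; with ``use_color`` the 2x2-block RGB
    histogram of ``color_crop`` is appended.  An all-zero block yields a zero
    sub-vector.
    """
    if isinstance(patch, Patch):
        tensor, meta = patch.tensor, patch
    else:
        tensor, meta = np.asarray(patch, dtype=float), None
    if tensor.ndim != 3 or tensor.shape[0] != tensor.shape[1]:
        raise ParameterError(f"patch tensor must be n x n x O, got {tensor.shape}")
    n = tensor.shape[0]
    offsets = _block_offsets(n)
    half = n // 2
    parts = []
    for by in offsets:
        for bx in offsets:
            block = tensor[by:by + half, bx:bx + half, :]
            parts.append(_normalize_rows(block.sum(axis=(0, 1))))
    vector = np.concatenate(parts)
    if use_color:
        if color_crop is None:
            raise ParameterError("describe_patch: use_color requires color_crop")
        vector = np.concatenate([vector, color_block_histogram(color_crop, color_bins)])
    if meta is not None:
        return PatchDescriptor(vector=vector, image_id=meta.image_id,
                               center=meta.center, size=meta.size)
    return PatchDescriptor(vector=vector)


def descriptor_field(stack: np.ndarray, n: int) -> np.ndarray:
    """Orientation descriptors of every n-patch of a C1 stack, stride 1.

    ``stack`` is (H', W', O); the result is (H'-n+1, W'-n+1, 9*O), where entry
    [r, c] equals ``describe_patch`` of the patch whose top-left cell is
    (r, c).  Block sums are evaluated with integral images, so the cost is
    independent of n.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ParameterError(f"descriptor_field: stack must be 3-D, got {stack.shape}")
    h, w, o = stack.shape
    if h < n or w < n:
        raise SizeError(f"descriptor_field: grid {h}x{w} too small for patch size {n}")
    offsets = _block_offsets(n)
    half = n // 2
    ii = np.zeros((h + 1, w + 1, o), dtype=float)
    ii[1:, 1:] = stack.cumsum(axis=0).cumsum(axis=1)
    gh, gw = h - n + 1, w - n + 1
    parts = []
    for by in offsets:
        for bx in offsets:
            y0, x0 = by, bx
            block = (ii[y0 + half:y0 + half + gh, x0 + half:x0 + half + gw]
                     - ii[y0 + half:y0 + half + gh, x0:x0 + gw]
                     - ii[y0:y0 + gh, x0 + half:x0 + half + gw]
                     + ii[y0:y0 + gh, x0:x0 + gw])
            parts.append(_normalize_rows(block))
    return np.concatenate(parts, axis=-1)


def color_histogram_field(rgb: np.ndarray, band: BandSpec, n: int,
                          grid_shape: tuple, bins: int = 8) -> np.ndarray:
    """RGB block histograms of every n-patch footprint, stride 1 on the C1
    grid.

    Returns (gh, gw, 4*3*bins) aligned with :func:`descriptor_field`
    positions; entry [r, c] equals ``color_block_histogram`` of the image
    crop under the patch whose top-left C1 cell is (r, c).  Uses one-hot
    integral images, so the cost is independent of the footprint size.
    """
    h, w = rgb.shape[:2]
    idx = (np.asarray(rgb, dtype=np.int32) * bins) // 256   # uint8 -> bin index
    ii = np.zeros((h + 1, w + 1, 3, bins))
    for ch in range(3):
        for b in range(bins):
            ii[1:, 1:, ch, b] = (idx[:, :, ch] == b).astype(float) \
                .cumsum(axis=0).cumsum(axis=1)
    gh, gw = grid_shape[0] - n + 1, grid_shape[1] - n + 1
    span = (n - 1) * band.step + band.pool_size   # footprint side in pixels
    half = span // 2
    y0 = band.step * np.arange(gh)
    x0 = band.step * np.arange(gw)
    parts = []
    for by in (0, half):
        for bx in (0, half):
            rows_lo, rows_hi = y0 + by, y0 + by + half
            cols_lo, cols_hi = x0 + bx, x0 + bx + half
            block = (ii[np.ix_(rows_hi, cols_hi)] - ii[np.ix_(rows_hi, cols_lo)]
                     - ii[np.ix_(rows_lo, cols_hi)] + ii[np.ix_(rows_lo, cols_lo)])
            block = block.reshape(gh, gw, 3 * bins)
            parts.append(_normalize_rows(block))
    return np.concatenate(parts, axis=-1)


def footprint_rect(center: tuple, n: int, band: BandSpec) -> tuple:
    """Image-pixel rectangle (y0, y1, x0, x1) covered by an n-patch centered at
    band-1 cell (cx, cy): the union of its member pooling windows."""
    cx, cy = center
    tl_x, tl_y = cx - n // 2, cy - n // 2
    y0 = tl_y * band.step
    x0 = tl_x * band.step
    y1 = (tl_y + n - 1) * band.step + band.pool_size
    x1 = (tl_x + n - 1) * band.step + band.pool_size
    return y0, y1, x0, x1


def extract_patch(stack: np.ndarray, center: tuple, n: int,
                  image_id: str = "", source_set: str = "D") -> Patch:
    """Crop the n x n x O tensor around a valid band-1 center."""
    cx, cy = center
    tl_x, tl_y = cx - n // 2, cy - n // 2
    if tl_x < 0 or tl_y < 0 or tl_y + n > stack.shape[0] or tl_x + n > stack.shape[1]:
        raise SizeError(f"patch at center {center} size {n} exceeds grid "
                        f"{stack.shape[:2]}")
    return Patch(image_id=image_id, center=(int(cx), int(cy)), size=n,
                 tensor=stack[tl_y:tl_y + n, tl_x:tl_x + n, :],
                 source_set=source_set)
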