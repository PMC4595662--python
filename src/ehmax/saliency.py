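"""Bottom-up saliency: orientation contrast + Lab color contrast, fused.

The orientation saliency map is a fine-minus-coarse contrast over the first
scales of the L-channel S1 stack:

    SFM_O = sum_{s=1..n_scales-offset} sum_theta (FM^{s,theta} - FM^{s+offset,theta})

The color saliency map is the per-pixel squared deviation of the Gaussian-
blurred Lab channels from their global means:

    SFM_C = sum_{i in {L,a,b}} (FM_C^i - avg(FM_C^i))^2

Both maps are standardized to zero mean / unit variance, fused as a weighted
sum, and the pixels are ranked by fused saliency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import PipelineConfig, SaliencyConfig
from .exceptions import IncompleteInputError, ParameterError
from .gabor import S1Maps, apply_s1, build_gabor_bank, evenly_spaced_orientations
from .io import LabImage, rgb_to_lab


@dataclass
class SaliencyResult:
    """Normalized orientation / color / fused saliency rasters plus the list
    of all pixels sorted by descending fused saliency.

    ``sorted_points`` is an (N, 3) array with columns (x, y, value); x indexes
    columns, y rows.  Ties are broken in row-major order.
    """

    sfm_o: np.ndarray
    sfm_c: np.ndarray
    sfm: np.ndarray
    sorted_points: np.ndarray


def orientation_saliency(s1: S1Maps, scale_offset: int = 4,
                         n_scales: int = 8, n_orientations: int = 12) -> np.ndarray:
    """Raw orientation saliency: summed fine-minus-coarse scale differences.

    Requires the S1 stack to contain scales ``1..n_scales`` at every one of
    ``n_orientations`` orientations; missing entries raise
    :class:`IncompleteInputError`.
    """
    thetas = evenly_spaced_orientations(n_orientations)
    out = None
    for s in range(1, n_scales - scale_offset + 1):
        for theta in thetas:
            for key in ((s, theta), (s + scale_offset, theta)):
                if key not in s1.maps:
                    raise IncompleteInputError(
                        f"orientation_saliency: missing S1 map (scale={key[0]}, "
                        f"theta={key[1]})")
            diff = s1.maps[(s, theta)] - s1.maps[(s + scale_offset, theta)]
            out = diff if out is None else out + diff
    return out


def color_saliency(lab: LabImage, blur_sigma: float = 1.0) -> np.ndarray:
    """Raw color saliency: squared deviation of blurred Lab channels from
    their global means, summed over channels."""
    out = np.zeros(lab.shape, dtype=float)
    for channel in (lab.L, lab.a, lab.b):
        blurred = gaussian_filter(np.asarray(channel, dtype=float), blur_sigma)
        out += (blurred - blurred.mean()) ** 2
    return out


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Standardize a raster to zero mean, unit standard deviation.

    A constant raster has no salient structure: it maps to all-zeros rather
    than raising on the degenerate standard deviation.
    """
    m = np.asarray(m, dtype=float)
    std = m.std()
    if std == 0 or not np.isfinite(std):
        return np.zeros_like(m)
    return (m - m.mean()) / std


def fuse_saliency(sfm_o_n: np.ndarray, sfm_c_n: np.ndarray,
                  orientation_weight: float = 0.4,
                  color_weight: float = 0.6) -> np.ndarray:
    """Weighted sum of the normalized orientation and color saliency maps."""
    if sfm_o_n.shape != sfm_c_n.shape:
        raise ParameterError(
            f"fuse_saliency: shape mismatch {sfm_o_n.shape} vs {sfm_c_n.shape}")
    return orientation_weight * sfm_o_n + color_weight * sfm_c_n


def sort_salient_points(sfm: np.ndarray) -> np.ndarray:
    """All pixels sorted by descending saliency; ties resolve row-major.

    Returns an (N, 3) float array with columns (x, y, value).
    """
    flat = np.asarray(sfm, dtype=float).ravel()
    order = np.argsort(-flat, kind="stable")
    ys, xs = np.divmod(order, sfm.shape[1])
    return np.column_stack([xs.astype(float), ys.astype(float), flat[order]])


def compute_saliency(pixels: np.ndarray, config: PipelineConfig | None = None,
                     s1: S1Maps | None = None,
                     lab: LabImage | None = None) -> SaliencyResult:
    """Full saliency chain for one RGB image.

    Precomputed ``s1`` (L-channel stack) and ``lab`` planes may be passed to
    avoid recomputation when the caller already has them.
    """
    cfg: SaliencyConfig = (config or PipelineConfig()).saliency
    gcfg = (config or PipelineConfig()).gabor
    if lab is None:
        lab = rgb_to_lab(pixels)
    if s1 is None:
        bank = build_gabor_bank(
            orientations=evenly_spaced_orientations(cfg.n_orientations),
            scales=list(range(1, cfg.n_scales + 1)),
            param_table=list(zip(gcfg.filter_sizes, gcfg.sigmas, gcfg.wavelengths)),
            aspect_ratio=gcfg.aspect_ratio)
        s1 = apply_s1(lab.L, bank)
    raw_o = orientation_saliency(s1, scale_offset=cfg.scale_offset,
                                 n_scales=cfg.n_scales,
                                 n_orientations=cfg.n_orientations)
    raw_c = color_saliency(lab, blur_sigma=cfg.color_blur_sigma)
    sfm_o = normalize_map(raw_o)
    sfm_c = normalize_map(raw_c)
    sfm = fuse_saliency(sfm_o, sfm_c, cfg.orientation_weight, cfg.color_weight)
    return SaliencyResult(sfm_o=sfm_o, sfm_c=sfm_c, sfm=sfm,
                          sorted_points=sort_salient_points(sfm))
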