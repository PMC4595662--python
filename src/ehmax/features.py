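"""Per-image feature preparation shared by learning and encoding.

Prototype learning only needs the first C1 scale band (S1 scales 1..8 cover
both the saliency stage and band 1), whereas C2 encoding needs all eight
bands; the two entry points below compute exactly what each stage uses, once
per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .c1 import C1Maps, map_points_to_band1, pool_c1
from .config import EncoderConfig, PipelineConfig
from .gabor import FilterBank, apply_s1, build_gabor_bank, evenly_spaced_orientations
from .io import ImageRecord, rgb_to_lab
from .patches import color_histogram_field, descriptor_field
from .saliency import compute_saliency


def learning_gabor_bank(cfg: PipelineConfig) -> FilterBank:
    """Bank covering the saliency scales (1..n_scales, enhanced-model
    orientations); band 1 pools its first two scales."""
    g = cfg.gabor
    n_scales = max(cfg.saliency.n_scales, max(cfg.c1.bands[0].scales))
    return build_gabor_bank(
        orientations=evenly_spaced_orientations(cfg.saliency.n_orientations),
        scales=list(range(1, n_scales + 1)),
        param_table=list(zip(g.filter_sizes, g.sigmas, g.wavelengths)),
        aspect_ratio=g.aspect_ratio)


def full_gabor_bank(cfg: PipelineConfig, n_orientations: int | None = None) -> FilterBank:
    """All-scale bank (16 scales) used for C2 encoding; ``n_orientations``
    overrides the enhanced-model default (e.g. 4 for the baseline)."""
    g = cfg.gabor
    n_or = n_orientations if n_orientations is not None else g.n_orientations
    return build_gabor_bank(
        orientations=evenly_spaced_orientations(n_or),
        scales=list(range(1, g.n_scales + 1)),
        param_table=list(zip(g.filter_sizes, g.sigmas, g.wavelengths)),
        aspect_ratio=g.aspect_ratio)


def combined_field(stack: np.ndarray, n: int, rgb: np.ndarray | None,
                   band, encoder: EncoderConfig) -> np.ndarray:
    """Stride-1 patch descriptor field of a C1 band stack.

    The 9-block orientation histograms, with the 2x2-block RGB histogram of
    each patch's image footprint appended when the encoder enables color.
    """
    f = descriptor_field(stack, n)
    if encoder.use_color_histogram:
        if rgb is None:
            raise ValueError("combined_field: color histograms need the RGB image")
        cf = color_histogram_field(rgb, band, n, stack.shape[:2],
                                   bins=encoder.color_bins)
        f = np.concatenate([f, cf], axis=-1)
    return f


def descriptors_at(field_arr: np.ndarray, top_lefts: np.ndarray) -> np.ndarray:
    """Descriptor matrix for patches at the given (tl_row, tl_col) positions
    of a precomputed field."""
    tls = np.asarray(top_lefts, dtype=int)
    return field_arr[tls[:, 0], tls[:, 1]]


@dataclass
class LearningImage:
    """Band-1 features of one image, precomputed for the learning loop.

    ``fields`` maps patch size -> stride-1 descriptor field; ``scan`` maps
    patch size -> (centers (P,2 cx,cy), descriptor matrix (P,D)) of the dense
    detection scan at stride n/4.  ``salient_band1`` holds the image's salient
    points mapped onto the band-1 grid in descending-saliency order (discovery
    images only).
    """

    record: ImageRecord
    band1: np.ndarray
    fields: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    salient_band1: np.ndarray | None = None

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def label(self) -> str | None:
        return self.record.label


def scan_top_lefts(grid_shape: tuple, n: int) -> np.ndarray:
    """Dense-scan top-left positions at stride n/4 over the valid grid."""
    gh, gw = grid_shape[0] - n + 1, grid_shape[1] - n + 1
    stride = max(1, n // 4)
    rr, cc = np.meshgrid(np.arange(0, gh, stride), np.arange(0, gw, stride),
                         indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def prepare_learning_image(record: ImageRecord, cfg: PipelineConfig,
                           bank: FilterBank | None = None,
                           with_saliency: bool | None = None) -> LearningImage:
    """Compute band-1 C1, descriptor fields, dense-scan matrices and (for
    discovery images) band-1-mapped salient points for one image."""
    if bank is None:
        bank = learning_gabor_bank(cfg)
    if with_saliency is None:
        with_saliency = record.source_set == "D"
    lab = rgb_to_lab(record)
    s1 = apply_s1(lab.L, bank)
    c1 = pool_c1(s1, bands=cfg.c1.bands, band_indices=[1])
    stack = c1.band_stack(1)

    img = LearningImage(record=record, band1=stack)
    for n in cfg.learning.patch_sizes:
        if stack.shape[0] < n or stack.shape[1] < n:
            continue
        f = combined_field(stack, n, record.pixels, cfg.c1.bands[0], cfg.encoder)
        img.fields[n] = f
        tls = scan_top_lefts(stack.shape[:2], n)
        X = descriptors_at(f, tls)
        centers = np.column_stack([tls[:, 1] + n // 2, tls[:, 0] + n // 2])
        img.scan[n] = (centers, X)

    if with_saliency:
        sal = compute_saliency(record.pixels, config=cfg, s1=s1, lab=lab)
        img.salient_band1 = map_points_to_band1(
            sal.sorted_points[:, :2], cfg.c1.bands, record.shape)
    return img


def prepare_encoding_c1(record: ImageRecord, cfg: PipelineConfig,
                        bank: FilterBank | None = None,
                        n_orientations: int | None = None) -> C1Maps:
    """All-band C1 maps of one image (the C2 encoding input)."""
    if bank is None:
        bank = full_gabor_bank(cfg, n_orientations)
    lab = rgb_to_lab(record)
    s1 = apply_s1(lab.L, bank)
    return pool_c1(s1, bands=cfg.c1.bands)
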