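"""Pipeline configuration: defaults, YAML round-trip, and invariant validation.

Every tunable of the pipeline lives here, grouped the way the pipeline is
staged: Gabor bank, saliency fusion, C1 scale bands, prototype learning,
the original-HMAX baseline, and the descriptor encoder.  All randomness in
the package flows from the single top-level ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError

# Gabor scale table for the 16-scale bank (filter size, envelope width sigma,
# cosine wavelength), one row per scale, filter sizes 7..37 px.  These are the
# standard published HMAX values; the envelope aspect ratio is 0.3.
GABOR_FILTER_SIZES = (7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27, 29, 31, 33, 35, 37)
GABOR_SIGMAS = (2.8, 3.6, 4.5, 5.4, 6.3, 7.3, 8.2, 9.2,
                10.2, 11.3, 12.3, 13.4, 14.6, 15.8, 17.0, 18.2)
GABOR_WAVELENGTHS = (3.5, 4.6, 5.6, 6.8, 7.9, 9.1, 10.3, 11.5,
                     12.7, 14.1, 15.4, 16.8, 18.2, 19.7, 21.2, 22.8)


@dataclass
class GaborConfig:
    """S1 Gabor filter bank parameters (the enhanced model uses 12 orientations)."""

    n_orientations: int = 12
    n_scales: int = 16
    aspect_ratio: float = 0.3
    filter_sizes: tuple = GABOR_FILTER_SIZES
    sigmas: tuple = GABOR_SIGMAS
    wavelengths: tuple = GABOR_WAVELENGTHS

    def validate(self) -> None:
        if self.n_orientations < 1:
            raise ConfigError("gabor.n_orientations: must be a positive integer")
        if not 1 <= self.n_scales <= len(self.filter_sizes):
            raise ConfigError("gabor.n_scales: must be in 1..len(filter_sizes)")
        if not 0 < self.aspect_ratio <= 1:
            raise ConfigError("gabor.aspect_ratio: must satisfy 0 < gamma <= 1")
        if any(s % 2 == 0 for s in self.filter_sizes):
            raise ConfigError("gabor.filter_sizes: all filter sizes must be odd")
        if len(self.sigmas) != len(self.filter_sizes) or \
                len(self.wavelengths) != len(self.filter_sizes):
            raise ConfigError("gabor.sigmas/wavelengths: must match filter_sizes length")
        if any(s <= 0 for s in self.sigmas) or any(w <= 0 for w in self.wavelengths):
            raise ConfigError("gabor.sigmas/wavelengths: must be positive")


@dataclass
class SaliencyConfig:
    """Bottom-up saliency: fine-minus-coarse orientation contrast on the L
    channel plus squared color deviation in Lab, fused with fixed weights."""

    orientation_weight: float = 0.4   # weight of the orientation saliency map
    color_weight: float = 0.6         # weight of the color saliency map
    scale_offset: int = 4             # fine-to-coarse scale interval of the difference
    n_orientations: int = 12
    n_scales: int = 8                 # first 8 Gabor scales enter the contrast sum
    color_blur_sigma: float = 1.0     # Gaussian blur (px) applied to Lab channels

    def validate(self) -> None:
        if self.orientation_weight + self.color_weight <= 0:
            raise ConfigError("saliency.orientation_weight+color_weight: must be > 0")
        if self.scale_offset < 1 or self.scale_offset >= self.n_scales:
            raise ConfigError("saliency.scale_offset: must be in 1..n_scales-1")
        if self.n_orientations < 1 or self.n_scales < 2:
            raise ConfigError("saliency.n_orientations/n_scales: must be positive")
        if self.color_blur_sigma <= 0:
            raise ConfigError("saliency.color_blur_sigma: must be > 0")


@dataclass(frozen=True)
class BandSpec:
    """One C1 scale band: a pair of adjacent S1 scales pooled jointly.

    ``scales`` are 1-based S1 scale indices, ``pool_size`` is the square
    max-pooling neighborhood in pixels, ``step`` the pooling stride.
    """

    scales: tuple
    pool_size: int
    step: int

    def __post_init__(self):
        object.__setattr__(self, "scales", tuple(self.scales))


def default_band_table() -> list:
    """Eight bands over adjacent scale pairs (1,2)..(15,16) with pooling
    neighborhoods 8,10,...,22 px and 50% stride (the standard HMAX table)."""
    return [BandSpec((2 * i + 1, 2 * i + 2), 8 + 2 * i, (8 + 2 * i) // 2)
            for i in range(8)]


@dataclass
class C1Config:
    bands: list = field(default_factory=default_band_table)

    def validate(self) -> None:
        if len(self.bands) != 8:
            raise ConfigError("c1.bands: exactly 8 scale bands are required")
        used = set()
        prev_pool = 0
        for i, b in enumerate(self.bands):
            if len(b.scales) != 2 or b.scales[1] != b.scales[0] + 1:
                raise ConfigError(f"c1.bands[{i}].scales: must be a pair of adjacent scales")
            if used & set(b.scales):
                raise ConfigError(f"c1.bands[{i}].scales: bands must use disjoint scales")
            used |= set(b.scales)
            if b.pool_size <= prev_pool:
                raise ConfigError(f"c1.bands[{i}].pool_size: must increase across bands")
            prev_pool = b.pool_size
            if not 1 <= b.step <= b.pool_size:
                raise ConfigError(f"c1.bands[{i}].step: must satisfy 1 <= step <= pool_size")


@dataclass
class LearningConfig:
    """Unsupervised iterative prototype learning.

    ``initial_patches`` is the number of mid-level patches sampled per patch
    size before clustering (k-means then uses initial_patches/5 clusters);
    ``refresh_count`` / ``purity_count`` are the top-q refresh and top-r purity
    pool sizes; ``top_clusters`` maps each patch size (band-1 C1 units) to the
    number of top-ranked clusters kept.
    """

    initial_patches: int = 2000
    refresh_count: int = 5            # top-q detections kept at each refresh
    purity_count: int = 10            # top-r detections entering the purity mean
    discriminativeness_weight: float = 1.0  # weight of discri in the combined score
    top_clusters: dict = field(default_factory=lambda: {16: 500, 28: 100})
    min_cluster_size: int = 3
    max_iterations: int = 5
    # Total misfit cost per class is svm_regularization/2 (per-sample weights
    # are normalized to sum to 1/2 per class); 20 reproduces the conventional
    # C=0.1 with unnormalized balanced weights at a ~200-patch negative pool.
    svm_regularization: float = 20.0
    svm_tol: float = 1e-8
    hard_negative_threshold: float = -1.0  # margin violators count as hard negatives
    hard_negatives_per_image: int = 10
    detection_threshold: float = 0.0       # firing / refresh decision boundary
    redundancy_cosine: float = 0.5         # classifier cosine merging duplicate clusters
    redundancy_coverage: float = 1.0 / 3.0  # firing-coverage fraction merging clusters

    @property
    def patch_sizes(self) -> tuple:
        return tuple(sorted(self.top_clusters))

    def validate(self) -> None:
        if self.refresh_count >= self.purity_count:
            raise ConfigError("learning.refresh_count: q < r required "
                              "(refresh_count must be < purity_count)")
        if self.min_cluster_size < 1:
            raise ConfigError("learning.min_cluster_size: must be >= 1")
        for name in ("initial_patches", "refresh_count", "purity_count",
                     "max_iterations", "hard_negatives_per_image"):
            if getattr(self, name) < 0 or (name != "max_iterations" and getattr(self, name) == 0):
                raise ConfigError(f"learning.{name}: must be a positive integer")
        if not self.top_clusters:
            raise ConfigError("learning.top_clusters: at least one patch size required")
        for n, g in self.top_clusters.items():
            if n < 4 or n % 4 != 0:
                raise ConfigError(f"learning.top_clusters[{n}]: patch size must be a "
                                  "positive multiple of 4")
            if g < 1:
                raise ConfigError(f"learning.top_clusters[{n}]: cluster count must be >= 1")
        if self.svm_regularization <= 0:
            raise ConfigError("learning.svm_regularization: must be > 0")


@dataclass
class OhmaxConfig:
    """Original-HMAX baseline: random C1 prototypes and Gaussian-like S2 tuning."""

    n_orientations: int = 4
    tuning_sharpness: float = 1.0   # beta of the exp(-beta * distance) response
    n_prototypes: int = 400
    prototype_sizes: tuple = (4, 8, 12, 16)

    def validate(self) -> None:
        if self.n_orientations < 1:
            raise ConfigError("ohmax.n_orientations: must be a positive integer")
        if self.tuning_sharpness <= 0:
            raise ConfigError("ohmax.tuning_sharpness: beta must be > 0")
        if self.n_prototypes < 1:
            raise ConfigError("ohmax.n_prototypes: must be >= 1")
        if not self.prototype_sizes or any(n < 1 for n in self.prototype_sizes):
            raise ConfigError("ohmax.prototype_sizes: must be positive integers")


@dataclass
class EncoderConfig:
    """Patch descriptor options: the 3x3 block orientation histograms are always
    computed; a 2x2-block RGB histogram can be appended."""

    use_color_histogram: bool = False
    color_bins: int = 8

    def validate(self) -> None:
        if self.color_bins < 1:
            raise ConfigError("encoder.color_bins: must be >= 1")


@dataclass
class PipelineConfig:
    gabor: GaborConfig = field(default_factory=GaborConfig)
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)
    c1: C1Config = field(default_factory=C1Config)
    learning: LearningConfig = field(default_factory=LearningConfig)
    ohmax: OhmaxConfig = field(default_factory=OhmaxConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    seed: int = 0
    max_side: int | None = None   # optional resize cap; off by default

    def validate(self) -> "PipelineConfig":
        self.gabor.validate()
        self.saliency.validate()
        self.c1.validate()
        self.learning.validate()
        self.ohmax.validate()
        self.encoder.validate()
        if self.max_side is not None and self.max_side < 64:
            raise ConfigError("max_side: must be >= 64 (or null)")
        return self


_SECTIONS = {
    "gabor": GaborConfig,
    "saliency": SaliencyConfig,
    "c1": C1Config,
    "learning": LearningConfig,
    "ohmax": OhmaxConfig,
    "encoder": EncoderConfig,
}

_TUPLE_FIELDS = {"filter_sizes", "sigmas", "wavelengths", "prototype_sizes", "scales"}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"{section}.{key}: unknown configuration field")
        if key == "bands":
            value = [BandSpec(tuple(b["scales"]), int(b["pool_size"]), int(b["step"]))
                     if isinstance(b, dict) else BandSpec(tuple(b[0]), b[1], b[2])
                     for b in value]
        elif key == "top_clusters":
            value = {int(k): int(v) for k, v in value.items()}
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig from a (possibly partial) nested dict."""
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            sub = data.pop(section)
            if not isinstance(sub, dict):
                raise ConfigError(f"{section}: must be a mapping")
            kwargs[section] = _build_section(cls, sub, section)
    for scalar in ("seed", "max_side"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if data:
        raise ConfigError(f"{sorted(data)[0]}: unknown configuration field")
    return PipelineConfig(**kwargs).validate()


def config_to_dict(cfg: PipelineConfig) -> dict:
    out: dict[str, Any] = {}
    for section, _ in _SECTIONS.items():
        sec = getattr(cfg, section)
        d = dataclasses.asdict(sec)
        if section == "c1":
            d["bands"] = [{"scales": list(b.scales), "pool_size": b.pool_size,
                           "step": b.step} for b in sec.bands]
        for key in list(d):
            if key in _TUPLE_FIELDS:
                d[key] = list(d[key])
        out[section] = d
    out["seed"] = cfg.seed
    out["max_side"] = cfg.max_side
    return out


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config file; unset fields take their defaults.

    An empty (or absent) file yields the full default configuration.
    Invariant violations raise :class:`ConfigError` naming the field.
    """
    if path is None:
        return PipelineConfig().validate()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config: top level must be a mapping")
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
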