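"""Image records, Lab color conversion, dataset loading and D/N splits.

The pipeline consumes two image sets: a *discovery* set D of labeled object
images and a *natural world* set N of object-free background images.  On disk
they follow the layout ``root/discovery/<class_name>/*.png|jpg`` and
``root/natural/*.png|jpg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor

from .exceptions import DatasetLayoutError, InsufficientDataError, ParameterError

_IMAGE_GLOBS = ("*.png", "*.jpg", "*.jpeg")

MIN_SIDE = 64  # must accommodate the largest Gabor filter and band-1 patches


@dataclass
class ImageRecord:
    """A single 8-bit RGB image with provenance.

    ``source_set`` is ``"D"`` for discovery images (which carry a class label)
    or ``"N"`` for natural-world backgrounds.
    """

    id: str
    pixels: np.ndarray
    label: str | None = None
    source_set: str = "D"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ParameterError(
                f"image {self.id!r}: expected 3 color channels, "
                f"got shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ParameterError(
                f"image {self.id!r}: minimum size is {MIN_SIDE}x{MIN_SIDE}, "
                f"got {h}x{w}")
        if self.source_set not in ("D", "N"):
            raise ParameterError(f"image {self.id!r}: source_set must be 'D' or 'N'")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]


@dataclass
class LabImage:
    """CIE L*a*b* planes of an image (D65 white point).  L is in [0, 100]."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.L.shape

    def stack(self) -> np.ndarray:
        return np.stack([self.L, self.a, self.b], axis=-1)


@dataclass
class DatasetSplits:
    """Disjoint halves of D and N used for cross-validated prototype learning."""

    D1: list
    D2: list
    N1: list
    N2: list
    seed: int


def rgb_to_lab(image: ImageRecord | np.ndarray) -> LabImage:
    """Convert an 8-bit sRGB image to CIE L*a*b* (D65, standard companding)."""
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ParameterError(
            f"rgb_to_lab: expected a 3-channel image, got shape {pixels.shape}")
    lab = skcolor.rgb2lab(pixels)
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def lab_to_rgb(lab: LabImage) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`; returns an 8-bit RGB raster."""
    rgb = skcolor.lab2rgb(lab.stack())
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def split_datasets(D: list, N: list, seed: int) -> DatasetSplits:
    """Split D and N into equal-sized disjoint halves, deterministically.

    Odd-sized sets split as ceil(n/2) / floor(n/2).  Raises
    :class:`InsufficientDataError` when either set has fewer than 2 images.
    """
    if len(D) < 2 or len(N) < 2:
        raise InsufficientDataError(
            f"split_datasets: need at least 2 images in each set, "
            f"got |D|={len(D)}, |N|={len(N)}")
    rng = np.random.default_rng(seed)

    def halves(records):
        order = rng.permutation(len(records))
        cut = math.ceil(len(records) / 2)
        first = [records[i] for i in order[:cut]]
        second = [records[i] for i in order[cut:]]
        return first, second

    d1, d2 = halves(D)
    n1, n2 = halves(N)
    return DatasetSplits(D1=d1, D2=d2, N1=n1, N2=n2, seed=seed)


def _load_image(path: Path, max_side: int | None) -> np.ndarray:
    img = Image.open(path).convert("RGB")
    if max_side is not None and max(img.size) > max_side:
        scale = max_side / max(img.size)
        img = img.resize((max(1, round(img.size[0] * scale)),
                          max(1, round(img.size[1] * scale))), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def load_dataset(root: str | Path, max_side: int | None = None):
    """Read the discovery/natural dataset layout into ImageRecords.

    Returns ``(discovery_records, natural_records)``; file order is sorted for
    determinism.  Missing top-level directories raise
    :class:`DatasetLayoutError`.
    """
    root = Path(root)
    disc_dir = root / "discovery"
    nat_dir = root / "natural"
    if not disc_dir.is_dir():
        raise DatasetLayoutError(f"missing directory: {disc_dir}")
    if not nat_dir.is_dir():
        raise DatasetLayoutError(f"missing directory: {nat_dir}")

    discovery = []
    for class_dir in sorted(p for p in disc_dir.iterdir() if p.is_dir()):
        for pattern in _IMAGE_GLOBS:
            for path in sorted(class_dir.glob(pattern)):
                discovery.append(ImageRecord(
                    id=str(path.relative_to(root)),
                    pixels=_load_image(path, max_side),
                    label=class_dir.name, source_set="D"))
    natural = []
    for pattern in _IMAGE_GLOBS:
        for path in sorted(nat_dir.glob(pattern)):
            natural.append(ImageRecord(
                id=str(path.relative_to(root)),
                pixels=_load_image(path, max_side),
                label=None, source_set="N"))
    if not discovery:
        raise DatasetLayoutError(f"no class images found under {disc_dir}")
    return discovery, natural
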