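"""Seeded synthetic discovery/natural image sets with ground-truth masks.

Each discovery scene plants exactly one colored, oriented motif (a "critical
part": cross, ring, stripe grating, or corner) at a random position on a
textured near-achromatic background; natural scenes are motif-free
backgrounds.  The binary mask records exactly the rendered motif pixels, so
saliency localization, cluster recovery and patch provenance are all
checkable against ground truth.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import BandSpec
from .exceptions import ParameterError
from .io import ImageRecord
from .patches import footprint_rect

SHAPES = ("cross", "ring", "grating", "corner")

# Saturated, mutually distinct motif colors on a muted gray background.
PALETTE = ((204, 32, 32), (32, 160, 48), (48, 64, 208),
           (216, 200, 40), (200, 48, 200), (40, 200, 200))

DEFAULT_IMAGE_SIZE = 128   # accommodates band-1 patches of size 28
DEFAULT_MOTIF_SCALE = 48   # stamp side in px; must stay within 64x64


@dataclass
class MotifSpec:
    """One motif class: shape, color, stamp scale (px) and base orientation."""

    motif_id: str
    shape: str
    color: tuple
    scale: int
    orientation: float

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ParameterError(f"unknown motif shape {self.shape!r}")
        if not 8 <= self.scale <= 64:
            raise ParameterError("motif scale must render inside a 64x64 stamp")


@dataclass
class Placement:
    motif_id: str
    x0: int
    y0: int
    stamp_size: int


@dataclass
class SyntheticScene:
    """A rendered scene: image, exact motif-support mask, label, placements.

    ``label_mask`` labels each pixel with 1 + the index of the placement that
    painted it (0 = background), distinguishing motifs that share a scene.
    """

    id: str
    image: np.ndarray
    mask: np.ndarray
    label: str
    placements: list = field(default_factory=list)
    label_mask: np.ndarray | None = None

    @property
    def record(self) -> ImageRecord:
        return ImageRecord(id=self.id, pixels=self.image, label=self.label,
                           source_set="D")


def render_motif(spec: MotifSpec, orientation: float | None = None,
                 scale: int | None = None) -> np.ndarray:
    """Render a motif stamp as a boolean support mask.

    Jittered per-image orientation/scale can override the spec's base values.
    """
    s = int(scale if scale is not None else spec.scale)
    theta = float(orientation if orientation is not None else spec.orientation)
    c = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    th = np.deg2rad(theta)
    u = (xx - c) * np.cos(th) + (yy - c) * np.sin(th)
    v = -(xx - c) * np.sin(th) + (yy - c) * np.cos(th)
    radius = s / 2.0 - 1.0
    bar = s / 12.0
    r = np.hypot(u, v)
    if spec.shape == "cross":
        stamp = ((np.abs(u) <= bar) & (np.abs(v) <= radius)) | \
                ((np.abs(v) <= bar) & (np.abs(u) <= radius))
    elif spec.shape == "ring":
        stamp = (r <= radius) & (r >= radius - s / 6.0)
    elif spec.shape == "grating":
        stamp = (np.cos(2.0 * np.pi * u / (s / 3.0)) > 0.0) & (r <= radius)
    else:  # corner: two bars meeting at a right angle
        lo, hi = -radius, radius
        stamp = ((u >= lo) & (u <= lo + s / 6.0) & (v >= lo) & (v <= hi)) | \
                ((v >= hi - s / 6.0) & (v <= hi) & (u >= lo) & (u <= hi))
    return stamp


def default_motifs(K: int) -> list:
    """K distinct motif classes cycling shapes/colors/orientations.

    Base orientations are chosen so the dominant edge-orientation channels of
    different classes do not coincide (a cross at 0 deg occupies the 0/90
    channels, a 45-deg grating has its stripe edges at 135 deg, a ring is
    isotropic): planted motifs must be distinct in the model's feature space.
    """
    if K > len(PALETTE):
        raise ParameterError(f"at most {len(PALETTE)} distinct motif classes")
    base_orientation = (0.0, 90.0, 45.0, 135.0)
    return [MotifSpec(motif_id=f"m{k}", shape=SHAPES[k % len(SHAPES)],
                      color=PALETTE[k], scale=DEFAULT_MOTIF_SCALE,
                      orientation=base_orientation[k % 4])
            for k in range(K)]


CLUTTER_COLORS = ((150, 120, 90), (96, 128, 150), (170, 170, 110),
                  (120, 150, 120), (160, 110, 130))


def _add_clutter(img: np.ndarray, rng: np.random.Generator,
                 n_elements: tuple = (3, 7)) -> None:
    """Scatter structure fragments over an image in place.

    Natural-world scenes are not bare texture: they contain edges, parallel
    contours, curve fragments and spots — in muted and in saturated colors —
    that share every *individual* low-level feature with object parts without
    forming any planted motif.  Only the specific arrangement of features
    (the motif) is unique to the discovery set, so detectors that key on a
    single orientation or color fire here, which is what makes the
    firing-ratio selectivity score and hard-negative mining informative.
    """
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(int(rng.integers(*n_elements))):
        cx, cy = rng.uniform(10, size - 10, size=2)
        if rng.random() < 0.6:
            color = CLUTTER_COLORS[int(rng.integers(len(CLUTTER_COLORS)))]
        else:
            color = PALETTE[int(rng.integers(len(PALETTE)))]
        color = np.asarray(color, dtype=np.uint8)
        kind = rng.random()
        th = np.deg2rad(rng.uniform(0.0, 180.0))
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        if kind < 0.4:           # single bar
            length = rng.uniform(18.0, 30.0)
            width = rng.uniform(4.0, 8.0)
            mask = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
        elif kind < 0.6:         # pair of parallel bars
            length = rng.uniform(16.0, 26.0)
            width = rng.uniform(3.0, 6.0)
            gap = rng.uniform(6.0, 10.0)
            mask = (np.abs(u) <= length / 2) & \
                   (np.abs(np.abs(v) - gap / 2) <= width / 2)
        elif kind < 0.8:         # arc fragment (quarter-circle-ish)
            radius = rng.uniform(9.0, 14.0)
            thick = rng.uniform(3.0, 6.0)
            r = np.hypot(u, v)
            ang = np.arctan2(v, u)
            span = rng.uniform(0.6, 1.4)
            mask = (np.abs(r - radius) <= thick / 2) & (np.abs(ang) <= span / 2)
        else:                    # blob
            radius = rng.uniform(5.0, 9.0)
            mask = np.hypot(xx - cx, yy - cy) <= radius
        img[mask] = color


def _background(size: int, kind: str, rng: np.random.Generator) -> np.ndarray:
    """Near-achromatic textured background (smooth value noise or an oriented
    gray grating at a non-motif orientation), uint8 HxWx3."""
    if kind == "noise":
        coarse = rng.standard_normal((9, 9))
        smooth = ndimage.zoom(coarse, size / 9.0, order=3)[:size, :size]
        smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
        gray = 115.0 + 20.0 * smooth
    elif kind == "texture":
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        th = np.deg2rad(75.0)
        gray = 118.0 + 18.0 * np.cos(2 * np.pi * (xx * np.cos(th) + yy * np.sin(th)) / 9.0)
    else:
        raise ParameterError(f"unknown background kind {kind!r}")
    img = gray[:, :, None] + rng.uniform(-4.0, 4.0, size=(size, size, 3))
    return np.clip(np.round(img), 30, 220).astype(np.uint8)


def _place_motif(scene_img: np.ndarray, spec: MotifSpec,
                 rng: np.random.Generator,
                 avoid: list | None = None, gap: int = 12,
                 region: tuple | None = None, max_tries: int = 64):
    """Render a jittered stamp, choose a position (optionally keeping a gap
    to earlier bounding boxes), and paint it.  Returns the Placement and
    stamp mask."""
    size = scene_img.shape[0]
    # Jitter stays within half the 15-degree orientation channel spacing so a
    # motif remains a single appearance mode for the recovery ground truth.
    orientation = spec.orientation + rng.uniform(-5.0, 5.0)
    scale = int(round(spec.scale * rng.uniform(0.9, 1.1)))
    stamp = render_motif(spec, orientation=orientation, scale=scale)
    s = stamp.shape[0]
    x_lo, x_hi, y_lo, y_hi = region if region is not None else (0, size, 0, size)
    x_hi, y_hi = min(x_hi, size), min(y_hi, size)
    if x_hi - x_lo < s or y_hi - y_lo < s:
        raise ParameterError("placement region too small for motif stamp")
    for _ in range(max_tries):
        x0 = int(rng.integers(x_lo, x_hi - s + 1))
        y0 = int(rng.integers(y_lo, y_hi - s + 1))
        if avoid and any(not (x0 + s + gap <= ax or ax + asz + gap <= x0
                              or y0 + s + gap <= ay or ay + asz + gap <= y0)
                         for ax, ay, asz in avoid):
            continue
        break
    else:
        raise ParameterError("could not place motif without overlap")
    scene_img[y0:y0 + s, x0:x0 + s][stamp] = np.asarray(spec.color, dtype=np.uint8)
    return Placement(spec.motif_id, x0, y0, s), stamp


def _compose_scene(scene_id: str, label: str, motifs: list, size: int,
                   background: str, rng: np.random.Generator,
                   non_overlapping: bool = True) -> SyntheticScene:
    img = _background(size, background, rng)
    mask = np.zeros((size, size), dtype=bool)
    label_mask = np.zeros((size, size), dtype=np.int32)
    placements = []
    boxes = []
    # Two-motif scenes put each motif in its own image half (random split
    # axis and order) so both parts keep uncontaminated local context.
    regions = [None] * len(motifs)
    if len(motifs) == 2:
        half = size // 2
        if rng.random() < 0.5:   # top/bottom halves
            lo, hi = (0, size, 0, half), (0, size, half, size)
        else:                    # left/right halves
            lo, hi = (0, half, 0, size), (half, size, 0, size)
        regions = [lo, hi] if rng.random() < 0.5 else [hi, lo]
    for spec, region in zip(motifs, regions):
        placement, stamp = _place_motif(img, spec, rng,
                                        avoid=boxes if non_overlapping else None,
                                        region=region)
        s = placement.stamp_size
        region = (slice(placement.y0, placement.y0 + s),
                  slice(placement.x0, placement.x0 + s))
        mask[region] |= stamp
        label_mask[region][stamp] = len(placements) + 1
        placements.append(placement)
        boxes.append((placement.x0, placement.y0, s))
    return SyntheticScene(id=scene_id, image=img, mask=mask, label=label,
                          placements=placements, label_mask=label_mask)


def generate_dataset(K: int, per_class: int, background: str = "noise",
                     seed: int = 0, image_size: int = DEFAULT_IMAGE_SIZE,
                     n_natural: int | None = None,
                     motifs: list | None = None):
    """Generate a K-class discovery set and a motif-free natural set.

    Each discovery scene contains exactly one motif of its class with random
    position and orientation/scale jitter.  Returns
    ``(discovery_scenes, natural_records)``; byte-identical given the seed.
    """
    if K < 2:
        raise ParameterError(f"generate_dataset: K must be >= 2, got {K}")
    rng = np.random.default_rng(seed)
    motifs = motifs if motifs is not None else default_motifs(K)
    scenes = []
    for k in range(K):
        label = f"class{k}_{motifs[k].shape}"
        for i in range(per_class):
            scenes.append(_compose_scene(f"{label}_{i:03d}", label, [motifs[k]],
                                         image_size, background, rng))
    if n_natural is None:
        n_natural = per_class
    natural = [_natural_record(f"natural_{i:03d}", image_size, background, rng)
               for i in range(n_natural)]
    return scenes, natural


def _natural_record(record_id: str, image_size: int, background: str,
                    rng: np.random.Generator) -> ImageRecord:
    pixels = _background(image_size, background, rng)
    _add_clutter(pixels, rng)
    return ImageRecord(id=record_id, pixels=pixels, label=None, source_set="N")


def generate_shared_motif_dataset(seed: int = 0, per_class: int = 10,
                                  background: str = "noise",
                                  image_size: int = DEFAULT_IMAGE_SIZE,
                                  n_natural: int | None = None):
    """Two classes that share one motif: every scene of class A and class B
    contains the shared motif m0 plus a class-unique motif.

    The shared motif's id is ``"m0"``; per-pixel provenance lives in each
    scene's ``label_mask`` / ``placements``.
    """
    rng = np.random.default_rng(seed)
    shared = MotifSpec("m0", "cross", PALETTE[0], 44, 0.0)
    unique = {"A": MotifSpec("mA", "ring", PALETTE[1], 44, 90.0),
              "B": MotifSpec("mB", "grating", PALETTE[2], 44, 45.0)}
    scenes = []
    for label in ("A", "B"):
        for i in range(per_class):
            scenes.append(_compose_scene(f"{label}_{i:03d}", label,
                                         [shared, unique[label]],
                                         image_size, background, rng))
    if n_natural is None:
        n_natural = per_class
    natural = [_natural_record(f"natural_{i:03d}", image_size, background, rng)
               for i in range(n_natural)]
    return scenes, natural


def scenes_to_records(scenes: list) -> list:
    return [s.record for s in scenes]


def patch_ground_truth_label(scene: SyntheticScene, center: tuple, n: int,
                             band: BandSpec, min_overlap: int = 1) -> str:
    """Ground-truth label of a band-1 patch: the scene's class when the patch
    footprint overlaps the motif mask (>= min_overlap pixels), else
    'background'."""
    y0, y1, x0, x1 = footprint_rect(center, n, band)
    h, w = scene.mask.shape
    overlap = scene.mask[max(0, y0):min(h, y1), max(0, x0):min(w, x1)].sum()
    return scene.label if overlap >= min_overlap else "background"


def patch_motif_id(scene: SyntheticScene, center: tuple, n: int,
                   band: BandSpec) -> str | None:
    """The motif id whose pixels dominate a patch footprint, or None."""
    y0, y1, x0, x1 = footprint_rect(center, n, band)
    h, w = scene.label_mask.shape
    crop = scene.label_mask[max(0, y0):min(h, y1), max(0, x0):min(w, x1)]
    counts = np.bincount(crop.ravel(), minlength=len(scene.placements) + 1)
    counts[0] = 0
    if counts.sum() == 0:
        return None
    return scene.placements[int(counts.argmax()) - 1].motif_id


def write_dataset(scenes: list, natural: list, out_dir: str | Path) -> None:
    """Write the standard dataset layout plus masks/ and truth.json."""
    out = Path(out_dir)
    (out / "natural").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    truth = {}
    for scene in scenes:
        class_dir = out / "discovery" / scene.label
        class_dir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(scene.image).save(class_dir / f"{scene.id}.png")
        Image.fromarray((scene.mask * 255).astype(np.uint8)).save(
            out / "masks" / f"{scene.id}.png")
        truth[scene.id] = {
            "label": scene.label,
            "placements": [{"motif_id": p.motif_id, "x0": p.x0, "y0": p.y0,
                            "stamp_size": p.stamp_size}
                           for p in scene.placements]}
    for rec in natural:
        Image.fromarray(rec.pixels).save(out / "natural" / f"{rec.id}.png")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
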