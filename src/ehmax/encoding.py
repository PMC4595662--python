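"""S2 detector maps and position-encoded C2 features.

Enhanced model: every learned cluster classifier slides over the descriptor
field of each C1 scale band (stride 1); each S2 unit is the SVM score of the
window under that classifier.  C2 takes, per cluster, the global maximum over
bands and positions plus the relative coordinates (x_max/W, y_max/L) of that
maximum in its map — 3 values per cluster, 3*Gamma per image.

Baseline (original HMAX): prototypes are random raw C1 crops and each S2 unit
is a Gaussian-like tuning response exp(-beta * ||X - P||) over the flattened
window including all orientations; C2 keeps only the per-prototype maxima
(M values, no positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .c1 import C1Maps
from .config import EncoderConfig, PipelineConfig
from .exceptions import EncodingError, ParameterError
from .features import combined_field
from .learning import ClusterBank


@dataclass
class S2ScoreMaps:
    """Detector-score rasters indexed by (unit_id, band_index).

    ``unit_id`` is a cluster id (enhanced model) or prototype index
    (baseline).  Bands whose C1 grid is smaller than the unit's patch size
    have no map.  ``unit_ids`` preserves the bank/prototype order.
    """

    maps: dict
    unit_ids: list

    def maps_for(self, unit_id) -> dict:
        return {b: m for (u, b), m in self.maps.items() if u == unit_id}


@dataclass
class C2Feature:
    """Per-image C2 vector; ``per_unit`` lists (max_score, x_rel, y_rel) or,
    for the baseline, plain maxima."""

    vector: np.ndarray
    per_unit: list


def compute_s2_ehmax(c1: C1Maps, bank: ClusterBank,
                     encoder: EncoderConfig | None = None,
                     rgb: np.ndarray | None = None) -> S2ScoreMaps:
    """Score every valid window of every band under every cluster classifier.

    A (cluster, band) pair whose band grid cannot fit the cluster's patch is
    skipped (no map) and later excluded from the C2 maximum.
    """
    if bank.gamma == 0:
        raise ParameterError("compute_s2_ehmax: empty cluster bank")
    encoder = encoder or EncoderConfig()
    maps = {}
    for bi in c1.band_indices:
        stack = c1.band_stack(bi)
        for n in bank.sizes:
            if stack.shape[0] < n or stack.shape[1] < n:
                continue
            f = combined_field(stack, n, rgb, c1.bands[bi - 1], encoder)
            gh, gw = f.shape[:2]
            X = f.reshape(gh * gw, -1)
            for cluster in bank.of_size(n):
                scores = cluster.classifier.score(X).reshape(gh, gw)
                maps[(cluster.id, bi)] = scores
    return S2ScoreMaps(maps=maps, unit_ids=[c.id for c in bank.clusters])


def compute_c2(s2: S2ScoreMaps) -> C2Feature:
    """Global max per unit with relative position encoding.

    Per unit: the maximum score over all its band maps; x_rel = column/W,
    y_rel = row/L of the (zero-based) argmax within the winning map.  Ties
    resolve to the lowest band, then row-major within the map.  A unit with
    no map at all raises :class:`EncodingError`.
    """
    entries, per_unit = [], []
    for uid in s2.unit_ids:
        unit_maps = s2.maps_for(uid)
        if not unit_maps:
            raise EncodingError(f"compute_c2: no S2 map for unit {uid}")
        best = None
        for bi in sorted(unit_maps):
            m = unit_maps[bi]
            flat_idx = int(np.argmax(m))
            val = float(m.ravel()[flat_idx])
            if best is None or val > best[0]:
                row, col = divmod(flat_idx, m.shape[1])
                best = (val, bi, row, col, m.shape)
        val, _, row, col, (L, W) = best
        x_rel, y_rel = col / W, row / L
        entries.extend([val, x_rel, y_rel])
        per_unit.append((val, x_rel, y_rel))
    return C2Feature(vector=np.asarray(entries), per_unit=per_unit)


@dataclass
class PrototypeSet:
    """Random raw C1 prototypes of the baseline model."""

    prototypes: list   # list of (image_id, (tl_row, tl_col), n, tensor)
    sizes: tuple
    beta: float = 1.0

    @property
    def M(self) -> int:
        return len(self.prototypes)


def sample_prototypes_random(c1_stacks: dict, M: int, sizes, seed: int,
                             beta: float = 1.0) -> PrototypeSet:
    """Sample M prototypes uniformly over images, positions and sizes.

    ``c1_stacks`` maps image_id -> band-1 stack (H', W', O).  Sampling is
    without replacement over the set of all valid (image, size, position)
    crops; requesting more raises :class:`ParameterError`.
    """
    sizes = tuple(sizes)
    slots = []
    for image_id in sorted(c1_stacks):
        h, w = c1_stacks[image_id].shape[:2]
        for n in sizes:
            if h >= n and w >= n:
                slots.append((image_id, n, h - n + 1, w - n + 1))
    total = sum(gh * gw for _, _, gh, gw in slots)
    if M > total:
        raise ParameterError(
            f"sample_prototypes_random: M={M} exceeds {total} available positions")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(total, size=M, replace=False))
    protos = []
    base = 0
    it = iter(zip(slots, np.cumsum([gh * gw for _, _, gh, gw in slots])))
    (image_id, n, gh, gw), upper = next(it)
    for flat in chosen:
        while flat >= upper:
            base = upper
            (image_id, n, gh, gw), upper = next(it)
        r, c = divmod(int(flat - base), gw)
        tensor = c1_stacks[image_id][r:r + n, c:c + n, :].copy()
        protos.append((image_id, (r, c), n, tensor))
    order = rng.permutation(M)  # decouple prototype order from image order
    protos = [protos[i] for i in order]
    return PrototypeSet(prototypes=protos, sizes=sizes, beta=beta)


def compute_s2_ohmax(c1: C1Maps, protos: PrototypeSet,
                     beta: float | None = None) -> S2ScoreMaps:
    """Gaussian-like tuning maps exp(-beta * ||X - P||) per prototype and band.

    The norm is Euclidean over the flattened window including all orientation
    channels, computed directly from the windowed differences (a window equal
    to its prototype responds exactly 1).
    """
    if protos.M == 0:
        raise ParameterError("compute_s2_ohmax: empty prototype set")
    beta = protos.beta if beta is None else beta
    by_size = {}
    for idx, (_, _, n, tensor) in enumerate(protos.prototypes):
        by_size.setdefault(n, []).append((idx, tensor))
    maps = {}
    for bi in c1.band_indices:
        stack = c1.band_stack(bi)
        h, w, _ = stack.shape
        for n, group in by_size.items():
            if h < n or w < n:
                continue
            p_stack = np.stack([t for _, t in group])  # (Mn, n, n, O)
            gh, gw = h - n + 1, w - n + 1
            dist = np.empty((gh, gw, len(group)))
            for r in range(gh):
                for c in range(gw):
                    diff = stack[r:r + n, c:c + n, :][None] - p_stack
                    dist[r, c] = np.sqrt((diff * diff).sum(axis=(1, 2, 3)))
            resp = np.exp(-beta * dist)
            for j, (idx, _) in enumerate(group):
                maps[(idx, bi)] = resp[:, :, j]
    return S2ScoreMaps(maps=maps, unit_ids=list(range(protos.M)))


def compute_c2_ohmax(s2: S2ScoreMaps) -> C2Feature:
    """Baseline C2: per-prototype global maximum only (length M, no positions)."""
    vals = []
    for uid in s2.unit_ids:
        unit_maps = s2.maps_for(uid)
        if not unit_maps:
            raise EncodingError(f"compute_c2_ohmax: no S2 map for prototype {uid}")
        vals.append(max(float(m.max()) for m in unit_maps.values()))
    return C2Feature(vector=np.asarray(vals), per_unit=list(vals))


def encode_image_ehmax(c1: C1Maps, bank: ClusterBank,
                       encoder: EncoderConfig | None = None,
                       rgb: np.ndarray | None = None,
                       ablate_position: bool = False) -> np.ndarray:
    """Convenience: C1 -> S2 -> C2 vector (3*Gamma, or Gamma when the position
    components are ablated)."""
    c2 = compute_c2(compute_s2_ehmax(c1, bank, encoder=encoder, rgb=rgb))
    if ablate_position:
        return c2.vector.reshape(-1, 3)[:, 0].copy()
    return c2.vector


def ablate_position_features(features: np.ndarray) -> np.ndarray:
    """Drop the (x_rel, y_rel) components of stacked C2 rows: (N, 3G) -> (N, G)."""
    X = np.atleast_2d(features)
    if X.shape[1] % 3 != 0:
        raise ParameterError("ablate_position_features: feature length not 3*Gamma")
    return X.reshape(X.shape[0], -1, 3)[:, :, 0].copy()
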