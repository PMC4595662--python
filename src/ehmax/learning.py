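"""Unsupervised iterative prototype learning.

Mid-level patches sampled from the salient regions of one discovery half are
k-means clustered (S patches -> S/5 clusters); each cluster then alternates
between (a) training a weighted linear SVM against random natural-world
patches, (b) mining hard negatives with a dense band-1 scan of the natural
half and retraining, and (c) refreshing its members with the top-q detections
in the *other* discovery half, swapping the halves every iteration.  Clusters
whose refresh yields fewer than 3 detections are deleted.  Surviving clusters
are ranked by

    score = purity~ + lambda3 * discri~

where purity is the mean SVM score of the cluster's top-r detections in D,
discri = FireNum_D / (FireNum_D + FireNum_N) is its firing-rate ratio, and ~
denotes standardization across the clusters of one patch size.  The top
Gamma_n clusters per patch size form the learned bank.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.svm import LinearSVC

from .config import LearningConfig, PipelineConfig
from .exceptions import ConfigError, InsufficientDataError, LearningFailureError, ParameterError
from .features import (LearningImage, descriptors_at, learning_gabor_bank,
                       prepare_learning_image)
from .io import DatasetSplits
from .patches import sample_patch_centers
from .saliency import normalize_map

logger = logging.getLogger(__name__)


@dataclass
class LinearClassifier:
    """A linear decision function w . x + b, positive toward cluster members."""

    weights: np.ndarray
    bias: float

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.bias


@dataclass(frozen=True)
class Member:
    """Provenance of one member patch: source image and band-1 center."""

    image_id: str
    cx: int
    cy: int


@dataclass
class Cluster:
    id: int
    patch_size: int
    members: list
    descriptors: np.ndarray
    classifier: LinearClassifier | None = None
    purity: float | None = None
    discri: float | None = None
    score: float | None = None
    deleted: bool = False
    firing_detections: list = field(default_factory=list)

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass
class ClusterBank:
    """The learned bank: top-ranked clusters across patch sizes, ordered by
    descending score within each size (smaller sizes first)."""

    clusters: list
    top_by_size: dict = field(default_factory=dict)

    @property
    def gamma(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list:
        return sorted({c.patch_size for c in self.clusters})

    def of_size(self, n: int) -> list:
        return [c for c in self.clusters if c.patch_size == n]


def train_cluster_classifier(positives: np.ndarray, negatives: np.ndarray,
                             cfg: LearningConfig) -> LinearClassifier:
    """Weighted linear SVM separating a cluster's patches from negatives.

    Per-sample weights give each class a total weight of 1/2 (inversely
    proportional to class size), which makes the fit invariant to duplicating
    either class.  Deterministic given the inputs.
    """
    pos = np.atleast_2d(np.asarray(positives, dtype=float))
    neg = np.atleast_2d(np.asarray(negatives, dtype=float))
    if len(neg) == 0:
        raise InsufficientDataError("train_cluster_classifier: empty negative set")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    w = np.concatenate([np.full(len(pos), 0.5 / len(pos)),
                        np.full(len(neg), 0.5 / len(neg))])
    svc = LinearSVC(C=cfg.svm_regularization, tol=cfg.svm_tol, dual=False,
                    max_iter=20000, random_state=0)
    svc.fit(X, y, sample_weight=w)
    return LinearClassifier(weights=svc.coef_[0].copy(), bias=float(svc.intercept_[0]))


def mine_hard_negatives(classifier: LinearClassifier, n_images: list, n: int,
                        threshold: float = -1.0, per_image: int = 10) -> np.ndarray:
    """Dense band-1 scan of natural images for high-scoring (hard) negatives.

    Returns the descriptor matrix of detections whose score exceeds
    ``threshold``, capped at the top ``per_image`` per image; may be empty.
    """
    rows = []
    for img in n_images:
        if n not in img.scan:
            continue
        _, X = img.scan[n]
        scores = classifier.score(X)
        idx = np.flatnonzero(scores > threshold)
        if idx.size == 0:
            continue
        top = idx[np.argsort(-scores[idx], kind="stable")][:per_image]
        rows.append(X[top])
    if not rows:
        return np.empty((0, 0))
    return np.vstack(rows)


def refresh_cluster(classifier: LinearClassifier, d_images: list, n: int,
                    q: int = 5, min_size: int = 3,
                    threshold: float = 0.0, min_dist: float | None = None):
    """Replace a cluster's members with its top-q detections in the other
    discovery half.

    Detections come from the dense band-1 scan (stride n/4), must score above
    ``threshold``, and are kept greedily in descending score order subject to
    within-image center spacing >= n/4 (the sampling overlap constraint).
    The q highest-scoring such detections become the new members.  Returns
    ``(members, descriptors)`` or ``None`` when fewer than ``min_size``
    detections survive (the cluster is then deleted).
    """
    if min_dist is None:
        min_dist = n / 4.0
    detections = []
    for img in d_images:
        if n not in img.scan:
            continue
        centers, X = img.scan[n]
        scores = classifier.score(X)
        for i in np.flatnonzero(scores > threshold):
            detections.append((float(scores[i]), img.id,
                               int(centers[i, 0]), int(centers[i, 1]), X[i]))
    detections.sort(key=lambda d: (-d[0], d[1], d[3], d[2]))
    kept, vecs = [], []
    d2 = min_dist ** 2
    for score, image_id, cx, cy, vec in detections:
        if len(kept) >= q:
            break
        clash = any(m.image_id == image_id
                    and (m.cx - cx) ** 2 + (m.cy - cy) ** 2 < d2 for m in kept)
        if not clash:
            kept.append(Member(image_id, cx, cy))
            vecs.append(vec)
    if len(kept) < min_size:
        return None
    return kept, np.asarray(vecs)


def init_clusters(descriptors: np.ndarray, members: list, k: int, seed: int,
                  patch_size: int, min_size: int = 3, id_start: int = 0) -> list:
    """k-means partition of the initial patches; clusters smaller than
    ``min_size`` are dropped immediately."""
    if k < 1:
        raise ParameterError(f"init_clusters: k must be >= 1, got {k}")
    X = np.asarray(descriptors, dtype=float)
    if len(X) < k:
        raise InsufficientDataError(
            f"init_clusters: {len(X)} descriptors for k={k} clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    clusters = []
    next_id = id_start
    for lbl in range(k):
        idx = np.flatnonzero(labels == lbl)
        if idx.size < min_size:
            continue
        clusters.append(Cluster(id=next_id, patch_size=patch_size,
                                members=[members[i] for i in idx],
                                descriptors=X[idx]))
        next_id += 1
    return clusters


def score_cluster(cluster: Cluster, d_images: list, n_images: list,
                  r: int = 10, q: int = 5,
                  detection_threshold: float = 0.0) -> tuple:
    """Raw purity and discriminativeness of a cluster.

    purity: mean SVM score of the top-r dense-scan detections across D;
    discri: FireNum_D / (FireNum_D + FireNum_N) with firing counted per
    detection above the decision threshold.  Requires r > q.
    """
    if r <= q:
        raise ConfigError("learning.purity_count: r must exceed refresh_count q")
    n = cluster.patch_size
    clf = cluster.classifier

    def all_scores(images):
        parts = [clf.score(img.scan[n][1]) for img in images if n in img.scan]
        return np.concatenate(parts) if parts else np.empty(0)

    d_scores = all_scores(d_images)
    n_scores = all_scores(n_images)
    if d_scores.size == 0:
        purity = 0.0
    else:
        top = np.sort(d_scores)[::-1][:r]
        purity = float(top.mean())
    fire_d = int((d_scores > detection_threshold).sum())
    fire_n = int((n_scores > detection_threshold).sum())
    discri = fire_d / (fire_d + fire_n) if (fire_d + fire_n) > 0 else 0.0
    return purity, discri


def cluster_firing_detections(cluster: Cluster, d_images: list,
                              threshold: float = 0.0) -> list:
    """All (image_id, cx, cy) locations where a cluster's detector fires
    (dense-scan score above the decision threshold) across D — the same
    detections FireNum_D counts."""
    n = cluster.patch_size
    dets = []
    for img in d_images:
        if n not in img.scan:
            continue
        centers, X = img.scan[n]
        scores = cluster.classifier.score(X)
        for i in np.flatnonzero(scores > threshold):
            dets.append((img.id, int(centers[i, 0]), int(centers[i, 1])))
    return dets


def _coverage(detections: list, kept: dict, n: int) -> float:
    """Fraction of detections lying within n/2 cells (per axis) of a kept
    detection in the same image — i.e. whose patch footprint shares at least
    half its extent with a kept footprint (``kept`` maps image_id -> (K, 2)
    centers)."""
    if not detections:
        return 0.0
    radius = n / 2.0
    count = 0
    for img_id, cx, cy in detections:
        centers = kept.get(img_id)
        if centers is not None and \
                bool(((np.abs(centers[:, 0] - cx) < radius)
                      & (np.abs(centers[:, 1] - cy) < radius)).any()):
            count += 1
    return count / len(detections)


def suppress_redundant_clusters(clusters: list, cosine_limit: float = 0.5,
                                coverage_limit: float = 0.5) -> None:
    """Drop clusters that repeat memory the bank already holds.

    Clusters are visited in descending score order and dropped when either
    redundancy signal fires against the kept set: (a) their classifier weight
    vector is nearly parallel (cosine above ``cosine_limit``) to a kept
    cluster's — the same appearance template, even when its detections land
    on different images — or (b) more than ``coverage_limit`` of their firing
    locations are already covered by kept clusters' firings (footprints
    intersecting in the same image) — a detector responding to image regions
    the bank already explains.
    """
    for n in sorted({c.patch_size for c in clusters}):
        group = sorted((c for c in clusters if c.patch_size == n and not c.deleted),
                       key=lambda c: (-(c.score if c.score is not None else -math.inf),
                                      c.id))
        kept_w: list = []
        kept_dets: dict = {}
        for cluster in group:
            w = cluster.classifier.weights
            w = w / (np.linalg.norm(w) or 1.0)
            parallel = any(float(w @ other) > cosine_limit for other in kept_w)
            covered = _coverage(cluster.firing_detections, kept_dets, n=n) \
                > coverage_limit
            if parallel or covered:
                cluster.deleted = True
                continue
            kept_w.append(w)
            for img_id, cx, cy in cluster.firing_detections:
                prev = kept_dets.get(img_id)
                row = np.array([[cx, cy]])
                kept_dets[img_id] = row if prev is None else np.vstack([prev, row])


def select_top(clusters: list, top_by_size: dict) -> ClusterBank:
    """Keep the Gamma_n highest-scoring clusters per patch size.

    Ties break toward the lower cluster id.  When fewer clusters survive than
    requested, all survivors are returned with a warning and the recorded
    count is adjusted.
    """
    selected, actual = [], {}
    for n in sorted(top_by_size):
        pool = sorted((c for c in clusters if c.patch_size == n and not c.deleted),
                      key=lambda c: (-(c.score if c.score is not None else -math.inf),
                                     c.id))
        want = top_by_size[n]
        if len(pool) < want:
            warnings.warn(f"only {len(pool)} clusters of size {n} survive "
                          f"(requested {want})", stacklevel=2)
        take = pool[:want]
        actual[n] = len(take)
        selected.extend(take)
    return ClusterBank(clusters=selected, top_by_size=actual)


def _standardize_scores(clusters: list, lambda3: float) -> None:
    """Combine z-normalized purity and discriminativeness per patch size."""
    for n in sorted({c.patch_size for c in clusters}):
        group = [c for c in clusters if c.patch_size == n and not c.deleted]
        if not group:
            continue
        pur = normalize_map(np.array([c.purity for c in group]))
        dis = normalize_map(np.array([c.discri for c in group]))
        for c, p, d in zip(group, pur, dis):
            c.score = float(p + lambda3 * d)


def _initial_positive_patches(d_images: list, cfg: PipelineConfig, n: int):
    """Saliency-guided initial sampling over one discovery half."""
    lrn = cfg.learning
    per_image = max(1, math.ceil(lrn.initial_patches / max(1, len(d_images))))
    members, rows = [], []
    for img in d_images:
        if n not in img.fields or img.salient_band1 is None:
            continue
        centers = sample_patch_centers(img.band1.shape[:2], n,
                                       max_count=per_image,
                                       sorted_points=img.salient_band1)
        for cx, cy in centers:
            members.append(Member(img.id, cx, cy))
        tls = np.array([[cy - n // 2, cx - n // 2] for cx, cy in centers], dtype=int)
        if len(tls):
            rows.append(descriptors_at(img.fields[n], tls))
    if not rows:
        return [], np.empty((0, 0))
    X = np.vstack(rows)[:lrn.initial_patches]
    return members[:lrn.initial_patches], X


def _random_negative_patches(n_images: list, cfg: PipelineConfig, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Random initial sampling (overlap-constrained) over one natural half."""
    lrn = cfg.learning
    per_image = max(1, math.ceil(lrn.initial_patches / max(1, len(n_images))))
    rows = []
    for img in n_images:
        if n not in img.fields:
            continue
        centers = sample_patch_centers(img.band1.shape[:2], n,
                                       max_count=per_image, rng=rng)
        tls = np.array([[cy - n // 2, cx - n // 2] for cx, cy in centers], dtype=int)
        if len(tls):
            rows.append(descriptors_at(img.fields[n], tls))
    if not rows:
        return np.empty((0, 0))
    return np.vstack(rows)[:lrn.initial_patches]


def prepare_split_features(splits: DatasetSplits, cfg: PipelineConfig) -> dict:
    """Compute LearningImage features for every image of all four subsets."""
    bank = learning_gabor_bank(cfg)
    out = {}
    for name in ("D1", "D2", "N1", "N2"):
        records = getattr(splits, name)
        out[name] = [prepare_learning_image(r, cfg, bank=bank) for r in records]
    return out


def run_learning(splits: DatasetSplits, cfg: PipelineConfig,
                 features: dict | None = None) -> ClusterBank:
    """Full iterative prototype learning over prepared D/N splits.

    ``features`` may carry precomputed :class:`LearningImage` lists (keys
    D1, D2, N1, N2); otherwise they are computed here.  Deterministic given
    ``cfg.seed``.  Raises :class:`LearningFailureError` when no cluster
    survives.
    """
    lrn = cfg.learning
    if features is None:
        features = prepare_split_features(splits, cfg)
    d_halves = (features["D1"], features["D2"])
    n_halves = (features["N1"], features["N2"])
    all_d = d_halves[0] + d_halves[1]
    all_n = n_halves[0] + n_halves[1]
    rng = np.random.default_rng(cfg.seed)

    all_clusters = []
    id_start = 0
    for n in lrn.patch_sizes:
        members, X = _initial_positive_patches(d_halves[0], cfg, n)
        if len(members) < lrn.min_cluster_size:
            logger.warning("patch size %d: only %d initial patches; skipping",
                           n, len(members))
            continue
        negatives = {
            0: _random_negative_patches(n_halves[0], cfg, n, rng),
            1: _random_negative_patches(n_halves[1], cfg, n, rng),
        }
        if negatives[0].size == 0:
            raise InsufficientDataError(
                f"patch size {n}: no negative patches could be sampled")
        k = max(1, math.ceil(len(members) / 5))
        clusters = init_clusters(X, members, k=k, seed=int(rng.integers(2 ** 31)),
                                 patch_size=n, min_size=lrn.min_cluster_size,
                                 id_start=id_start)
        id_start += k
        logger.info("patch size %d: %d initial patches -> %d clusters",
                    n, len(members), len(clusters))

        # Refresh alternates between the discovery halves, so a stabilized
        # cluster repeats the member set it had two iterations earlier; track
        # per-parity member sets to detect convergence.
        history: dict = {c.id: {} for c in clusters}
        stable: dict = {c.id: False for c in clusters}
        for it in range(lrn.max_iterations):
            half = it % 2
            n_train = n_halves[half]
            d_refresh = d_halves[1 - half]
            neg_pool = negatives[half]
            survivors = 0
            for cluster in clusters:
                if cluster.deleted:
                    continue
                clf = train_cluster_classifier(cluster.descriptors, neg_pool, lrn)
                hard = mine_hard_negatives(clf, n_train, n,
                                           threshold=lrn.hard_negative_threshold,
                                           per_image=lrn.hard_negatives_per_image)
                if hard.size:
                    clf = train_cluster_classifier(
                        cluster.descriptors, np.vstack([neg_pool, hard]), lrn)
                refreshed = refresh_cluster(clf, d_refresh, n,
                                            q=lrn.refresh_count,
                                            min_size=lrn.min_cluster_size,
                                            threshold=lrn.detection_threshold)
                cluster.classifier = clf
                if refreshed is None:
                    cluster.deleted = True
                    continue
                new_members, new_X = refreshed
                stable[cluster.id] = history[cluster.id].get(half) == \
                    frozenset(new_members)
                history[cluster.id][half] = frozenset(new_members)
                cluster.members = new_members
                cluster.descriptors = new_X
                survivors += 1
            # Clusters whose refreshed member sets coincide encode the same
            # memory; keep the lowest id and drop the redundant copies.
            seen: dict = {}
            for cluster in clusters:
                if cluster.deleted:
                    continue
                key = cluster.member_set
                if key in seen:
                    cluster.deleted = True
                    survivors -= 1
                else:
                    seen[key] = cluster.id
            logger.info("patch size %d iteration %d: %d clusters survive",
                        n, it + 1, survivors)
            if it >= 1 and all(stable[c.id] for c in clusters if not c.deleted):
                break

        alive = [c for c in clusters if not c.deleted]
        # With max_iterations=0 the k-means clusters are scored unrefined;
        # they still need a classifier for Eq-style purity scoring.
        for cluster in alive:
            if cluster.classifier is None:
                cluster.classifier = train_cluster_classifier(
                    cluster.descriptors, negatives[0], lrn)
        for cluster in alive:
            cluster.purity, cluster.discri = score_cluster(
                cluster, all_d, all_n, r=lrn.purity_count, q=lrn.refresh_count,
                detection_threshold=lrn.detection_threshold)
            cluster.firing_detections = cluster_firing_detections(
                cluster, all_d, threshold=lrn.detection_threshold)
        all_clusters.extend(clusters)

    survivors = [c for c in all_clusters if not c.deleted]
    if not survivors:
        raise LearningFailureError("run_learning: no cluster survived refinement")
    _standardize_scores(survivors, lrn.discriminativeness_weight)
    suppress_redundant_clusters(survivors, cosine_limit=lrn.redundancy_cosine,
                                coverage_limit=lrn.redundancy_coverage)
    survivors = [c for c in survivors if not c.deleted]
    return select_top(survivors, lrn.top_clusters)


# -- serialization -----------------------------------------------------------

def save_bank(bank: ClusterBank, out_dir: str | Path) -> None:
    """Write a cluster bank as clusters.json + one weight vector file per
    classifier (plain text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"top_by_size": {str(k): v for k, v in bank.top_by_size.items()},
            "clusters": []}
    for c in bank.clusters:
        wfile = f"weights_{c.id:04d}.txt"
        np.savetxt(out / wfile, c.classifier.weights)
        meta["clusters"].append({
            "id": c.id, "patch_size": c.patch_size,
            "purity": c.purity, "discri": c.discri, "score": c.score,
            "bias": c.classifier.bias, "weights_file": wfile,
            "members": [{"image_id": m.image_id, "cx": m.cx, "cy": m.cy}
                        for m in c.members],
        })
    (out / "clusters.json").write_text(json.dumps(meta, indent=1))


def load_bank(in_dir: str | Path) -> ClusterBank:
    src = Path(in_dir)
    meta = json.loads((src / "clusters.json").read_text())
    clusters = []
    for cm in meta["clusters"]:
        weights = np.loadtxt(src / cm["weights_file"])
        clusters.append(Cluster(
            id=cm["id"], patch_size=cm["patch_size"],
            members=[Member(m["image_id"], m["cx"], m["cy"]) for m in cm["members"]],
            descriptors=np.empty((0, 0)),
            classifier=LinearClassifier(weights=np.atleast_1d(weights),
                                        bias=cm["bias"]),
            purity=cm["purity"], discri=cm["discri"], score=cm["score"]))
    top = {int(k): v for k, v in meta["top_by_size"].items()}
    return ClusterBank(clusters=clusters, top_by_size=top)
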