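"""Iterative prototype learning: clustering, detectors, refresh, scoring."""

import types

import numpy as np
import pytest

from ehmax.config import LearningConfig
from ehmax.exceptions import (ConfigError, InsufficientDataError,
                              ParameterError)
from ehmax.features import LearningImage, scan_top_lefts
from ehmax.learning import (Cluster, LinearClassifier, init_clusters,
                            mine_hard_negatives, refresh_cluster,
                            score_cluster, select_top,
                            train_cluster_classifier)

LCFG = LearningConfig()


def _fake_image(rng, image_id, grid=(40, 40), dim=12, n=16,
                planted=None):
    """A LearningImage with a random descriptor field (no pixels involved).

    ``planted`` optionally maps (tl_row, tl_col) -> descriptor row to place
    known patches at known scan positions.
    """
    gh, gw = grid[0] - n + 1, grid[1] - n + 1
    field = rng.standard_normal((gh, gw, dim)) * 0.1
    if planted:
        for (r, c), vec in planted.items():
            field[r, c] = vec
    tls = scan_top_lefts(grid, n)
    X = field[tls[:, 0], tls[:, 1]]
    centers = np.column_stack([tls[:, 1] + n // 2, tls[:, 0] + n // 2])
    record = types.SimpleNamespace(id=image_id, label=None, pixels=None)
    img = LearningImage(record=record, band1=np.zeros(grid + (1,)))
    img.fields[n] = field
    img.scan[n] = (centers, X)
    return img


class TestClassifier:
    def test_separable_classes_get_correct_signs(self):
        pos = np.tile([1.0, 0.0, 0.0], (4, 1))
        neg = np.tile([-1.0, 0.0, 0.0], (30, 1))
        clf = train_cluster_classifier(pos, neg, LCFG)
        assert (clf.score(pos) > 0).all()
        assert (clf.score(neg) < 0).all()

    def test_duplicating_negatives_leaves_decision_unchanged(self, rng):
        pos = rng.standard_normal((5, 8)) + 2.0
        neg = rng.standard_normal((40, 8))
        probe = rng.standard_normal((20, 8))
        a = train_cluster_classifier(pos, neg, LCFG)
        b = train_cluster_classifier(pos, np.vstack([neg, neg]), LCFG)
        assert np.allclose(a.score(probe), b.score(probe), atol=1e-6)

    def test_scores_are_affine_in_the_descriptor(self, rng):
        clf = LinearClassifier(weights=rng.standard_normal(6), bias=0.3)
        x = rng.standard_normal(6)
        assert clf.score(2 * x)[0] == pytest.approx(
            2 * clf.score(x)[0] - 0.3, abs=1e-12)

    def test_empty_negative_set_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            train_cluster_classifier(rng.random((4, 5)), np.empty((0, 5)), LCFG)


class TestHardNegatives:
    def test_silent_classifier_returns_nothing(self, rng):
        imgs = [_fake_image(rng, f"n{i}") for i in range(3)]
        clf = LinearClassifier(weights=np.zeros(12), bias=-5.0)
        assert mine_hard_negatives(clf, imgs, 16).size == 0

    def test_member_copies_are_found_first(self, rng):
        member = np.full(12, 3.0)
        img = _fake_image(rng, "n0", planted={(4, 8): member})
        clf = LinearClassifier(weights=np.ones(12) / 12, bias=-1.5)
        hard = mine_hard_negatives(clf, [img], 16, threshold=-1.0, per_image=3)
        assert np.allclose(hard[0], member)

    def test_matches_sliding_window_oracle(self, rng):
        img = _fake_image(rng, "n0")
        clf = LinearClassifier(weights=rng.standard_normal(12), bias=0.0)
        hard = mine_hard_negatives(clf, [img], 16, threshold=-0.05, per_image=50)
        _, X = img.scan[16]
        scores = X @ clf.weights
        expect = X[np.argsort(-scores, kind="stable")][scores[np.argsort(
            -scores, kind="stable")] > -0.05]
        assert np.allclose(hard, expect[:50])


class TestRefresh:
    def test_keeps_top_q_of_many_detections(self, rng):
        member = np.full(12, 3.0)
        planted = {(0, 0): member, (0, 12): member, (12, 0): member,
                   (12, 12): member, (4, 4): member, (8, 20): member,
                   (20, 8): member}
        img = _fake_image(rng, "d0", planted=planted)
        clf = LinearClassifier(weights=np.ones(12), bias=-20.0)
        members, X = refresh_cluster(clf, [img], 16, q=5)
        assert len(members) == 5
        assert all((m.image_id == "d0") for m in members)

    def test_fewer_than_three_detections_deletes_cluster(self, rng):
        member = np.full(12, 3.0)
        img = _fake_image(rng, "d0", planted={(0, 0): member, (20, 20): member})
        clf = LinearClassifier(weights=np.ones(12), bias=-20.0)
        assert refresh_cluster(clf, [img], 16, q=5) is None

    def test_detections_match_scan_and_suppression_oracle(self, rng):
        imgs = [_fake_image(rng, f"d{i}") for i in range(2)]
        clf = LinearClassifier(weights=rng.standard_normal(12), bias=0.0)
        result = refresh_cluster(clf, imgs, 16, q=4, threshold=-0.2)
        # oracle: merge all scan detections, sort, greedy 4-apart within image
        dets = []
        for img in imgs:
            centers, X = img.scan[16]
            scores = X @ clf.weights
            for i, s in enumerate(scores):
                if s > -0.2:
                    dets.append((float(s), img.id, int(centers[i, 0]),
                                 int(centers[i, 1])))
        dets.sort(key=lambda d: (-d[0], d[1], d[3], d[2]))
        kept = []
        for s, iid, cx, cy in dets:
            if len(kept) >= 4:
                break
            if all(not (iid == kid and (cx - kx) ** 2 + (cy - ky) ** 2 < 16)
                   for kid, kx, ky in kept):
                kept.append((iid, cx, cy))
        assert [(m.image_id, m.cx, m.cy) for m in result[0]] == kept


class TestInitClusters:
    def test_patch_count_over_five_clusters(self, rng):
        X = rng.standard_normal((25, 6))
        members = [None] * 25
        clusters = init_clusters(X, members, k=5, seed=0, patch_size=16,
                                 min_size=1)
        assert len(clusters) == 5
        assert sum(len(c.members) for c in clusters) == 25

    def test_recovers_well_separated_blobs(self, rng):
        centers = np.array([[10, 0], [0, 10], [-10, -10]], dtype=float)
        X = np.vstack([c + 0.1 * rng.standard_normal((8, 2)) for c in centers])
        clusters = init_clusters(X, list(range(24)), k=3, seed=1, patch_size=16)
        groups = [frozenset(c.members) for c in clusters]
        truth = [frozenset(range(i * 8, (i + 1) * 8)) for i in range(3)]
        assert sorted(groups, key=min) == sorted(truth, key=min)

    def test_same_seed_same_partition(self, rng):
        X = rng.standard_normal((40, 5))
        a = init_clusters(X, list(range(40)), k=6, seed=9, patch_size=16)
        b = init_clusters(X, list(range(40)), k=6, seed=9, patch_size=16)
        assert [c.members for c in a] == [c.members for c in b]

    def test_small_clusters_dropped(self, rng):
        X = np.vstack([np.zeros((7, 2)), [[50.0, 50.0]]])
        clusters = init_clusters(X, list(range(8)), k=2, seed=0,
                                 patch_size=16, min_size=3)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 7

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ParameterError):
            init_clusters(rng.random((5, 2)), list(range(5)), k=0, seed=0,
                          patch_size=16)


class TestScoring:
    def _cluster(self, weights, bias=0.0, n=16):
        return Cluster(id=0, patch_size=n, members=[], descriptors=np.empty(0),
                       classifier=LinearClassifier(np.asarray(weights, float),
                                                   bias))

    def test_firing_ratio_eight_to_two(self, rng):
        # detector fires at 8 planted sites in D and 2 in N, nowhere else
        key = np.full(12, 5.0)
        d_imgs = [_fake_image(rng, f"d{i}",
                              planted={(0, 0): key, (12, 12): key})
                  for i in range(4)]
        n_imgs = [_fake_image(rng, "n0", planted={(0, 0): key, (12, 12): key})]
        cluster = self._cluster(np.ones(12), bias=-30.0)
        purity, discri = score_cluster(cluster, d_imgs, n_imgs, r=10, q=5)
        assert discri == pytest.approx(0.8)

    def test_never_firing_in_discovery_gives_zero_discri(self, rng):
        d_imgs = [_fake_image(rng, "d0")]
        n_imgs = [_fake_image(rng, "n0")]
        cluster = self._cluster(np.zeros(12), bias=-1.0)
        _, discri = score_cluster(cluster, d_imgs, n_imgs, r=10, q=5)
        assert discri == 0.0

    def test_purity_is_mean_of_top_r_scores(self, rng):
        d_imgs = [_fake_image(rng, "d0")]
        w = rng.standard_normal(12)
        cluster = self._cluster(w)
        purity, _ = score_cluster(cluster, d_imgs, [], r=10, q=5)
        scores = np.sort(d_imgs[0].scan[16][1] @ w)[::-1]
        assert purity == pytest.approx(scores[:10].mean())

    def test_purity_pool_must_exceed_refresh_count(self, rng):
        cluster = self._cluster(np.zeros(12))
        with pytest.raises(ConfigError):
            score_cluster(cluster, [], [], r=5, q=5)


class TestSelectTop:
    def _scored(self, id_, n, score):
        return Cluster(id=id_, patch_size=n, members=[], descriptors=np.empty(0),
                       score=score)

    def test_counts_per_size_are_united(self):
        clusters = [self._scored(i, 16, -i) for i in range(8)] + \
                   [self._scored(100 + i, 28, -i) for i in range(3)]
        bank = select_top(clusters, {16: 5, 28: 1})
        assert bank.gamma == 6
        assert bank.top_by_size == {16: 5, 28: 1}
        assert [c.patch_size for c in bank.clusters] == [16] * 5 + [28]

    def test_shortfall_returns_all_survivors_with_warning(self):
        clusters = [self._scored(i, 16, float(i)) for i in range(3)]
        with pytest.warns(UserWarning):
            bank = select_top(clusters, {16: 30})
        assert bank.gamma == 3
        assert bank.top_by_size == {16: 3}

    def test_score_ties_break_toward_lower_id(self):
        clusters = [self._scored(5, 16, 1.0), self._scored(2, 16, 1.0),
                    self._scored(9, 16, 2.0)]
        bank = select_top(clusters, {16: 2})
        assert [c.id for c in bank.clusters] == [9, 2]
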