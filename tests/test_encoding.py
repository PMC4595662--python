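"""S2 detector maps and position-encoded C2 features, both model variants."""

import numpy as np
import pytest

from ehmax.c1 import C1Maps
from ehmax.config import EncoderConfig, default_band_table
from ehmax.encoding import (PrototypeSet, ablate_position_features, compute_c2,
                            compute_c2_ohmax, compute_s2_ehmax,
                            compute_s2_ohmax, sample_prototypes_random)
from ehmax.exceptions import EncodingError, ParameterError
from ehmax.learning import Cluster, ClusterBank, LinearClassifier
from ehmax.patches import describe_patch

BANDS = default_band_table()


def _c1(rng, shapes, n_orient=4):
    """C1Maps with random stacks; ``shapes`` maps band index -> (gh, gw)."""
    thetas = [180.0 * i / n_orient for i in range(n_orient)]
    maps = {(b, t): rng.random(shape) for b, shape in shapes.items()
            for t in thetas}
    return C1Maps(maps=maps, bands=BANDS, image_shape=(128, 128))


def _bank(weights, bias=0.0, n=16):
    cluster = Cluster(id=0, patch_size=n, members=[], descriptors=np.empty(0),
                      classifier=LinearClassifier(np.asarray(weights, float),
                                                  bias))
    return ClusterBank(clusters=[cluster], top_by_size={n: 1})


class TestS2Enhanced:
    def test_zero_c1_scores_equal_bias(self, rng):
        c1 = _c1(rng, {1: (20, 20)})
        for key in c1.maps:
            c1.maps[key] = np.zeros((20, 20))
        bank = _bank(rng.standard_normal(36), bias=-0.7)
        s2 = compute_s2_ehmax(c1, bank)
        assert np.allclose(s2.maps[(0, 1)], -0.7, atol=1e-12)

    def test_matches_exhaustive_window_scoring(self, rng):
        c1 = _c1(rng, {1: (30, 30)})
        w = rng.standard_normal(36)
        bank = _bank(w, bias=0.2)
        s2 = compute_s2_ehmax(c1, bank)
        stack = c1.band_stack(1)
        m = s2.maps[(0, 1)]
        assert m.shape == (15, 15)
        for r in (0, 7, 14):
            for c in (0, 3, 14):
                d = describe_patch(stack[r:r + 16, c:c + 16, :]).vector
                assert m[r, c] == pytest.approx(float(d @ w + 0.2), abs=1e-9)

    def test_small_bands_are_skipped(self, rng):
        c1 = _c1(rng, {1: (30, 30), 8: (10, 10)})
        s2 = compute_s2_ehmax(c1, _bank(rng.standard_normal(36)))
        assert (0, 1) in s2.maps and (0, 8) not in s2.maps

    def test_eight_maps_per_cluster_on_large_grids(self, rng):
        shapes = {b: (40, 40) for b in range(1, 9)}
        s2 = compute_s2_ehmax(_c1(rng, shapes), _bank(rng.standard_normal(36)))
        assert len(s2.maps_for(0)) == 8

    def test_planted_member_attains_band_maximum(self, rng):
        c1 = _c1(rng, {1: (31, 31)})
        stack = c1.band_stack(1)
        motif = describe_patch(stack[5:21, 9:25, :]).vector
        bank = _bank(motif / np.linalg.norm(motif), bias=0.0)
        s2 = compute_s2_ehmax(c1, bank)
        r, c = np.unravel_index(np.argmax(s2.maps[(0, 1)]),
                                s2.maps[(0, 1)].shape)
        assert (r, c) == (5, 9)

    def test_empty_bank_rejected(self, rng):
        with pytest.raises(ParameterError):
            compute_s2_ehmax(_c1(rng, {1: (20, 20)}),
                             ClusterBank(clusters=[], top_by_size={}))


class TestC2:
    def test_worked_example_with_position(self):
        m = np.zeros((20, 10))   # L=20 rows, W=10 columns
        m[4, 3] = 2.5
        from ehmax.encoding import S2ScoreMaps
        c2 = compute_c2(S2ScoreMaps(maps={("k", 1): m}, unit_ids=["k"]))
        assert np.allclose(c2.vector, [2.5, 3 / 10, 4 / 20])

    def test_three_entries_per_cluster(self, rng):
        from ehmax.encoding import S2ScoreMaps
        maps = {(u, 1): rng.random((8, 8)) for u in range(4)}
        c2 = compute_c2(S2ScoreMaps(maps=maps, unit_ids=list(range(4))))
        assert c2.vector.shape == (12,)
        rel = c2.vector.reshape(4, 3)[:, 1:]
        assert ((rel >= 0) & (rel <= 1)).all()

    def test_ties_resolve_to_lowest_band_then_row_major(self):
        from ehmax.encoding import S2ScoreMaps
        flat = np.ones((6, 6))
        c2 = compute_c2(S2ScoreMaps(maps={("k", 2): flat, ("k", 1): flat},
                                    unit_ids=["k"]))
        assert np.allclose(c2.vector, [1.0, 0.0, 0.0])

    def test_unit_without_any_map_is_an_error(self):
        from ehmax.encoding import S2ScoreMaps
        with pytest.raises(EncodingError):
            compute_c2(S2ScoreMaps(maps={}, unit_ids=["k"]))

    def test_position_ablation_keeps_score_entries(self, rng):
        X = rng.random((5, 12))
        kept = ablate_position_features(X)
        assert kept.shape == (5, 4)
        assert np.allclose(kept, X[:, ::3])


class TestPrototypes:
    def _stacks(self, rng, n_images=3, shape=(31, 31, 4)):
        return {f"img{i}": rng.random(shape) for i in range(n_images)}

    def test_requested_count_and_sizes(self, rng):
        protos = sample_prototypes_random(self._stacks(rng), M=100,
                                          sizes=(16, 28), seed=0)
        assert protos.M == 100
        assert {n for _, _, n, _ in protos.prototypes} <= {16, 28}

    def test_same_seed_identical_set(self, rng):
        stacks = self._stacks(rng)
        a = sample_prototypes_random(stacks, M=20, sizes=(16,), seed=3)
        b = sample_prototypes_random(stacks, M=20, sizes=(16,), seed=3)
        assert [(i, tl, n) for i, tl, n, _ in a.prototypes] == \
               [(i, tl, n) for i, tl, n, _ in b.prototypes]

    def test_crops_lie_inside_their_grids(self, rng):
        stacks = self._stacks(rng)
        protos = sample_prototypes_random(stacks, M=50, sizes=(16, 28), seed=1)
        for image_id, (r, c), n, tensor in protos.prototypes:
            h, w, _ = stacks[image_id].shape
            assert 0 <= r <= h - n and 0 <= c <= w - n
            assert tensor.shape == (n, n, 4)
            assert np.array_equal(tensor,
                                  stacks[image_id][r:r + n, c:c + n, :])

    def test_oversampling_rejected(self, rng):
        stacks = {"img0": rng.random((16, 16, 4))}
        with pytest.raises(ParameterError):
            sample_prototypes_random(stacks, M=2, sizes=(16,), seed=0)


class TestS2Baseline:
    def test_window_equal_to_prototype_responds_exactly_one(self, rng):
        c1 = _c1(rng, {1: (30, 30)})
        stack = c1.band_stack(1)
        proto = stack[4:20, 7:23, :].copy()
        protos = PrototypeSet(prototypes=[("x", (4, 7), 16, proto)],
                              sizes=(16,), beta=1.0)
        s2 = compute_s2_ohmax(c1, protos)
        assert s2.maps[(0, 1)][4, 7] == 1.0

    def test_gaussian_like_tuning_value(self):
        # distance 2 at beta 1 responds exp(-2)
        stack = np.zeros((16, 16, 1))
        proto = np.zeros((16, 16, 1))
        proto[0, 0, 0] = 2.0
        c1 = C1Maps(maps={(1, 0.0): stack[:, :, 0]}, bands=BANDS,
                    image_shape=(128, 128))
        protos = PrototypeSet(prototypes=[("x", (0, 0), 16, proto)],
                              sizes=(16,), beta=1.0)
        s2 = compute_s2_ohmax(c1, protos)
        assert s2.maps[(0, 1)][0, 0] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_matches_exhaustive_distance_oracle(self, rng):
        c1 = _c1(rng, {1: (30, 30)})
        stack = c1.band_stack(1)
        proto = rng.random((16, 16, 4))
        protos = PrototypeSet(prototypes=[("x", (0, 0), 16, proto)],
                              sizes=(16,), beta=0.5)
        s2 = compute_s2_ohmax(c1, protos)
        for r in (0, 5, 14):
            for c in (2, 9, 14):
                d = np.sqrt(((stack[r:r + 16, c:c + 16, :] - proto) ** 2).sum())
                assert s2.maps[(0, 1)][r, c] == pytest.approx(
                    np.exp(-0.5 * d), abs=1e-9)

    def test_eight_maps_per_prototype_and_bounded_c2(self, rng):
        shapes = {b: (40, 40) for b in range(1, 9)}
        c1 = _c1(rng, shapes)
        stacks = {"img": c1.band_stack(1)}
        protos = sample_prototypes_random(stacks, M=3, sizes=(16,), seed=0,
                                          beta=0.1)
        s2 = compute_s2_ohmax(c1, protos)
        assert len(s2.maps) == 24
        c2 = compute_c2_ohmax(s2)
        assert c2.vector.shape == (3,)
        assert ((c2.vector > 0) & (c2.vector <= 1)).all()
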