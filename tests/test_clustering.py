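"""MaxMin selection and Tanimoto k-means against brute-force oracles."""

import itertools

import pytest

from molscreen import (
    cluster_set,
    kmeans,
    make_fixture_set,
    maxmin_select,
    path_fingerprint,
    tanimoto_distance,
)
from molscreen.similarity import Fingerprint

from .oracles import best_partition_objective, maxmin_bruteforce


def fp(bit_indices, nbits=64):
    mask = 0
    for i in bit_indices:
        mask |= 1 << i
    return Fingerprint(bits=mask, nbits=nbits)


def two_block_fps():
    """Six fingerprints in two tight blocks, far apart."""
    block1 = [fp({0, 1, 2, 3, 4}), fp({0, 1, 2, 3, 5}), fp({0, 1, 2, 3, 6})]
    block2 = [fp({20, 21, 22, 23, 24}), fp({20, 21, 22, 23, 25}),
              fp({20, 21, 22, 23, 26})]
    return block1 + block2


class TestTanimotoDistance:
    def test_identical_zero(self):
        assert tanimoto_distance(fp({1, 2}), fp({1, 2})) == 0.0

    def test_disjoint_one(self):
        assert tanimoto_distance(fp({1}), fp({2})) == 1.0

    def test_two_thirds(self):
        assert tanimoto_distance(fp({1, 2}), fp({2, 3})) == pytest.approx(2 / 3)


class TestMaxMin:
    def test_k1_is_just_the_seed(self):
        fps = two_block_fps()
        res = maxmin_select(fps, 1, seed_index=2)
        assert res.picked_indices == [2]

    def test_k_equals_n_picks_everything(self):
        fps = two_block_fps()
        res = maxmin_select(fps, len(fps), seed_index=0)
        assert sorted(res.picked_indices) == list(range(len(fps)))

    def test_second_pick_crosses_the_gap(self):
        fps = two_block_fps()
        res = maxmin_select(fps, 2, seed_index=0)
        assert res.picked_indices[1] in (3, 4, 5)

    def test_matches_bruteforce_greedy(self):
        fps = two_block_fps()

        def dist(i, j):
            return tanimoto_distance(fps[i], fps[j])

        for k in (2, 3):
            ours = maxmin_select(fps, k, seed_index=1).picked_indices
            assert ours == maxmin_bruteforce(dist, len(fps), k, seed=1)

    def test_pick_radii_non_increasing(self):
        cset = make_fixture_set("mixed_bench", 12, rng_seed=5)
        fps = [path_fingerprint(r.mol) for r in cset]
        res = maxmin_select(fps, 6, seed_index=0)
        radii = res.min_distances[1:]  # the seed's radius is infinite
        assert all(a >= b for a, b in zip(radii, radii[1:]))

    def test_deterministic_under_rng_seed(self):
        fps = two_block_fps()
        a = maxmin_select(fps, 3, rng_seed=11)
        b = maxmin_select(fps, 3, rng_seed=11)
        assert a.picked_indices == b.picked_indices

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            maxmin_select(two_block_fps(), 0)
        with pytest.raises(ValueError):
            maxmin_select(two_block_fps(), 7)


class TestKMeans:
    def test_k_equals_n_zero_objective(self):
        fps = two_block_fps()
        res = kmeans(fps, len(fps), init_indices=list(range(len(fps))))
        assert res.objective == pytest.approx(0.0, abs=1e-12)
        assert sorted(set(res.assignments)) == list(range(len(fps)))

    def test_identical_points_single_cluster(self):
        fps = [fp({1, 2, 3})] * 4
        res = kmeans(fps, 1, init_indices=[0])
        assert res.objective == pytest.approx(0.0, abs=1e-12)
        assert res.converged

    def test_two_block_fixture_separates_blocks(self):
        fps = two_block_fps()
        picks = maxmin_select(fps, 2, seed_index=0)
        res = kmeans(fps, 2, init_indices=picks.picked_indices)
        assert len({res.assignments[i] for i in (0, 1, 2)}) == 1
        assert len({res.assignments[i] for i in (3, 4, 5)}) == 1
        assert res.assignments[0] != res.assignments[3]

    def test_reaches_bruteforce_optimum_on_two_blocks(self):
        fps = two_block_fps()
        vecs = [f.to_vector() for f in fps]
        picks = maxmin_select(fps, 2, seed_index=0)
        res = kmeans(fps, 2, init_indices=picks.picked_indices)
        assert res.objective == pytest.approx(
            best_partition_objective(vecs, 2), abs=1e-9)

    def test_objective_history_non_increasing(self):
        cset = make_fixture_set("mixed_bench", 14, rng_seed=2)
        fps = [path_fingerprint(r.mol) for r in cset]
        picks = maxmin_select(fps, 3, seed_index=0)
        res = kmeans(fps, 3, init_indices=picks.picked_indices)
        hist = res.objective_history
        assert all(a >= b - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_no_single_point_reassignment_improves(self):
        """Local optimality: moving any one compound to another cluster
        (recomputing that cluster's centroid membership cost against the
        final centroids) never lowers the objective."""
        import numpy as np
        fps = two_block_fps()
        res = kmeans(fps, 2, init_indices=[0, 3])
        vecs = np.stack([f.to_vector() for f in fps])

        def cont_tani(x, c):
            num = float(x @ c)
            den = float(x @ x) + float(c @ c) - num
            return num / den if den > 0 else 1.0

        for i in range(len(fps)):
            own = res.assignments[i]
            for j in range(2):
                if j != own:
                    assert (1 - cont_tani(vecs[i], res.centroids[own])
                            <= 1 - cont_tani(vecs[i], res.centroids[j]) + 1e-12)

    def test_every_cluster_non_empty(self):
        fps = [fp({1}), fp({1}), fp({1}), fp({30})]
        res = kmeans(fps, 3, init_indices=[0, 1, 3])
        assert set(res.assignments) == {0, 1, 2}

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            kmeans(two_block_fps(), 7, init_indices=list(range(7)))


class TestClusterSet:
    def test_k1_single_cluster(self):
        cset = make_fixture_set("alkanes", 5)
        cset, res = cluster_set(cset, k=1, rng_seed=0)
        assert set(res.assignments) == {0}
        assert all(r.annotations["cluster"].value == "0" for r in cset)

    def test_deterministic_repeat(self):
        a = cluster_set(make_fixture_set("mixed_bench", 12, rng_seed=4), 3,
                        rng_seed=9)[1]
        b = cluster_set(make_fixture_set("mixed_bench", 12, rng_seed=4), 3,
                        rng_seed=9)[1]
        assert a.assignments == b.assignments
        assert a.objective == b.objective

    def test_two_scaffold_families_split_cleanly(self):
        """Alkanes vs phenols: k=2 must produce family-pure clusters, and the
        exhaustive partition scan confirms it attains the global optimum."""
        from molscreen.model import CompoundSet
        from molscreen.io import parse_smiles
        smiles = ["CCCC", "CCCCC", "CCCCCC",
                  "Oc1ccccc1", "Oc1ccc(C)cc1", "Oc1ccc(CC)cc1"]
        cset = CompoundSet(set_number=1)
        for i, smi in enumerate(smiles, 1):
            cset.add(parse_smiles(smi, auto_name=f"CMPD{i}"))
        cset, res = cluster_set(cset, k=2, rng_seed=0)
        assert len(set(res.assignments[:3])) == 1
        assert len(set(res.assignments[3:])) == 1
        assert res.assignments[0] != res.assignments[3]
        vecs = [path_fingerprint(r.mol).to_vector() for r in cset]
        assert res.objective <= best_partition_objective(vecs, 2) + 1e-9

    def test_representatives_flagged(self):
        cset, res = cluster_set(make_fixture_set("alkanes", 6), k=2, rng_seed=0)
        reps = [r for r in cset if r.annotations["is_representative"].value == "1"]
        assert len(reps) == 2
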