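import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynoc
from dynoc.factorization import CommunityModel


def model_from_labels(labels, k):
    """Hard-partition membership matrix from a label vector."""
    C = np.zeros((len(labels), k))
    C[np.arange(len(labels)), labels] = 1.0
    return CommunityModel(C=C, Z=np.ones((2, k)), k=k, beta=0.0)


class TestConsensusAndCcc:
    def test_identical_runs_give_unit_ccc(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        runs = [model_from_labels(labels, 3) for _ in range(5)]
        res = dynoc.consensus_and_ccc(runs, 3)
        assert res.ccc == pytest.approx(1.0)
        # consensus is binary and block structured
        assert set(np.unique(res.consensus)) <= {0.0, 1.0}
        np.testing.assert_array_equal(res.consensus, res.consensus.T)
        assert (np.diag(res.consensus) == 1.0).all()

    def test_two_pair_hand_built_dendrogram(self):
        # pairs (0,1) and (2,3) always together, never across: the tree's
        # cophenetic distances reproduce 1 - consensus exactly
        runs = [model_from_labels([0, 0, 1, 1], 2) for _ in range(4)]
        res = dynoc.consensus_and_ccc(runs, 2)
        assert res.ccc == pytest.approx(1.0)
        np.testing.assert_array_equal(
            res.consensus,
            np.array([
                [1.0, 1.0, 0.0, 0.0],
                [1.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 1.0],
                [0.0, 0.0, 1.0, 1.0],
            ]),
        )

    def test_random_partitions_less_stable_than_identical(self):
        rng = np.random.default_rng(0)
        random_runs = [
            model_from_labels(rng.integers(0, 4, size=40), 4) for _ in range(100)
        ]
        res = dynoc.consensus_and_ccc(random_runs, 4)
        assert res.ccc < 0.9  # well below the identical-run value of 1.0

    def test_stability_decreases_with_partition_noise(self):
        # flip an increasing fraction of labels between runs; median ccc drops
        rng = np.random.default_rng(1)
        base = np.repeat(np.arange(4), 10)
        cccs = []
        for flip in (0.05, 0.25, 0.6):
            runs = []
            for _ in range(40):
                labels = base.copy()
                idx = rng.random(40) < flip
                labels[idx] = rng.integers(0, 4, size=int(idx.sum()))
                runs.append(model_from_labels(labels, 4))
            cccs.append(dynoc.consensus_and_ccc(runs, 4).ccc)
        assert cccs[0] > cccs[1] > cccs[2]

    def test_mismatched_k_rejected(self):
        runs = [model_from_labels([0, 1], 2), model_from_labels([0, 1, 0][:2], 3)]
        with pytest.raises(dynoc.ParameterError):
            dynoc.consensus_and_ccc(runs, 2)


class TestStabilityCurve:
    def test_one_row_per_k_and_planted_k_most_stable(self, small_truth):
        W = dynoc.simulate_group_tensors(small_truth, 1, 0.05, seed=2)
        F = dynoc.preprocess_nonnegative(W[0])
        curve = dynoc.stability_curve(F, [2, 5], n_runs=10, beta=0.1, seed=0,
                                      max_sweeps=100)
        assert list(curve["k"]) == [2, 5]
        planted = curve.loc[curve["k"] == 2, "ccc"].item()
        overfit = curve.loc[curve["k"] == 5, "ccc"].item()
        assert planted >= overfit

    def test_n_runs_validated(self, noise_free_tensor):
        with pytest.raises(dynoc.ParameterError):
            dynoc.stability_curve(noise_free_tensor, [2], n_runs=1)


class TestNodeDiversity:
    def test_uniform_membership_reaches_ln_k(self):
        k = 4
        model = CommunityModel(C=np.full((3, k), 1.0), Z=np.ones((2, k)), k=k, beta=0.0)
        prof = dynoc.node_diversity(model)
        np.testing.assert_allclose(prof.H, np.log(k))

    def test_single_community_node_is_zero(self):
        model = model_from_labels([0, 1, 1], 2)
        np.testing.assert_array_equal(dynoc.node_diversity(model).H, 0.0)

    def test_hand_evaluated_two_community_split(self):
        # normalized weights (0.75, 0.25) -> H ~ 0.5623 nats
        C = np.array([[0.75, 0.25]])
        model = CommunityModel(C=C, Z=np.ones((1, 2)), k=2, beta=0.0)
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert dynoc.node_diversity(model).H[0, 0] == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_weights_modulate_with_sqrt_z(self):
        # z = (4, 1) turns equal strengths into a (2/3, 1/3) distribution
        C = np.array([[1.0, 1.0]])
        model = CommunityModel(C=C, Z=np.array([[4.0, 1.0]]), k=2, beta=0.0)
        expected = -(2 / 3 * np.log(2 / 3) + 1 / 3 * np.log(1 / 3))
        assert dynoc.node_diversity(model).H[0, 0] == pytest.approx(expected)

    @given(seed=st.integers(0, 100), k=st.integers(1, 6))
    @settings(max_examples=30, deadline=None)
    def test_entropy_bounds(self, seed, k):
        rng = np.random.default_rng(seed)
        model = CommunityModel(
            C=rng.uniform(size=(7, k)), Z=rng.uniform(size=(3, k)), k=k, beta=0.0
        )
        H = dynoc.node_diversity(model).H
        assert (H >= -1e-12).all()
        assert (H <= np.log(k) + 1e-12).all()


class TestCommunityMembers:
    def test_hand_computed_threshold(self):
        C = np.array([[1.0], [0.9], [0.1], [0.0], [0.0]])
        # mean 0.4, population SD ~ 0.4517, threshold ~ 0.8517
        np.testing.assert_array_equal(dynoc.community_members(C, 0), [0, 1])

    def test_one_hot_column(self):
        C = np.zeros((5, 1))
        C[3, 0] = 1.0
        np.testing.assert_array_equal(dynoc.community_members(C, 0), [3])

    def test_constant_column_empty_with_warning(self):
        with pytest.warns(RuntimeWarning):
            members = dynoc.community_members(np.full((4, 1), 0.7), 0)
        assert members.size == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(size=(10, 1))
        a = dynoc.community_members(C, 0)
        b = dynoc.community_members(3.7 * C, 0)
        np.testing.assert_array_equal(a, b)


class TestOverlappingNodes:
    def test_block_one_hot_has_no_overlap(self):
        model = model_from_labels([0, 0, 0, 1, 1, 1], 2)
        assert dynoc.overlapping_nodes(model.C) == {}

    def test_planted_truth_overlap_recovered(self):
        truth = dynoc.make_truth(10, 2, overlap_fraction=0.2, T=5, seed=1)
        found = dynoc.overlapping_nodes(truth.membership)
        assert set(found) == set(truth.overlap_nodes)

    def test_node_in_three_communities_listed_once(self):
        C = np.zeros((6, 3))
        C[np.arange(1, 6) % 5, :] = 0.1
        C[0, :] = 1.0
        found = dynoc.overlapping_nodes(C)
        assert list(found) == [0]
        assert found[0] == [0, 1, 2]


class TestActivityLevel:
    def test_hand_evaluated_series(self):
        # members strengths (1.0, 0.8), z = (2, 4) -> series (1.8, 3.6)
        C = np.array([[1.0], [0.8], [0.1], [0.0], [0.0], [0.0]])
        model = CommunityModel(C=C, Z=np.array([[2.0], [4.0]]), k=1, beta=0.0)
        prof = dynoc.activity_level(model)
        np.testing.assert_array_equal(prof.members[0], [0, 1])
        np.testing.assert_allclose(prof.series[:, 0], [1.8, 3.6])
        assert prof.summary[0] == pytest.approx(2.7)

    def test_zero_intensity_gives_zero_activity(self):
        C = np.array([[1.0], [0.8], [0.1], [0.0], [0.0], [0.0]])
        model = CommunityModel(C=C, Z=np.zeros((3, 1)), k=1, beta=0.0)
        prof = dynoc.activity_level(model)
        assert (prof.series == 0).all() and (prof.summary == 0).all()

    def test_linear_in_intensity(self):
        rng = np.random.default_rng(0)
        C = np.zeros((8, 1))
        C[:3, 0] = [1.0, 0.9, 0.8]
        Z = rng.uniform(size=(4, 1))
        a = dynoc.activity_level(CommunityModel(C=C, Z=Z, k=1, beta=0.0))
        b = dynoc.activity_level(CommunityModel(C=C, Z=2 * Z, k=1, beta=0.0))
        np.testing.assert_allclose(b.summary, 2 * a.summary)

    def test_invariant_to_subthreshold_regions(self):
        C = np.array([[1.0], [0.8], [0.1], [0.0], [0.0], [0.0]])
        model = dynoc.CommunityModel(C=C, Z=np.array([[2.0], [4.0]]), k=1, beta=0.0)
        base = dynoc.activity_level(model)
        C2 = np.vstack([C, [[0.05]], [[0.02]]])
        model2 = dynoc.CommunityModel(C=C2, Z=model.Z, k=1, beta=0.0)
        np.testing.assert_allclose(dynoc.activity_level(model2).series, base.series)


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=8)
        diff, p = dynoc.compare_groups(vals, vals, n_perm=2000, seed=1)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert p > 0.5

    def test_extreme_separation_small_p(self):
        diff, p = dynoc.compare_groups([0] * 5, [10] * 5, n_perm=10000, seed=2)
        assert p <= 0.01
        assert diff == -10.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=6), rng.normal(loc=0.5, size=7)
        d1, p1 = dynoc.compare_groups(a, b, n_perm=3000, seed=4)
        d2, p2 = dynoc.compare_groups(b, a, n_perm=3000, seed=4)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_degenerate_pooled_data(self):
        with pytest.warns(RuntimeWarning):
            _, p = dynoc.compare_groups([1.0, 1.0], [1.0, 1.0], n_perm=200, seed=0)
        assert p == 1.0
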