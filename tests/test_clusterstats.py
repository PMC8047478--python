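"""Cluster permutation statistics: oracles, invariances, error control."""

import numpy as np
import pytest
from scipy.stats import t as t_dist

from illuseeg.channels import subset_layout
from illuseeg.clusterstats import (
    AdjacencyGraph,
    ClusterConfig,
    actvsbl_subject_maps,
    build_adjacency,
    dependent_t,
    equalize_trials,
    find_clusters,
    permutation_test,
)


def brute_force_clusters(t_map, t_lo, t_hi, neighbors):
    """Flood-fill oracle over an explicit sample graph.

    ``neighbors`` maps channel index -> set of neighbouring channels; the
    non-channel axes are chained bin-by-bin.
    """
    shape = t_map.shape
    out = []
    for sign, supra in ((1, t_map > t_hi), (-1, t_map < t_lo)):
        seen = np.zeros(shape, bool)
        for start in zip(*np.nonzero(supra)):
            if seen[start]:
                continue
            stack, members = [start], []
            seen[start] = True
            while stack:
                node = stack.pop()
                members.append(node)
                for nb in _neighbors_of(node, shape, neighbors):
                    if supra[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            out.append((sorted(members), sign, float(sum(t_map[m] for m in members))))
    return out


def _neighbors_of(node, shape, neighbors):
    ch, *rest = node
    rest = tuple(rest)
    for nb_ch in neighbors.get(ch, ()):
        yield (nb_ch, *rest)
    for ax, size in enumerate(shape[1:]):
        for step in (-1, 1):
            coord = rest[ax] + step
            if 0 <= coord < size:
                new_rest = rest[:ax] + (coord,) + rest[ax + 1 :]
                yield (ch, *new_rest)


class TestAdjacency:
    def test_pairwise_edges(self):
        pos = np.array([[0, 0, 1.0], [0, 0.3, 0.95], [1.0, 0, 0]])
        graph = build_adjacency(pos, threshold=0.5)
        assert graph.neighbors[0] == frozenset({1})
        assert graph.neighbors[2] == frozenset()

    def test_zero_threshold_empty(self):
        pos = np.array([[0, 0, 1.0], [0, 1.0, 0]])
        with pytest.warns(UserWarning):
            graph = build_adjacency(pos, threshold=0.0)
        assert all(len(nb) == 0 for nb in graph.neighbors)

    def test_64_channel_layout_connectivity(self):
        import networkx as nx

        _, pos = subset_layout(64)
        graph = build_adjacency(pos, threshold=0.55)
        counts = [len(nb) for nb in graph.neighbors]
        assert 5 <= np.mean(counts) <= 9
        g = nx.Graph(list(map(tuple, graph.edge_array())))
        g.add_nodes_from(range(64))
        assert nx.is_connected(g)

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            AdjacencyGraph((frozenset({1}), frozenset()))


class TestDependentT:
    def test_identical_conditions_zero(self):
        diffs = np.zeros((5, 2, 4))
        np.testing.assert_array_equal(dependent_t(diffs), 0.0)

    def test_constant_difference_closed_form(self, rng):
        n, d = 8, 2.0
        base = rng.standard_normal(n)
        diffs = (d + base)[:, None, None] * np.ones((1, 1, 3))
        expected = (d + base.mean()) * np.sqrt(n) / base.std(ddof=1)
        np.testing.assert_allclose(dependent_t(diffs), expected, rtol=1e-12)

    def test_textbook_four_subjects(self):
        diffs = np.array([2.0, 4.0, 3.0, 7.0]).reshape(4, 1, 1)
        # mean 4, sd sqrt(14/3), t = 4*2/sd
        expected = 4.0 / (np.sqrt(14.0 / 3.0) / 2.0)
        assert dependent_t(diffs)[0, 0] == pytest.approx(expected, rel=1e-12)


class TestActVsBaseline:
    def test_identical_windows_zero(self, epochs_factory, rng):
        eps = epochs_factory(rng.standard_normal((4, 2, 100)))
        maps = actvsbl_subject_maps([eps], (-0.1, 0.1), (-0.1, 0.1))
        # activation minus its own time-average: zero mean over the window
        np.testing.assert_allclose(maps.mean(axis=2), 0.0, atol=1e-12)

    def test_constant_offset_recovered(self, epochs_factory):
        data = np.zeros((3, 1, 100))
        base = epochs_factory(data)
        shifted = epochs_factory(data + 5.0)
        maps_a = actvsbl_subject_maps([base], (0.0, 0.2), (-0.2, -0.1))
        data2 = data.copy()
        data2[:, :, 60:] += 5.0  # activation half raised by 5
        eps = epochs_factory(data2)
        t_act = eps.times[60]
        maps = actvsbl_subject_maps([eps], (t_act, eps.times[-1]), (eps.times[0], t_act - 0.05))
        np.testing.assert_allclose(maps, 5.0, atol=1e-12)
        assert maps_a.shape[0] == 1

    def test_two_subject_hand_computation(self, epochs_factory):
        rate = 200.0
        subjects = []
        for c in (1.0, 2.0):
            data = np.full((2, 1, 200), c)
            data[:, :, 100:] = 3.0 * c
            subjects.append(epochs_factory(data))
        eps = subjects[0]
        act = (eps.times[100], eps.times[-1])
        base = (eps.times[0], eps.times[99])
        maps = actvsbl_subject_maps(subjects, act, base)
        np.testing.assert_allclose(maps[0], 2.0, atol=1e-12)
        np.testing.assert_allclose(maps[1], 4.0, atol=1e-12)


class TestFindClusters:
    def _crit(self, n):
        return (
            float(t_dist.ppf(0.025, n - 1)),
            float(t_dist.ppf(0.975, n - 1)),
        )

    def test_singleton_cluster(self):
        t_map = np.zeros((3, 5))
        t_map[1, 2] = 50.0
        clusters = find_clusters(t_map, n_subjects=8)
        assert len(clusters) == 1
        assert clusters[0].members.tolist() == [1 * 5 + 2]
        assert clusters[0].sign == 1

    def test_non_adjacent_channels_stay_separate(self):
        t_map = np.zeros((3, 5))
        t_map[0, 2] = 50.0
        t_map[2, 2] = 50.0
        graph = AdjacencyGraph((frozenset({1}), frozenset({0, 2}), frozenset({1})))
        clusters = find_clusters(t_map, 8, graph)
        assert len(clusters) == 2

    def test_adjacent_channels_merge(self):
        t_map = np.zeros((2, 5))
        t_map[0, 2] = 50.0
        t_map[1, 2] = 50.0
        graph = AdjacencyGraph((frozenset({1}), frozenset({0})))
        clusters = find_clusters(t_map, 8, graph)
        assert len(clusters) == 1
        assert clusters[0].t_sum == pytest.approx(100.0)

    @pytest.mark.parametrize("with_freq_axis", [False, True])
    def test_matches_flood_fill_oracle(self, rng, with_freq_axis):
        n = 10
        lo, hi = self._crit(n)
        neighbors = {0: {1}, 1: {0, 2}, 2: {1}}
        graph = AdjacencyGraph((frozenset({1}), frozenset({0, 2}), frozenset({1})))
        for _ in range(60):
            shape = (3, 4, 5) if with_freq_axis else (3, 5)
            t_map = rng.standard_normal(shape) * 3.0
            got = find_clusters(t_map, n, graph)
            expected = brute_force_clusters(t_map, lo, hi, neighbors)
            got_sets = sorted(
                (sorted(np.unravel_index(c.members, shape)[0].tolist()), round(c.t_sum, 9))
                for c in got
            )
            exp_sets = sorted(
                (sorted(m[0] for m in members), round(tsum, 9))
                for members, _, tsum in expected
            )
            assert len(got) == len(expected)
            got_sums = sorted(round(c.t_sum, 9) for c in got)
            exp_sums = sorted(round(tsum, 9) for _, _, tsum in expected)
            assert got_sums == exp_sums
            # member sets agree exactly
            got_members = sorted(sorted(map(int, c.members)) for c in got)
            exp_members = sorted(
                sorted(int(np.ravel_multi_index(m, shape)) for m in members)
                for members, _, _ in expected
            )
            assert got_members == exp_members


class TestPermutationTest:
    def test_all_zero_data_no_significance(self):
        diffs = np.zeros((6, 2, 10))
        res = permutation_test(diffs, config=ClusterConfig(n_permutations=100, seed=0))
        assert res.significant == []

    def test_exhaustive_matches_monte_carlo_at_n4(self, rng):
        diffs = rng.standard_normal((4, 2, 6)) + 1.0
        cfg_ex = ClusterConfig(n_permutations=16, seed=0, exhaustive=True)
        res_ex = permutation_test(diffs, config=cfg_ex)
        # auto mode falls back to exhaustive enumeration when 2^N <= B
        cfg_auto = ClusterConfig(n_permutations=1000, seed=1)
        res_auto = permutation_test(diffs, config=cfg_auto)
        assert len(res_ex.clusters) == len(res_auto.clusters)
        for a, b in zip(res_ex.clusters, res_auto.clusters):
            assert a.p_value == b.p_value

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        diffs = rng.standard_normal((8, 1, 12)) + 0.6
        res_ex = permutation_test(
            diffs, config=ClusterConfig(n_permutations=256, exhaustive=True)
        )
        res_mc = permutation_test(
            diffs, config=ClusterConfig(n_permutations=10_000, seed=3, exhaustive=False)
        )
        for a, b in zip(res_ex.clusters, res_mc.clusters):
            assert abs(a.p_value - b.p_value) < 0.02

    def test_planted_effect_detected_with_min_p(self, rng):
        # Cohen's d = 2 on half the grid
        n = 16
        effect = np.zeros((2, 20))
        effect[:, 5:15] = 1.0
        diffs = rng.standard_normal((n, 2, 20)) * 0.5 + effect
        cfg = ClusterConfig(n_permutations=500, seed=0, exhaustive=False)
        adj = AdjacencyGraph((frozenset({1}), frozenset({0})))
        res = permutation_test(diffs, adj, cfg)
        top = res.clusters[0]
        assert top.p_value == pytest.approx(1.0 / 501.0)
        planted = {c * 20 + t for c in range(2) for t in range(5, 15)}
        assert len(planted & set(map(int, top.members))) >= 0.8 * len(planted)

    def test_sign_symmetry(self, rng):
        diffs = rng.standard_normal((6, 2, 15)) + 0.8
        cfg = ClusterConfig(n_permutations=200, seed=5)
        res_pos = permutation_test(diffs, config=cfg)
        res_neg = permutation_test(-diffs, config=cfg)
        assert [c.sign for c in res_pos.clusters] == [-c.sign for c in res_neg.clusters]
        assert [c.p_value for c in res_pos.clusters] == [
            c.p_value for c in res_neg.clusters
        ]

    def test_type_one_error_controlled(self, rng):
        # null datasets: the family-wise significant-cluster rate stays at
        # or below alpha (plus Monte-Carlo slack)
        n_datasets = 60
        hits = 0
        adj = AdjacencyGraph((frozenset({1}), frozenset({0})))
        for d in range(n_datasets):
            diffs = rng.standard_normal((8, 2, 25))
            res = permutation_test(
                diffs, adj, ClusterConfig(n_permutations=200, seed=d, exhaustive=False)
            )
            hits += bool(res.significant)
        rate = hits / n_datasets
        mc_se = np.sqrt(0.05 * 0.95 / n_datasets)
        assert rate <= 0.05 + 2 * mc_se


class TestEqualizeTrials:
    def test_equal_counts_untouched(self, epochs_factory, rng):
        a = epochs_factory(rng.standard_normal((10, 1, 20)))
        b = epochs_factory(rng.standard_normal((10, 1, 20)))
        a2, b2 = equalize_trials(a, b, seed=0)
        assert a2 is a and b2 is b

    def test_larger_side_subsampled(self, epochs_factory, rng):
        a = epochs_factory(rng.standard_normal((50, 1, 20)))
        b = epochs_factory(rng.standard_normal((30, 1, 20)))
        a2, b2 = equalize_trials(a, b, seed=1)
        assert a2.n_trials == b2.n_trials == 30
        # subset of the original trials, order preserved
        matches = [np.any(np.all(a.data == trial, axis=(1, 2))) for trial in a2.data]
        assert all(matches)

    def test_seed_determinism(self, epochs_factory, rng):
        a = epochs_factory(rng.standard_normal((40, 1, 10)))
        b = epochs_factory(rng.standard_normal((15, 1, 10)))
        a2, _ = equalize_trials(a, b, seed=9)
        a3, _ = equalize_trials(a, b, seed=9)
        np.testing.assert_array_equal(a2.data, a3.data)

    def test_empty_side_rejected(self, epochs_factory, rng):
        a = epochs_factory(np.empty((0, 1, 10)))
        b = epochs_factory(rng.standard_normal((5, 1, 10)))
        with pytest.raises(ValueError):
            equalize_trials(a, b)
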