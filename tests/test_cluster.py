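"""Cluster permutation statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from auderp import (build_adjacency, fibonacci_montage, form_clusters,
                    paired_t_map, permutation_test)
from auderp.cluster import Cluster, max_cluster_mass, paired_t
from auderp.containers import Erp

from oracles import bfs_clusters, exhaustive_cluster_p, scipy_paired_t


def _erps(layout, stack, subject_prefix="s"):
    """Wrap an (n_subjects, ch, time) stack as a list of Erp objects."""
    return [Erp(stack[i], -0.2, 500.0, 10, "A", layout,
                subject_id=f"{subject_prefix}{i}") for i in range(stack.shape[0])]


class TestPairedT:
    def test_hand_example(self):
        d = np.array([3.0, 1.0, 4.0, 1.0, 5.0])[:, None, None]
        t = paired_t(d)[0, 0]
        assert t == pytest.approx(2.8 / (1.78885 / np.sqrt(5)), abs=1e-4)
        assert t == pytest.approx(3.50, abs=0.005)
        # scipy as the independent statistics routine
        assert t == pytest.approx(stats.ttest_1samp(d[:, 0, 0], 0).statistic)

    def test_zero_variance_guarded(self):
        d = np.full((4, 2, 3), 2.0)
        assert np.all(paired_t(d) == 0)

    def test_identical_conditions_zero_map(self, layout8, rng):
        stack = rng.standard_normal((6, 8, 40))
        a = _erps(layout8, stack)
        b = _erps(layout8, stack)
        assert np.all(paired_t_map(a, b) == 0)

    def test_mismatched_subjects_rejected(self, layout8, rng):
        a = _erps(layout8, rng.standard_normal((4, 8, 10)))
        b = _erps(layout8, rng.standard_normal((4, 8, 10)), subject_prefix="t")
        with pytest.raises(ValueError):
            paired_t_map(a, b)


class TestClusterFormation:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle(self, seed):
        lay = fibonacci_montage(6)
        adj = build_adjacency(lay, 1.2)
        rng = np.random.default_rng(seed)
        t_map = rng.standard_normal((6, 10)) * 2
        df = 7
        clusters, thr = form_clusters(t_map, 0.2, df, adj)
        oracle = bfs_clusters(t_map, thr, adj.neighbors)
        assert len(clusters) == len(oracle)
        ours = sorted(frozenset(zip(c.channels.tolist(), c.times.tolist()))
                      for c in clusters)
        assert ours == sorted(o["members"] for o in oracle)
        for c, mass in zip(clusters, sorted((o["mass"] for o in oracle),
                                            reverse=True)):
            assert c.mass == pytest.approx(mass, abs=1e-9)

    def test_subthreshold_map_empty(self, layout8):
        adj = build_adjacency(layout8, 1.2)
        clusters, _ = form_clusters(np.zeros((8, 20)), 0.05, 9, adj)
        assert clusters == []

    def test_contiguous_block_single_cluster(self):
        lay = fibonacci_montage(6)
        adj = build_adjacency(lay, np.pi)  # fully connected
        t_map = np.zeros((6, 12))
        t_map[1:4, 3:8] = 5.0
        clusters, _ = form_clusters(t_map, 0.05, 9, adj)
        assert len(clusters) == 1
        assert clusters[0].n_samples == 15
        assert clusters[0].mass == pytest.approx(75.0)

    def test_max_mass_agrees_with_full_extraction(self, rng):
        lay = fibonacci_montage(12)
        adj = build_adjacency(lay, 0.8)
        t_map = rng.standard_normal((12, 30)) * 1.8
        clusters, thr = form_clusters(t_map, 0.1, 10, adj)
        best = max(c.mass for c in clusters) if clusters else 0.0
        assert max_cluster_mass(t_map, thr, adj) == pytest.approx(best)


class TestPermutationTest:
    def _paired_data(self, layout, n=8, n_t=15, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((n, layout.n_channels, n_t))
        a = base + rng.standard_normal((n, layout.n_channels, n_t))
        a[:, :2, 5:10] += effect
        b = base
        return _erps(layout, a), _erps(layout, b)

    def test_exhaustive_equals_enumeration_oracle(self):
        lay = fibonacci_montage(6)
        adj = build_adjacency(lay, 1.2)
        a, b = self._paired_data(lay, n=8, effect=1.5, seed=3)
        res = permutation_test(a, b, threshold_p=0.05, adjacency=adj,
                               exhaustive=True)
        assert res.n_permutations == 256
        diffs = np.stack([x.data - y.data for x, y in zip(a, b)])
        oracle = exhaustive_cluster_p(diffs, 0.05, adj.neighbors)
        assert len(res.clusters) == len(oracle)
        for c, o in zip(res.clusters, oracle):
            assert c.mass == pytest.approx(o["mass"], abs=1e-9)
            assert c.p == pytest.approx(o["p"], abs=1e-12)

    def test_identical_conditions_give_empty_result(self, layout8, rng):
        stack = rng.standard_normal((6, 8, 20))
        res = permutation_test(_erps(layout8, stack), _erps(layout8, stack),
                               n_permutations=100)
        assert res.clusters == []
        assert res.min_p == 1.0

    def test_p_floor_and_monotonicity(self):
        lay = fibonacci_montage(8)
        a, b = self._paired_data(lay, n=10, effect=2.5, seed=1)
        res = permutation_test(a, b, n_permutations=200, seed=5)
        assert all(c.p >= 1 / (res.n_permutations + 1) for c in res.clusters)
        masses = [c.mass for c in res.clusters]
        ps = [c.p for c in res.clusters]
        assert masses == sorted(masses, reverse=True)
        assert ps == sorted(ps)  # bigger mass, smaller (or equal) p

    def test_deterministic_per_seed(self):
        lay = fibonacci_montage(8)
        a, b = self._paired_data(lay, n=6, effect=1.0, seed=2)
        r1 = permutation_test(a, b, n_permutations=150, seed=9)
        r2 = permutation_test(a, b, n_permutations=150, seed=9)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]
        assert np.array_equal(r1.null_max_mass, r2.null_max_mass)

    def test_channel_relabelling_invariance(self):
        lay = fibonacci_montage(10)
        adj = build_adjacency(lay, 0.9)
        a, b = self._paired_data(lay, n=6, effect=2.0, seed=4)
        res = permutation_test(a, b, n_permutations=100, seed=0, adjacency=adj)

        perm = np.random.default_rng(0).permutation(10)
        from auderp.layout import SensorLayout
        lay_p = SensorLayout([lay.channel_names[i] for i in perm],
                             lay.positions[perm], "Cz")
        ap = [Erp(e.data[perm], e.tmin, e.srate, e.n_trials, e.condition,
                  lay_p, e.subject_id) for e in a]
        bp = [Erp(e.data[perm], e.tmin, e.srate, e.n_trials, e.condition,
                  lay_p, e.subject_id) for e in b]
        adj_p = build_adjacency(lay_p, 0.9)
        res_p = permutation_test(ap, bp, n_permutations=100, seed=0,
                                 adjacency=adj_p)
        assert sorted(c.mass for c in res.clusters) == pytest.approx(
            sorted(c.mass for c in res_p.clusters))

    def test_small_n_rejected(self, layout8, rng):
        a = _erps(layout8, rng.standard_normal((1, 8, 10)))
        with pytest.raises(ValueError):
            permutation_test(a, a, n_permutations=10)

    def test_matches_mne_observed_clusters(self):
        """Cross-check observed cluster masses against MNE's implementation."""
        mne = pytest.importorskip("mne")
        from scipy import sparse

        lay = fibonacci_montage(12)
        adj = build_adjacency(lay, 0.8)
        a, b = self._paired_data(lay, n=9, n_t=25, effect=1.2, seed=7)
        res = permutation_test(a, b, n_permutations=50, seed=0, adjacency=adj,
                               threshold_p=0.05)

        diffs = np.stack([x.data - y.data for x, y in zip(a, b)])
        n = diffs.shape[0]
        thr = stats.t.ppf(0.95, n - 1)
        mat = np.zeros((12, 12))
        for i, nb in enumerate(adj.neighbors):
            mat[i, nb] = 1
        X = diffs.transpose(0, 2, 1)  # MNE wants (obs, time, space)
        t_obs, clusters, _, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            X, threshold=thr, tail=1, adjacency=sparse.coo_matrix(mat),
            n_permutations=50, seed=0, out_type="indices", verbose=False)
        mne_masses = sorted(
            (t_obs[tidx, sidx].sum() for tidx, sidx in clusters), reverse=True)
        ours = sorted((c.mass for c in res.clusters), reverse=True)
        assert ours == pytest.approx(mne_masses, rel=1e-9)
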