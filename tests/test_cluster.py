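"""Cluster permutation statistics: t-maps, clustering, sign-flip nulls."""

import numpy as np
import pytest
from scipy import stats

from codefrp.cluster import (
    TMap,
    cluster_permutation_test,
    form_clusters,
    paired_t_map,
    summarize_clusters,
)
from codefrp.containers import DifferenceWaveSet
from codefrp.montage import AdjacencyGraph, load_default_adjacency


def _diffs(data, channels=None, t0=100.0, dt=10.0):
    data = np.asarray(data, float)
    n, E, T = data.shape
    if channels is None:
        channels = load_default_adjacency().nodes[:E]
    times = t0 + dt * np.arange(T)
    return DifferenceWaveSet(tuple(range(n)), tuple(channels), times, data)


def _chain_adjacency(channels):
    edges = frozenset(
        tuple(sorted((a, b))) for a, b in zip(channels, channels[1:])
    )
    return AdjacencyGraph(tuple(sorted(channels)), edges)


class TestTMap:
    def test_all_zero_diffs_give_zero_t(self):
        tm = paired_t_map(_diffs(np.zeros((4, 3, 5))), window_ms=(0, 1e9))
        assert np.all(tm.t == 0.0)

    def test_hand_computed_value(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [1.0, 2.0, 3.0]
        tm = paired_t_map(_diffs(data), window_ms=(0, 1e9))
        assert tm.t[0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-4)
        assert tm.t[0, 0] == pytest.approx(3.4641, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(5, 4, 6))
        t_pos = paired_t_map(_diffs(data), window_ms=(0, 1e9)).t
        t_neg = paired_t_map(_diffs(-data), window_ms=(0, 1e9)).t
        assert np.allclose(t_neg, -t_pos)

    def test_zero_variance_nonzero_mean_is_signed_infinity(self):
        data = np.ones((4, 1, 2))
        data[:, 0, 1] = -1.0
        tm = paired_t_map(_diffs(data), window_ms=(0, 1e9))
        assert tm.t[0, 0] == np.inf and tm.t[0, 1] == -np.inf

    def test_window_restriction(self):
        tm = paired_t_map(_diffs(np.zeros((3, 2, 10))), window_ms=(120, 150))
        assert len(tm.times_ms) == 4  # 120, 130, 140, 150


def _brute_force_clusters(t, mask, adjacency_pairs, min_size=2):
    """Flood fill over an explicit neighbour function (independent oracle)."""
    E, T = t.shape
    seen = set()
    clusters = []
    for e in range(E):
        for ti in range(T):
            if not mask[e, ti] or (e, ti) in seen:
                continue
            comp = []
            stack = [(e, ti)]
            seen.add((e, ti))
            while stack:
                ce, ct = stack.pop()
                comp.append((ce, ct))
                neigh = [(ce, ct - 1), (ce, ct + 1)] + [
                    (ne, ct) for ne in adjacency_pairs.get(ce, ())
                ]
                for ne, nt in neigh:
                    if 0 <= nt < T and 0 <= ne < E and mask[ne, nt] and (ne, nt) not in seen:
                        seen.add((ne, nt))
                        stack.append((ne, nt))
            if len(comp) >= min_size:
                clusters.append((frozenset(comp), t[tuple(zip(*comp))].sum()))
    return clusters


class TestClusterFormation:
    def _tmap(self, t, channels):
        return TMap(tuple(channels), 100.0 + 10.0 * np.arange(t.shape[1]), t, 9,
                    (100.0, 1000.0))

    def test_isolated_point_discarded(self):
        channels = ("Fz", "FCz", "Cz")
        t = np.zeros((3, 5))
        t[1, 2] = 5.0
        clusters = form_clusters(
            self._tmap(t, channels), 2.0, _chain_adjacency(channels), "greater"
        )
        assert clusters == []

    def test_two_consecutive_points_form_mass_seven(self):
        channels = ("Fz", "FCz", "Cz")
        t = np.zeros((3, 5))
        t[0, 1], t[0, 2] = 3.0, 4.0
        clusters = form_clusters(
            self._tmap(t, channels), 2.0, _chain_adjacency(channels), "greater"
        )
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(7.0)
        assert clusters[0].tmin_ms == 110.0 and clusters[0].tmax_ms == 120.0

    def test_matches_brute_force_flood_fill(self):
        rng = np.random.default_rng(1)
        adj = load_default_adjacency()
        channels = tuple(adj.nodes[:6])
        sub = adj.without(set(adj.nodes) - set(channels))
        idx = {c: i for i, c in enumerate(channels)}
        pairs: dict[int, list[int]] = {i: [] for i in range(6)}
        for a, b in sub.edges:
            pairs[idx[a]].append(idx[b])
            pairs[idx[b]].append(idx[a])
        for _ in range(100):
            t = rng.normal(size=(6, 10))
            thr = 0.8
            got = form_clusters(self._tmap(t, channels), thr, sub, "greater")
            want = _brute_force_clusters(t, t > thr, pairs)
            got_sets = {
                frozenset(m for m in c.members): round(c.mass, 9) for c in got
            }
            want_sets = {m: round(mass, 9) for m, mass in want}
            assert got_sets == want_sets


class TestPermutationTest:
    def test_all_zero_diffs_yield_no_clusters(self):
        adj = load_default_adjacency()
        res = cluster_permutation_test(
            _diffs(np.zeros((5, 24, 8))), adj, window_ms=(0, 1e9)
        )
        assert res.clusters == [] and res.mode == "exhaustive"

    def test_exhaustive_p_values_are_dyadic(self):
        rng = np.random.default_rng(2)
        adj = load_default_adjacency()
        data = rng.normal(size=(6, 24, 8)) + 0.6
        res = cluster_permutation_test(_diffs(data), adj, window_ms=(0, 1e9))
        assert res.n_permutations == 64
        for c in res.clusters:
            assert 0.0 < c.p_value <= 1.0
            assert (c.p_value * 64) == pytest.approx(round(c.p_value * 64))

    def test_sign_symmetry_between_directions(self):
        rng = np.random.default_rng(3)
        adj = load_default_adjacency()
        data = rng.normal(size=(6, 24, 8)) + 0.4
        up = cluster_permutation_test(_diffs(data), adj, "greater", window_ms=(0, 1e9))
        dn = cluster_permutation_test(_diffs(-data), adj, "less", window_ms=(0, 1e9))
        assert len(up.clusters) == len(dn.clusters)
        for cu, cd in zip(up.clusters, dn.clusters):
            assert cu.mass == pytest.approx(-cd.mass)
            assert cu.p_value == pytest.approx(cd.p_value)
            assert set(cu.members) == set(cd.members)

    def test_scaling_up_never_weakens_evidence(self):
        rng = np.random.default_rng(4)
        adj = load_default_adjacency()
        data = rng.normal(size=(6, 24, 8)) + 0.5
        base = cluster_permutation_test(_diffs(data), adj, window_ms=(0, 1e9))
        scaled = cluster_permutation_test(_diffs(3.0 * data), adj, window_ms=(0, 1e9))
        if base.clusters and scaled.clusters:
            assert scaled.clusters[0].p_value <= base.clusters[0].p_value + 1e-12

    def test_monte_carlo_agrees_with_exhaustive_for_five_participants(self):
        rng = np.random.default_rng(5)
        channels = ("Fz", "FCz", "Cz", "CPz")
        adj = _chain_adjacency(channels)
        data = rng.normal(size=(5, 4, 8)) + 0.7
        diffs = _diffs(data, channels=channels)
        exact = cluster_permutation_test(
            diffs, adj, window_ms=(0, 1e9), max_exhaustive=2**20
        )
        assert exact.mode == "exhaustive" and exact.n_permutations == 32
        mc = cluster_permutation_test(
            diffs, adj, window_ms=(0, 1e9), max_exhaustive=2,
            n_monte_carlo=10_000, seed=9,
        )
        assert mc.mode == "monte_carlo"
        assert len(exact.clusters) == len(mc.clusters)
        for ce, cm in zip(exact.clusters, mc.clusters):
            # 99% binomial interval around the exact p
            half = 2.576 * np.sqrt(ce.p_value * (1 - ce.p_value) / 10_000)
            assert abs(cm.p_value - ce.p_value) <= half + 1e-4

    def test_unstable_monte_carlo_rejected(self):
        adj = load_default_adjacency()
        with pytest.raises(ValueError, match="100"):
            cluster_permutation_test(
                _diffs(np.zeros((24, 24, 4))), adj, max_exhaustive=2,
                n_monte_carlo=50, window_ms=(0, 1e9),
            )

    def test_default_threshold_is_one_sided_critical_t(self):
        adj = load_default_adjacency()
        res = cluster_permutation_test(
            _diffs(np.zeros((8, 24, 4))), adj, window_ms=(0, 1e9)
        )
        assert res.threshold_t == pytest.approx(stats.t.ppf(0.95, 7))

    def test_agrees_with_mne_reference(self):
        """Independent cross-check: identical cluster masses and matching
        p-values (up to the permutation-counting convention) against MNE's
        spatio-temporal cluster test on the same data."""
        mne = pytest.importorskip("mne")
        import scipy.sparse as sp

        rng = np.random.default_rng(7)
        adj = load_default_adjacency()
        channels = tuple(adj.nodes[:8])
        sub = adj.without(set(adj.nodes) - set(channels))
        n, E, T = 6, len(channels), 10
        data = rng.normal(size=(n, E, T))
        data[:, :3, 3:7] += 1.2
        diffs = _diffs(data, channels=channels)
        res = cluster_permutation_test(
            diffs, sub, "greater", window_ms=(0, 1e9), min_size=1,
            max_exhaustive=2**10,
        )
        idx = {c: i for i, c in enumerate(channels)}
        rows, cols = [], []
        for a, b in sub.edges:
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
        A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(E, E))
        thr = float(stats.t.ppf(0.95, n - 1))
        tobs, clusters, pvals, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            np.transpose(data, (0, 2, 1)), threshold=thr, adjacency=A, tail=1,
            n_permutations="all", out_type="indices", verbose="error",
        )
        mne_masses = sorted(
            float(tobs[tidx, eidx].sum()) for tidx, eidx in clusters
        )
        our_masses = sorted(c.mass for c in res.clusters)
        assert np.allclose(our_masses, mne_masses)
        mne_by_mass = {
            round(float(tobs[tidx, eidx].sum()), 9): float(p)
            for (tidx, eidx), p in zip(clusters, pvals)
        }
        for c in res.clusters:
            assert abs(c.p_value - mne_by_mass[round(c.mass, 9)]) <= 2 / 2**n


class TestSummary:
    def test_empty_result_empty_table(self):
        adj = load_default_adjacency()
        res = cluster_permutation_test(
            _diffs(np.zeros((4, 24, 4))), adj, window_ms=(0, 1e9)
        )
        table = summarize_clusters(res)
        assert len(table) == 0
        assert list(table.columns)[:3] == ["direction", "tmin_ms", "tmax_ms"]

    def test_extent_and_tie_ordering(self):
        rng = np.random.default_rng(8)
        adj = load_default_adjacency()
        data = rng.normal(size=(6, 24, 12)) + 0.5
        res = cluster_permutation_test(_diffs(data), adj, window_ms=(0, 1e9))
        table = summarize_clusters(res)
        if len(table) >= 2:
            p = table["p_value"].to_numpy()
            assert (np.diff(p) >= -1e-12).all()
            for i in range(len(table) - 1):
                if p[i] == p[i + 1]:
                    assert abs(table["mass"][i]) >= abs(table["mass"][i + 1])
        for row in table.itertuples():
            assert row.tmin_ms <= row.tmax_ms
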