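"""Source-level ROI network: projection, coherence, betweenness, overlap."""

import itertools

import numpy as np
import pytest

from rippleloc import (
    betweenness_ranking,
    combined_localization,
    network_overlap,
    project_to_rois,
    resection_adjacent_labels,
    roi_coherence,
    roi_series_per_window,
)
from rippleloc.localize import SourceEstimate
from rippleloc.network import BetweennessRanking

FS = 1000.0


class TestProjectToRois:
    def test_single_roi_takes_grid_average(self, rng):
        series = rng.standard_normal((7, 100))
        labels = np.ones(7, dtype=int)
        out, empty = project_to_rois(series, labels, n_rois=90)
        assert np.allclose(out[0], series.mean(axis=0))
        assert len(empty) == 89
        assert np.allclose(out[1:], 0.0)

    def test_grid_permutation_invariance(self, rng):
        series = rng.standard_normal((30, 50))
        labels = rng.integers(1, 10, size=30)
        out1, _ = project_to_rois(series, labels, n_rois=10)
        perm = rng.permutation(30)
        out2, _ = project_to_rois(series[perm], labels[perm], n_rois=10)
        assert np.allclose(out1, out2)

    def test_toy_parcellation_covers_all_rois(self, forward_model, rng):
        series = rng.standard_normal((forward_model.n_sources, 40))
        out, empty = project_to_rois(series, forward_model.roi_labels)
        assert out.shape[0] == 90
        assert empty == []

    def test_bad_label_rejected(self, rng):
        with pytest.raises(ValueError, match="labels"):
            project_to_rois(rng.standard_normal((5, 10)), np.array([0, 1, 2, 3, 4]))


class TestRoiCoherence:
    def test_duplicated_series_coherence_one(self, rng):
        base = rng.standard_normal((4, 1, 200))
        wins = np.concatenate([base, base], axis=1)
        C = roi_coherence(wins, FS)
        assert C.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_series_low(self, rng):
        wins = rng.standard_normal((50, 5, 200))
        C = roi_coherence(wins, FS)
        off = C.values[~np.eye(5, dtype=bool)]
        assert (off < 0.2).all()

    def test_single_window_rejected(self, rng):
        with pytest.raises(ValueError):
            roi_coherence(rng.standard_normal((1, 5, 200)), FS)

    def test_symmetric_unit_diagonal(self, rng):
        C = roi_coherence(rng.standard_normal((6, 8, 128)), FS).values
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)


def brute_force_betweenness(adj):
    """Pair-normalized betweenness by explicit shortest-path enumeration."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        # BFS shortest-path DAG counting, independent of networkx
        dist = {s: 0}
        sigma = {s: 1.0}
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in np.nonzero(adj[u])[0]:
                    v = int(v)
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        sigma[v] = 0.0
                        nxt.append(v)
                        order.append(v)
                    if dist[v] == dist[u] + 1:
                        sigma[v] += sigma[u]
            frontier = nxt
        if t not in dist:
            continue
        # count, for every node v, shortest s-t paths through v
        sigma_rev = {t: 1.0}
        for v in reversed(order):
            if v in sigma_rev:
                continue
            tot = 0.0
            for u in np.nonzero(adj[v])[0]:
                u = int(u)
                if u in dist and dist.get(u) == dist[v] + 1 and u in sigma_rev:
                    tot += sigma_rev[u]
            sigma_rev[v] = tot
        for v in range(n):
            if v in (s, t) or v not in dist or dist[v] >= dist[t]:
                continue
            paths_through = sigma[v] * sigma_rev.get(v, 0.0)
            if paths_through:
                bc[v] += paths_through / sigma[t]
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def coherence_from_adj(adj):
    m = np.where(adj, 0.9, 0.1).astype(float)
    np.fill_diagonal(m, 1.0)
    return m


class TestBetweenness:
    def test_path_graph(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = True
        r = betweenness_ranking(coherence_from_adj(adj))
        assert np.allclose(r.betweenness, [0.0, 1.0, 0.0])
        assert r.ranking[0] == 2

    def test_complete_graph_all_zero(self):
        adj = ~np.eye(5, dtype=bool)
        r = betweenness_ranking(coherence_from_adj(adj))
        assert np.allclose(r.betweenness, 0.0)

    def test_matches_exhaustive_enumeration_small_graphs(self):
        """All connected graphs on <= 5 labeled nodes, exact equality."""
        checked = 0
        for n in (3, 4, 5):
            pairs = list(itertools.combinations(range(n), 2))
            for mask in range(1, 2 ** len(pairs)):
                adj = np.zeros((n, n), dtype=bool)
                for b, (i, j) in enumerate(pairs):
                    if mask >> b & 1:
                        adj[i, j] = adj[j, i] = True
                # connectivity check
                seen = {0}
                stack = [0]
                while stack:
                    u = stack.pop()
                    for v in np.nonzero(adj[u])[0]:
                        if v not in seen:
                            seen.add(int(v))
                            stack.append(int(v))
                if len(seen) != n:
                    continue
                r = betweenness_ranking(coherence_from_adj(adj))
                assert np.allclose(r.betweenness, brute_force_betweenness(adj), atol=1e-12)
                checked += 1
        assert checked > 500

    def test_matches_brute_force_random_8_node(self, rng):
        for _ in range(50):
            adj = rng.random((8, 8)) < 0.35
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            r = betweenness_ranking(coherence_from_adj(adj))
            assert np.allclose(r.betweenness, brute_force_betweenness(adj), atol=1e-12)

    def test_empty_graph_warns_label_order(self):
        m = np.full((6, 6), 0.1)
        np.fill_diagonal(m, 1.0)
        with pytest.warns(UserWarning, match="empty"):
            r = betweenness_ranking(m)
        assert r.ranking == [1, 2, 3, 4, 5, 6]
        assert np.allclose(r.betweenness, 0.0)


class TestNetworkOverlap:
    def test_full_overlap(self):
        assert network_overlap(list(range(1, 11)), set(range(1, 11))) == (10, 1.0)

    def test_disjoint(self):
        assert network_overlap([1, 2, 3], {50, 51}) == (0, 0.0)

    def test_empty_resection_rejected(self):
        with pytest.raises(ValueError):
            network_overlap([1], set())


def _est(roi):
    return SourceEstimate(power=np.ones(2), peak_index=0, peak_roi=roi)


def _ranking(top):
    n = 90
    return BetweennessRanking(betweenness=np.zeros(n),
                              ranking=top + [i for i in range(1, n + 1) if i not in top],
                              top=top)


class TestCombinedLocalization:
    def test_no_rescue_equals_plain(self):
        ests = [_est(1), _est(2), _est(50)]
        comb = combined_localization(ests, _ranking([70, 71]), {1}, adjacent={1, 2})
        assert comb == pytest.approx(1 / 3)

    def test_rescue_adds_adjacent_hub_events(self):
        ests = [_est(1), _est(2), _est(50)]
        comb = combined_localization(ests, _ranking([2, 71]), {1}, adjacent={1, 2})
        assert comb == pytest.approx(2 / 3)

    def test_monotone_vs_plain_on_random_instances(self, rng):
        from rippleloc import resection_overlap

        for _ in range(50):
            ests = [_est(int(r)) for r in rng.integers(1, 91, size=12)]
            res = set(int(r) for r in rng.integers(1, 91, size=3))
            top = [int(r) for r in rng.choice(np.arange(1, 91), size=10, replace=False)]
            adj = res | {int(r) for r in rng.integers(1, 91, size=5)}
            plain = resection_overlap(ests, res)
            comb = combined_localization(ests, _ranking(top), res, adjacent=adj)
            assert comb >= plain

    def test_adjacency_includes_resection(self, forward_model):
        adj = resection_adjacent_labels(forward_model, {7})
        assert 7 in adj
        assert len(adj) >= 1


def test_roi_series_shapes(forward_model, rng):
    wins = rng.standard_normal((3, 64, 120))
    series = roi_series_per_window(wins, forward_model)
    assert series.shape == (3, 90, 120)
    series_pw = roi_series_per_window(wins, forward_model, common_filter=False)
    assert series_pw.shape == (3, 90, 120)
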