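"""Graph embedding features: canonical closed-form values, brute-force and
networkx oracle equivalence, the radius/diameter inequality, and
monotonicity under edge addition."""

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pytest

from vgeeg.graph_features import (
    average_degree,
    density,
    feature_vector,
    global_efficiency,
    graph_entropy,
    max_clique_size,
    max_degree,
    radius_and_diameter,
)
from vgeeg.visibility import build_visibility_graph

from conftest import random_sequence


def adj(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


def complete(n):
    return adj(n, itertools.combinations(range(n), 2))


def path(n):
    return adj(n, [(i, i + 1) for i in range(n - 1)])


def star(leaves):
    return adj(leaves + 1, [(0, i) for i in range(1, leaves + 1)])


# -- independent oracles -----------------------------------------------------


def bfs_distances(a):
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in np.nonzero(a[u])[0]:
                if np.isinf(dist[src, v]):
                    dist[src, v] = dist[src, u] + 1
                    q.append(v)
    return dist


def brute_max_clique(a):
    n = a.shape[0]
    nbr = [int(sum(1 << j for j in np.nonzero(a[i])[0])) for i in range(n)]
    best = 1 if n else 0
    for mask in range(1, 1 << n):
        m, ok = mask, True
        while m:
            v = (m & -m).bit_length() - 1
            m &= m - 1
            if mask & ~(nbr[v] | (1 << v)):
                ok = False
                break
        if ok:
            best = max(best, int.bit_count(mask))
    return best


def random_connected(rng, n):
    a = path(n)
    extra = rng.random((n, n)) < 0.3
    extra = np.triu(extra, 1)
    a |= extra | extra.T
    return a


# -- canonical values --------------------------------------------------------


class TestCanonicalGraphs:
    def test_k5_feature_vector(self):
        fv = feature_vector(complete(5))
        assert fv.average_degree == 4.0
        assert fv.max_degree == 4
        assert fv.density == 1.0
        assert (fv.radius, fv.diameter) == (1, 1)
        assert fv.entropy == pytest.approx(2 * math.log(5))
        assert fv.global_efficiency == 1.0
        assert fv.max_clique_size == 5

    def test_single_edge_feature_vector(self):
        fv = feature_vector(complete(2))
        assert (fv.average_degree, fv.max_degree, fv.density) == (1.0, 1, 1.0)
        assert (fv.radius, fv.diameter) == (1, 1)
        # triangle-free: clustering term is zero
        assert fv.entropy == pytest.approx(math.log(2))
        assert fv.global_efficiency == 1.0
        assert fv.max_clique_size == 2

    def test_k4_entropy(self):
        assert graph_entropy(complete(4)) == pytest.approx(2 * math.log(4))

    def test_p4_values(self):
        a = path(4)
        assert average_degree(a) == 1.5
        assert density(a) == 0.5
        assert radius_and_diameter(a) == (2, 3)
        # degrees (1,2,2,1)/6; triangle-free so the q-term vanishes
        expected = -(2 * (1 / 6) * math.log(1 / 6) + 2 * (2 / 6) * math.log(2 / 6))
        assert graph_entropy(a) == pytest.approx(expected)
        assert graph_entropy(a) == pytest.approx(1.3297, abs=1e-4)

    def test_p3_global_efficiency(self):
        assert global_efficiency(path(3)) == pytest.approx(5 / 6)

    def test_p5_radius_diameter(self):
        assert radius_and_diameter(path(5)) == (2, 4)

    def test_star_radius_diameter_and_degree(self):
        a = star(5)
        assert radius_and_diameter(a) == (1, 2)
        assert max_degree(a) == 5

    def test_edgeless_degrees(self):
        a = np.zeros((3, 3), dtype=bool)
        assert max_degree(a) == 0
        assert average_degree(a) == 0.0
        with pytest.raises(ValueError):
            graph_entropy(a)

    def test_bipartite_clique_is_two(self):
        a = adj(6, [(i, j + 3) for i in range(3) for j in range(3)])
        assert max_clique_size(a) == 2

    def test_disconnected_radius_raises_but_efficiency_tolerates(self):
        a = np.zeros((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            radius_and_diameter(a)
        assert global_efficiency(a) == 0.0

    def test_convex_series_graph_matches_k5(self):
        g = build_visibility_graph([(s, (s - 2) ** 2) for s in range(5)])
        assert feature_vector(g) == feature_vector(complete(5))


# -- oracle equivalence ------------------------------------------------------


class TestOracleEquivalence:
    def test_metrics_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            a = random_connected(rng, n)
            dist = bfs_distances(a)
            deg = a.sum(axis=1)
            assert average_degree(a) == pytest.approx(deg.mean())
            assert max_degree(a) == deg.max()
            assert density(a) == pytest.approx(
                2 * np.triu(a).sum() / (n * (n - 1))
            )
            ecc = dist.max(axis=1)
            assert radius_and_diameter(a) == (int(ecc.min()), int(ecc.max()))
            inv = 1 / dist[dist > 0]
            assert global_efficiency(a) == pytest.approx(inv.sum() / (n * (n - 1)))
            assert max_clique_size(a) == brute_max_clique(a)

    def test_metrics_match_networkx(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 15))
            a = random_connected(rng, n)
            g = nx.from_numpy_array(a)
            assert density(a) == pytest.approx(nx.density(g))
            assert radius_and_diameter(a) == (nx.radius(g), nx.diameter(g))
            assert global_efficiency(a) == pytest.approx(nx.global_efficiency(g))
            assert max_clique_size(a) == max(
                len(c) for c in nx.find_cliques(g)
            )
            # entropy cross-check from networkx degree/clustering primitives
            deg = np.array([d for _, d in g.degree()], dtype=float)
            clus = np.array([nx.clustering(g, v) for v in g])
            h = 0.0
            for dist_vec in (deg, clus):
                if dist_vec.sum() > 0:
                    p = dist_vec / dist_vec.sum()
                    p = p[p > 0]
                    h += float(-(p * np.log(p)).sum())
            assert graph_entropy(a) == pytest.approx(h)


# -- invariants --------------------------------------------------------------


class TestInvariants:
    def test_radius_diameter_inequality_on_visibility_graphs(self):
        # r <= D <= 2r for every connected graph
        rng = np.random.default_rng(101)
        for _ in range(150):
            g = build_visibility_graph(random_sequence(rng, int(rng.integers(5, 40))))
            fv = feature_vector(g)
            assert fv.radius <= fv.diameter <= 2 * fv.radius

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(5, 12))
            a = random_connected(rng, n)
            perm = rng.permutation(n)
            b = a[np.ix_(perm, perm)]
            fa, fb = feature_vector(a), feature_vector(b)
            assert np.allclose(fa.as_array(), fb.as_array())

    def test_monotonicity_under_edge_addition(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            n = int(rng.integers(5, 12))
            a = random_connected(rng, n)
            missing = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if not a[i, j]
            ]
            if not missing:
                continue
            i, j = missing[int(rng.integers(len(missing)))]
            b = a.copy()
            b[i, j] = b[j, i] = True
            fa, fb = feature_vector(a), feature_vector(b)
            assert fb.average_degree >= fa.average_degree
            assert fb.max_degree >= fa.max_degree
            assert fb.density >= fa.density
            assert fb.global_efficiency >= fa.global_efficiency
            assert fb.max_clique_size >= fa.max_clique_size
            assert fb.diameter <= fa.diameter
            assert fb.radius <= fa.radius

    def test_feature_bounds(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            fv = feature_vector(build_visibility_graph(random_sequence(rng, n)))
            assert 0 <= fv.average_degree <= fv.max_degree <= n - 1
            assert 0 <= fv.density <= 1
            assert fv.entropy >= 0
            assert 0 <= fv.global_efficiency <= 1
            assert 1 <= fv.max_clique_size <= n
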