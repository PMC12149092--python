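"""Eight graph-theoretic embedding features of a visibility graph.

For a graph G = (V, E) on n nodes the feature vector is, in fixed order:

1. average degree          d_bar = 2|E| / n
2. maximum degree          Delta = max_v deg(v)
3. density                 D(G) = 2|E| / (n (n-1))
4. radius                  r = min_v max_u d(u, v)
5. diameter                D = max_v max_u d(u, v)
6. entropy                 H(G) = -sum_i p_i ln p_i - sum_i q_i ln q_i
7. global efficiency       E = (1/(n(n-1))) sum_{u != v} 1 / d(u, v)
8. maximum clique size     omega(G), exact

Distances d(u, v) are unweighted hop counts.  The entropy uses two
normalized distributions over nodes: p = degrees / sum(degrees) and
q = local clustering coefficients / sum(clustering coefficients); zero
entries contribute nothing (0 ln 0 := 0) and a triangle-free graph has a
zero q-term.  For any connected graph the radius and diameter satisfy
r <= D <= 2 r.

Maximum clique is computed exactly with Bron–Kerbosch branch and bound with
pivoting over bitset node sets; band-level visibility graphs are small
(n < ~150), so exact search is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .visibility import VisibilityGraph

__all__ = [
    "GraphFeatureVector",
    "FEATURE_NAMES",
    "average_degree",
    "max_degree",
    "density",
    "radius_and_diameter",
    "graph_entropy",
    "global_efficiency",
    "max_clique_size",
    "feature_vector",
]

FEATURE_NAMES: tuple[str, ...] = (
    "average_degree",
    "max_degree",
    "density",
    "radius",
    "diameter",
    "entropy",
    "global_efficiency",
    "max_clique_size",
)


@dataclass(frozen=True)
class GraphFeatureVector:
    average_degree: float
    max_degree: int
    density: float
    radius: int
    diameter: int
    entropy: float
    global_efficiency: float
    max_clique_size: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.average_degree,
                self.max_degree,
                self.density,
                self.radius,
                self.diameter,
                self.entropy,
                self.global_efficiency,
                self.max_clique_size,
            ],
            dtype=float,
        )


def _adjacency(g) -> np.ndarray:
    if isinstance(g, VisibilityGraph):
        return g.adjacency()
    a = np.asarray(g, dtype=bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(a != a.T) or np.any(np.diag(a)):
        raise ValueError("adjacency must be symmetric with empty diagonal")
    return a


def average_degree(g) -> float:
    a = _adjacency(g)
    n = a.shape[0]
    return float(a.sum()) / n  # sum of degrees = 2|E|


def max_degree(g) -> int:
    a = _adjacency(g)
    return int(a.sum(axis=1).max()) if a.shape[0] else 0


def density(g) -> float:
    a = _adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return float(a.sum()) / (n * (n - 1))


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="D", unweighted=True)


def radius_and_diameter(g) -> tuple[int, int]:
    a = _adjacency(g)
    if a.shape[0] == 1:
        return 0, 0
    d = _distance_matrix(a)
    if np.isinf(d).any():
        raise ValueError("radius/diameter undefined for a disconnected graph")
    ecc = d.max(axis=1)
    return int(ecc.min()), int(ecc.max())


def _local_clustering(a: np.ndarray) -> np.ndarray:
    """Local clustering coefficient per node: triangles through the node
    divided by deg (deg - 1) / 2; zero for degree < 2."""
    af = a.astype(float)
    deg = af.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", af, af, af) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _entropy_of(dist: np.ndarray) -> float:
    total = dist.sum()
    if total <= 0:
        return 0.0
    p = dist / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def graph_entropy(g) -> float:
    a = _adjacency(g)
    deg = a.sum(axis=1).astype(float)
    if deg.sum() == 0:
        raise ValueError("entropy undefined for an empty edge set")
    return _entropy_of(deg) + _entropy_of(_local_clustering(a))


def global_efficiency(g) -> float:
    a = _adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    d = _distance_matrix(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[np.isinf(d)] = 0.0  # unreachable pairs contribute nothing
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum()) / (n * (n - 1))


def max_clique_size(g) -> int:
    """Exact maximum clique via Bron–Kerbosch with pivoting on bitsets."""
    a = _adjacency(g)
    n = a.shape[0]
    if n == 0:
        return 0
    nbr = [0] * n
    for i in range(n):
        bits = 0
        for j in np.nonzero(a[i])[0]:
            bits |= 1 << int(j)
        nbr[i] = bits
    best = 1  # a single node is always a clique

    def expand(r_size: int, p: int, x: int) -> None:
        nonlocal best
        if p == 0 and x == 0:
            best = max(best, r_size)
            return
        if r_size + int.bit_count(p) <= best:
            return  # bound: cannot beat the incumbent
        # pivot: vertex of P|X with most neighbours in P
        px = p | x
        pivot, pivot_deg = -1, -1
        m = px
        while m:
            v = (m & -m).bit_length() - 1
            m &= m - 1
            dv = int.bit_count(nbr[v] & p)
            if dv > pivot_deg:
                pivot, pivot_deg = v, dv
        cand = p & ~nbr[pivot]
        while cand:
            v_bit = cand & -cand
            v = v_bit.bit_length() - 1
            cand &= cand - 1
            expand(r_size + 1, p & nbr[v], x & nbr[v])
            p &= ~v_bit
            x |= v_bit

    expand(0, (1 << n) - 1, 0)
    return best


def feature_vector(g) -> GraphFeatureVector:
    """All eight features of one (connected) visibility graph."""
    a = _adjacency(g)
    n = a.shape[0]
    deg = a.sum(axis=1).astype(float)
    d = _distance_matrix(a)
    if np.isinf(d).any():
        raise ValueError("feature vector requires a connected graph")
    ecc = d.max(axis=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return GraphFeatureVector(
        average_degree=float(deg.sum()) / n,
        max_degree=int(deg.max()),
        density=float(deg.sum()) / (n * (n - 1)),
        radius=int(ecc.min()),
        diameter=int(ecc.max()),
        entropy=_entropy_of(deg) + _entropy_of(_local_clustering(a)),
        global_efficiency=float(inv.sum()) / (n * (n - 1)),
        max_clique_size=max_clique_size(a),
    )
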