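"""Natural visibility graph construction over PSD sequences.

A PSD sequence is an ordered list of points (s_i, y_i) = (frequency, power).
Two points i < j are joined by an edge when every intermediate point k
(i < k < j) lies strictly below the straight chord from i to j:

    y_k  <  y_j + (y_i - y_j) * (s_j - s_k) / (s_j - s_i)

Adjacent points see each other vacuously, so every visibility graph contains
the path backbone 0-1-2-...-(n-1) and is therefore connected.  The
inequality is strict: a point exactly on the chord blocks visibility.

The builder runs in O(n^2) using, for each left endpoint i, the running
maximum of slopes to intermediate points — point j is visible from i iff
slope(i, j) strictly exceeds every slope(i, k) with i < k < j.  This is
algebraically identical to the chord criterion for strictly increasing s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .spectral import PSDSequence

__all__ = ["VisibilityGraph", "is_visible", "build_visibility_graph",
           "write_graph", "read_graph"]


@dataclass(frozen=True)
class VisibilityGraph:
    """Undirected simple graph on the points of one PSD sequence."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]  # (i, j) with i < j
    node_positions: np.ndarray  # (n_nodes, 2): (s, y)
    band: str = ""
    channel_label: str = ""
    window_index: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_sequence(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, PSDSequence):
        return points.frequencies, points.powers
    pts = np.asarray(points, dtype=float)
    return pts[:, 0], pts[:, 1]


def is_visible(points, i: int, j: int) -> bool:
    """Literal evaluation of the visibility criterion for one pair i < j."""
    s, y = _as_points(points)
    if not i < j:
        raise ValueError("require i < j")
    if np.any(np.diff(s) <= 0):
        raise ValueError("s values must be strictly increasing")
    for k in range(i + 1, j):
        chord = y[j] + (y[i] - y[j]) * (s[j] - s[k]) / (s[j] - s[i])
        if not y[k] < chord:
            return False
    return True


def build_visibility_graph(seq) -> VisibilityGraph:
    """Build the natural visibility graph of a PSD sequence (or any ordered
    sequence of (s, y) points)."""
    s, y = _as_points(seq)
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 points to build a visibility graph")
    if np.any(np.diff(s) <= 0):
        raise ValueError("s values must be strictly increasing")

    edges: set[tuple[int, int]] = set()
    for i in range(n - 1):
        edges.add((i, i + 1))
        slopes = (y[i + 2 :] - y[i]) / (s[i + 2 :] - s[i])
        # slope from i to the immediate neighbour, then running max of
        # slopes to all intermediate points
        first = (y[i + 1] - y[i]) / (s[i + 1] - s[i])
        inter_max = np.maximum.accumulate(
            np.concatenate(([first], slopes[:-1]))
        )
        visible = slopes > inter_max
        for off in np.nonzero(visible)[0]:
            edges.add((i, i + 2 + off))

    meta = {}
    if isinstance(seq, PSDSequence):
        meta = dict(
            band=seq.band.name,
            channel_label=seq.channel_label,
            window_index=seq.window_index,
        )
    return VisibilityGraph(
        n_nodes=n,
        edges=frozenset(edges),
        node_positions=np.column_stack([s, y]),
        **meta,
    )


def write_graph(g: VisibilityGraph, path: str | Path) -> Path:
    """Write a graph as a JSON header line followed by '<i> <j>' edge lines."""
    path = Path(path)
    header = json.dumps(
        {
            "n_nodes": g.n_nodes,
            "band": g.band,
            "channel": g.channel_label,
            "window": g.window_index,
        }
    )
    lines = [header] + [f"{i} {j}" for i, j in sorted(g.edges)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_graph(path: str | Path) -> VisibilityGraph:
    lines = Path(path).read_text().splitlines()
    meta = json.loads(lines[0])
    edges = frozenset(
        tuple(int(t) for t in ln.split()) for ln in lines[1:] if ln.strip()
    )
    n = meta["n_nodes"]
    return VisibilityGraph(
        n_nodes=n,
        edges=edges,
        node_positions=np.column_stack([np.arange(n, dtype=float), np.zeros(n)]),
        band=meta.get("band", ""),
        channel_label=meta.get("channel", ""),
        window_index=meta.get("window", 0),
    )
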