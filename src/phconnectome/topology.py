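"""Graph filtration and persistent homology of a distance network.

The filtration thresholds the distance network at a growing radius eps in
[0, 1] (strict rule ``d_ij < eps``) and tracks

* beta-0: connected components — M bars born at 0 whose finite deaths are
  exactly the single-linkage merge heights (minimum-spanning-tree edge
  weights);
* beta-1: independent cycles of the clique (Vietoris-Rips) complex built on
  the thresholded graph, restricted to dimension <= 2 so cycles can be
  filled in by triangles.

Edges with d_ij >= 1 never appear (eps ranges over [0, 1]); features that
survive the whole filtration are capped at death 1.  For every
positive-persistence cycle a deterministic representative is recorded: the
birth edge (u, v) closed by the hop-shortest, lexicographically smallest
path between u and v among strictly earlier edges.  Representatives feed the
per-subject frequency network, which counts how often each edge takes part
in a long-lived cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np

from .cohort import ParameterError
from .multiscale import DistanceNetwork

DEATH_CAP = 1.0


@dataclass
class Barcode:
    """Finite multiset of (birth, death) persistence intervals."""

    dim: int
    bars: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        if self.dim not in (0, 1):
            raise ParameterError("dim must be 0 or 1")
        if np.any(self.bars[:, 1] < self.bars[:, 0]):
            raise ParameterError("negative-length bar")


@dataclass
class CycleRecord:
    """A representative cycle fixed at its birth."""

    birth: float
    death: float
    nodes: tuple[int, ...]  # cyclic node order

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    @property
    def edge_set(self) -> frozenset[tuple[int, int]]:
        n = len(self.nodes)
        return frozenset(
            tuple(sorted((self.nodes[k], self.nodes[(k + 1) % n]))) for k in range(n)
        )


def _as_distance(dn) -> np.ndarray:
    d = dn.d if isinstance(dn, DistanceNetwork) else np.asarray(dn, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance network must be square")
    return d


def _sorted_edges(d: np.ndarray) -> list[tuple[float, int, int]]:
    """Edges with d < 1, ascending by (distance, i, j)."""
    m = d.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    keep = d[iu, ju] < DEATH_CAP
    edges = [(float(d[i, j]), int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]
    edges.sort()
    return edges


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def beta0_barcode(dn) -> Barcode:
    """Component persistence: M bars born at 0.

    Finite deaths are the merge distances of single linkage on d (one per
    MST edge); each component that never merges keeps an essential bar
    capped at death 1.
    """
    d = _as_distance(dn)
    m = d.shape[0]
    uf = _UnionFind(m)
    deaths = []
    for w, i, j in _sorted_edges(d):
        if uf.union(i, j):
            deaths.append(w)
    deaths.extend([DEATH_CAP] * (m - len(deaths)))
    bars = np.column_stack([np.zeros(m), np.sort(deaths)])
    return Barcode(0, bars)


def _bfs_path(adj: dict[int, list[int]], src: int, dst: int) -> list[int] | None:
    """Hop-shortest path with lexicographic tie-breaking (sorted neighbours)."""
    prev: dict[int, int] = {src: -1}
    queue = deque([src])
    while queue:
        node = queue.popleft()
        if node == dst:
            break
        for nb in sorted(adj.get(node, ())):
            if nb not in prev:
                prev[nb] = node
                queue.append(nb)
    if dst not in prev:
        return None
    path = [dst]
    while path[-1] != src:
        path.append(prev[path[-1]])
    return path[::-1]


def beta1_barcode(dn) -> tuple[Barcode, list[CycleRecord]]:
    """Cycle persistence of the clique complex (dimension <= 2).

    Standard boundary-matrix reduction over GF(2): edges that do not merge
    components create cycles; triangle columns (filtration value = longest
    side) are reduced and pair each killed cycle with its filling triangle.
    Zero-persistence pairs are discarded.  Returns the barcode and one
    deterministic representative per bar.
    """
    d = _as_distance(dn)
    m = d.shape[0]
    edges = _sorted_edges(d)
    edge_rank = {(i, j): r for r, (_, i, j) in enumerate(edges)}

    # dimension-0 pass: mark creator ("positive") edges
    uf = _UnionFind(m)
    positive = []
    for r, (_, i, j) in enumerate(edges):
        if not uf.union(i, j):
            positive.append(r)
    positive_set = set(positive)

    # triangles of the complex, sorted by (max edge distance, vertices)
    triangles = []
    nbrs: dict[int, set[int]] = {v: set() for v in range(m)}
    for _, i, j in edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    for i in range(m):
        for j in sorted(nbrs[i]):
            if j <= i:
                continue
            for k in sorted(nbrs[i] & nbrs[j]):
                if k <= j:
                    continue
                val = max(d[i, j], d[i, k], d[j, k])
                triangles.append((float(val), i, j, k))
    triangles.sort()

    # reduction of the triangle boundary matrix over GF(2)
    low_to_col: dict[int, set[int]] = {}
    pairs: dict[int, float] = {}  # positive edge rank -> death value
    for val, i, j, k in triangles:
        col = {
            edge_rank[(min(i, j), max(i, j))],
            edge_rank[(min(i, k), max(i, k))],
            edge_rank[(min(j, k), max(j, k))],
        }
        while col:
            low = max(col)
            if low not in low_to_col:
                break
            col ^= low_to_col[low]
        if col:
            low = max(col)
            low_to_col[low] = col
            if low in positive_set:
                pairs[low] = val

    bars = []
    cycles: list[CycleRecord] = []
    for r in positive:
        birth = edges[r][0]
        death = pairs.get(r, DEATH_CAP)
        if death <= birth:
            continue
        u, v = edges[r][1], edges[r][2]
        adj: dict[int, list[int]] = {}
        for _, a, b in edges[:r]:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        path = _bfs_path(adj, u, v)
        assert path is not None, "positive edge endpoints must be pre-connected"
        bars.append((birth, death))
        cycles.append(CycleRecord(birth, death, tuple(path)))

    bars_arr = np.array(bars, dtype=float).reshape(-1, 2)
    return Barcode(1, bars_arr), cycles


def components_at(dn, eps: float) -> int:
    """Connected components of the graph with edges d_ij < eps."""
    d = _as_distance(dn)
    m = d.shape[0]
    uf = _UnionFind(m)
    count = m
    for w, i, j in _sorted_edges(d):
        if w >= eps:
            break
        if uf.union(i, j):
            count -= 1
    return count


def frequency_network(
    cycles: list[CycleRecord],
    n_rois: int,
    mode: str = "probability",
    min_persistence: float | None = None,
) -> np.ndarray:
    """Integrate a subject's long-lived cycles into an edge-frequency matrix.

    ``min_persistence`` defaults to the median positive persistence of the
    subject's own cycles, keeping the longer-lived half ("long persistence
    carries signal, short persistence is noise").  ``probability`` mode gives
    the fraction of retained cycles containing each edge; the
    ``persistence_weighted`` mode weights each cycle by its persistence.
    """
    if mode not in ("probability", "persistence_weighted"):
        raise ParameterError("mode must be 'probability' or 'persistence_weighted'")
    f = np.zeros((n_rois, n_rois))
    if not cycles:
        return f
    pers = np.array([c.persistence for c in cycles])
    if min_persistence is None:
        min_persistence = float(np.median(pers))
    retained = [c for c in cycles if c.persistence >= min_persistence]
    if not retained:
        return f
    total = (
        float(len(retained))
        if mode == "probability"
        else float(sum(c.persistence for c in retained))
    )
    for c in retained:
        wgt = 1.0 if mode == "probability" else c.persistence
        for i, j in c.edge_set:
            f[i, j] += wgt
            f[j, i] += wgt
    return f / total
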