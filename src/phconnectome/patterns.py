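"""Group-specific connectivity patterns from frequency networks.

Per-group frequency networks are summed edge-wise; edges whose summed
frequency exceeds the other group's by at least ``epsilon_t`` (default 2)
form that group's binary difference network.  Loop structures — a minimum
cycle basis of each difference network — are extracted and ranked by their
edge count.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cohort import ParameterError


@dataclass
class DifferenceNetwork:
    delta: np.ndarray
    direction: str
    epsilon_t: float
    normalized: bool = False


@dataclass(frozen=True, order=True)
class Loop:
    """A simple cycle in canonical orientation; weight = number of edges."""

    nodes: tuple[int, ...]

    @property
    def weight(self) -> int:
        return len(self.nodes)

    @property
    def edge_set(self) -> frozenset[tuple[int, int]]:
        n = len(self.nodes)
        return frozenset(
            tuple(sorted((self.nodes[k], self.nodes[(k + 1) % n]))) for k in range(n)
        )


def aggregate_group(freq_nets: list[np.ndarray], normalized: bool = False) -> np.ndarray:
    """Entrywise sum of a group's frequency networks (mean if normalized)."""
    if not freq_nets:
        raise ParameterError("need at least one frequency network")
    mats = [np.asarray(f, dtype=float) for f in freq_nets]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ParameterError("frequency networks must share one shape")
    total = np.sum(mats, axis=0)
    return total / len(mats) if normalized else total


def difference_network(
    sum_a: np.ndarray,
    sum_b: np.ndarray,
    epsilon_t: float = 2.0,
    direction: str = "group_a_specific",
    strict_literal: bool = False,
) -> DifferenceNetwork:
    """Edges appearing at least ``epsilon_t`` more often in group A than B.

    ``strict_literal`` flips the comparison to a strict ``<`` (selecting
    edges *less* specific to group A), kept only for completeness.
    """
    a = np.asarray(sum_a, dtype=float)
    b = np.asarray(sum_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("matrices must share one shape")
    diff = a - b
    delta = (diff < epsilon_t) if strict_literal else (diff >= epsilon_t)
    delta = delta.astype(np.int8)
    np.fill_diagonal(delta, 0)
    delta = np.minimum(delta, delta.T)  # keep symmetric support only
    return DifferenceNetwork(delta, direction, float(epsilon_t))


def _canonical_cycle(nodes: list[int]) -> tuple[int, ...]:
    """Rotate/reflect so the smallest node is first and its smaller
    neighbour second."""
    n = len(nodes)
    start = nodes.index(min(nodes))
    rot = nodes[start:] + nodes[:start]
    if rot[1] > rot[-1]:
        rot = [rot[0]] + rot[1:][::-1]
    return tuple(rot)


def _order_cycle(node_set: set[int], graph: nx.Graph) -> tuple[int, ...] | None:
    """Order an (unordered) cycle-basis node set into a closed walk using
    graph edges; deterministic backtracking in sorted node order."""
    nodes = sorted(node_set)
    start = nodes[0]
    target_len = len(nodes)

    def extend(path: list[int], used: set[int]):
        cur = path[-1]
        for nb in sorted(graph.neighbors(cur)):
            if nb == start and len(path) == target_len:
                return path
            if nb in node_set and nb not in used:
                res = extend(path + [nb], used | {nb})
                if res is not None:
                    return res
        return None

    return None if target_len < 3 else (
        None if (res := extend([start], {start})) is None else _canonical_cycle(res)
    )


def extract_loops(delta: DifferenceNetwork | np.ndarray) -> list[Loop]:
    """Minimum cycle basis of the difference network, one Loop per element.

    The number of loops equals the cyclomatic number |E| - |V| + #components
    of the difference network.
    """
    mat = delta.delta if isinstance(delta, DifferenceNetwork) else np.asarray(delta)
    g = nx.from_numpy_array(mat)
    loops = []
    for cycle_nodes in nx.minimum_cycle_basis(g):
        ordered = _order_cycle(set(cycle_nodes), g)
        if ordered is not None:
            loops.append(Loop(ordered))
    loops.sort()
    return loops


def rank_loops(loops: list[Loop], k: int = 8) -> list[Loop]:
    """Top-k loops by weight (descending), ties broken by canonical node
    order; returns all loops when fewer than k exist."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    ranked = sorted(loops, key=lambda lp: (-lp.weight, lp.nodes))
    return ranked[:k]
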