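"""Independent oracles used by the test suite.

Everything here recomputes quantities by a different route than the package:
GF(2) boundary-matrix ranks for Betti numbers, scipy single-linkage for
component merge heights, brute-force tent evaluation for landscapes, and a
constrained quadratic program for the fused-lasso objective.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def gf2_rank(rows: list[set[int]]) -> int:
    """Rank over GF(2) of a sparse 0/1 matrix given as sets of column ids."""
    basis: dict[int, set[int]] = {}
    rank = 0
    for row in rows:
        row = set(row)
        while row:
            lead = max(row)
            if lead in basis:
                row ^= basis[lead]
            else:
                basis[lead] = row
                rank += 1
                break
    return rank


def betti_numbers_at(d: np.ndarray, eps: float) -> tuple[int, int]:
    """(beta0, beta1) of the clique complex (dim <= 2) of the graph with
    edges d_ij < eps, computed from scratch via boundary ranks."""
    m = d.shape[0]
    edges = [
        (i, j)
        for i, j in itertools.combinations(range(m), 2)
        if d[i, j] < eps and d[i, j] < 1.0
    ]
    edge_id = {e: k for k, e in enumerate(edges)}
    # beta0 = V - rank(d1); rank(d1) = V - #components
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    n_comp = len({find(v) for v in range(m)})

    adj = [set() for _ in range(m)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    tri_rows = []
    for i in range(m):
        for j in sorted(adj[i]):
            if j <= i:
                continue
            for k in sorted(adj[i] & adj[j]):
                if k > j:
                    tri_rows.append(
                        {edge_id[(i, j)], edge_id[(i, k)], edge_id[(j, k)]}
                    )
    rank_d2 = gf2_rank(tri_rows)
    beta1 = len(edges) - m + n_comp - rank_d2
    return n_comp, beta1


def single_linkage_merge_heights(d: np.ndarray) -> np.ndarray:
    """Sorted merge heights from scipy hierarchical clustering."""
    import scipy.cluster.hierarchy as sch
    from scipy.spatial.distance import squareform

    z = sch.linkage(squareform(d, checks=False), method="single")
    return np.sort(z[:, 2])


def brute_force_landscape(bars: np.ndarray, k: int, xs: np.ndarray) -> np.ndarray:
    """k-th largest (1-based) tent value at each x, by direct evaluation."""
    if len(bars) == 0:
        return np.zeros_like(xs)
    b = bars[:, 0][:, None]
    d = bars[:, 1][:, None]
    tents = np.maximum(np.minimum(xs[None, :] - b, d - xs[None, :]), 0.0)
    padded = np.vstack([tents, np.zeros((k, len(xs)))])
    return -np.sort(-padded, axis=0)[k - 1]


def qp_fused_lasso_objective(y, X, w, lam1, lam2) -> float:
    """Optimal objective of the column problem via a generic constrained QP
    (beta = p - q with p, q >= 0; slack s >= |pairwise difference|)."""
    n = X.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    npair = len(pairs)
    dim = 2 * n + npair

    def f(v):
        b = v[:n] - v[n : 2 * n]
        r = y - X @ b
        return (
            0.5 * r @ r
            + lam1 * np.sum(w * (v[:n] + v[n : 2 * n]))
            + 0.5 * lam2 * np.sum(v[2 * n :])
        )

    a1 = np.zeros((npair, dim))
    for r, (u, v) in enumerate(pairs):
        a1[r, u], a1[r, n + u] = 1.0, -1.0
        a1[r, v], a1[r, n + v] = -1.0, 1.0
        a1[r, 2 * n + r] = -1.0
    a2 = a1.copy()
    a2[:, : 2 * n] *= -1.0
    cons = [LinearConstraint(a1, -np.inf, 0.0), LinearConstraint(a2, -np.inf, 0.0)]
    res = minimize(
        f, np.zeros(dim), bounds=[(0.0, None)] * dim, constraints=cons,
        method="SLSQP", options={"maxiter": 3000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return float(res.fun)
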