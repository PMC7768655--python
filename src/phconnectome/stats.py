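"""Group-level and subject-level statistics.

Graph-theory metrics (local/global efficiency, clustering, betweenness) are
compared between groups with two-sample t-tests; persistent-homology
features (beta-0 derivative curves, beta-1 landscapes) with a label-
permutation test whose statistic is the distance between the two group-mean
feature objects.  Subject-level discriminability is summarized by the
distances-within-group / distances-between-group (DWG/DBG) panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import cdist, pdist

from .cohort import ParameterError


# ---------------------------------------------------------------------------
# graph metrics (binary undirected)


@dataclass(frozen=True)
class GraphMetrics:
    le: float  # local efficiency
    bet: float  # mean node betweenness (unnormalized shortest-path counts)
    ge: float  # global efficiency
    cco: float  # mean clustering coefficient


def _bfs_lengths(adj_list: list[np.ndarray], src: int, n: int) -> np.ndarray:
    dist = np.full(n, np.inf)
    dist[src] = 0
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj_list[u]:
                if dist[v] == np.inf:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    adj_list = [np.flatnonzero(adj[u]) for u in range(n)]
    total = 0.0
    for u in range(n):
        dist = _bfs_lengths(adj_list, u, n)
        finite = dist[(dist > 0) & np.isfinite(dist)]
        total += float(np.sum(1.0 / finite))
    return total / (n * (n - 1))


def _mean_betweenness(adj: np.ndarray) -> float:
    """Brandes' accumulation for unweighted graphs; undirected pairs counted
    once, matching the classic closed forms (star S5 center = 6)."""
    n = adj.shape[0]
    adj_list = [np.flatnonzero(adj[u]) for u in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            stack.append(v)
            for w in adj_list[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(stack):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return float(np.mean(bc / 2.0))


def graph_metrics(adj: np.ndarray) -> GraphMetrics:
    """All four binary-graph metrics of one network."""
    adj = np.asarray(adj)
    if not np.array_equal(adj, adj.T) or np.any(np.diag(adj) != 0):
        raise ParameterError("adjacency must be symmetric with zero diagonal")
    if not np.isin(adj, (0, 1)).all():
        raise ParameterError("adjacency must be binary")
    n = adj.shape[0]
    if adj.sum() == 0:
        warnings.warn("empty graph: all metrics zero", UserWarning, stacklevel=2)
        return GraphMetrics(0.0, 0.0, 0.0, 0.0)

    ge = _global_efficiency(adj)

    le_total = 0.0
    for u in range(n):
        nb = np.flatnonzero(adj[u])
        if len(nb) >= 2:
            le_total += _global_efficiency(adj[np.ix_(nb, nb)])
    le = le_total / n

    deg = adj.sum(axis=1).astype(float)
    tri = np.diag(adj @ adj @ adj) / 2.0
    possible = deg * (deg - 1) / 2.0
    local_c = np.divide(tri, possible, out=np.zeros(n), where=possible > 0)
    cco = float(local_c.mean())

    return GraphMetrics(le=le, bet=_mean_betweenness(adj), ge=ge, cco=cco)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    measure: str
    p_value: float
    statistic: float
    method: str
    n_permutations: int = 0


def ttest_groups(values_a, values_b, measure: str = "") -> GroupComparison:
    """Two-sided two-sample t-test (equal variances)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if np.isclose(a.mean(), b.mean()):
            warnings.warn("zero variance in both groups; p set to 1", UserWarning)
            return GroupComparison(measure, 1.0, 0.0, "t_test")
    stat, p = scipy.stats.ttest_ind(a, b)
    if np.isnan(p):
        warnings.warn("degenerate t-test; p set to 1", UserWarning)
        stat, p = 0.0, 1.0
    return GroupComparison(measure, float(p), float(stat), "t_test")


def mean_distance_statistic(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Default permutation statistic: Euclidean distance between group means."""
    return float(
        np.linalg.norm(features_a.mean(axis=0) - features_b.mean(axis=0))
    )


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    statistic=mean_distance_statistic,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    measure: str = "",
) -> GroupComparison:
    """Label-permutation test with add-one p-value.

    ``features`` is (n_subjects, n_features); ``labels`` binary.  The
    observed statistic is compared against ``n_perm`` uniformly drawn label
    permutations; p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ParameterError("labels must contain exactly two groups")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    mask = labels == classes[0]
    observed = statistic(features[mask], features[~mask])
    n = len(labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm = mask[perm]
        if statistic(features[pm], features[~pm]) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return GroupComparison(measure, float(p), float(observed), "permutation", n_perm)


# ---------------------------------------------------------------------------
# DWG / DBG panel


@dataclass
class DistancePanel:
    dwg_a: np.ndarray
    dwg_b: np.ndarray
    dbg: np.ndarray
    p_l: float = field(default=np.nan)
    p_r: float = field(default=np.nan)


def dwg_dbg(feature_vectors: np.ndarray, labels: np.ndarray) -> DistancePanel:
    """Pairwise Euclidean distances split into within/between-group vectors.

    27 subjects in a group give C(27, 2) = 351 within-group distances; 27 vs
    36 give 972 between-group distances.  p_l / p_r compare each DWG column
    against DBG by two-sample t-test.
    """
    x = np.asarray(feature_vectors, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ParameterError("labels must contain exactly two groups")
    xa, xb = x[labels == classes[0]], x[labels == classes[1]]
    for name, arr in (("group A", xa), ("group B", xb)):
        if len(arr) < 2:
            warnings.warn(f"{name} has < 2 subjects; its DWG is empty", UserWarning)
    dwg_a = pdist(xa) if len(xa) >= 2 else np.empty(0)
    dwg_b = pdist(xb) if len(xb) >= 2 else np.empty(0)
    dbg = cdist(xa, xb).ravel()
    p_l = ttest_groups(dwg_a, dbg).p_value if len(dwg_a) >= 2 else np.nan
    p_r = ttest_groups(dwg_b, dbg).p_value if len(dwg_b) >= 2 else np.nan
    return DistancePanel(dwg_a, dwg_b, dbg, p_l, p_r)


# ---------------------------------------------------------------------------
# parameter grid search


def grid_search(
    records,
    n_lambda1_candidates=(100, 200, 300, 400, 500),
    lambda2_candidates=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    measures=("PH-0",),
    n_perm: int = 1000,
    seed: int = 0,
    **pipeline_opts,
) -> pd.DataFrame:
    """Evaluate the full pipeline at every {N_lambda1, lambda2} cell.

    Returns a tidy frame (n_lambda1, lambda2, measure, p_value, statistic);
    the best cell for a measure is the row with minimal p (most specific
    group difference).
    """
    from .pipeline import cohort_group_tests  # deferred: circular import

    if not len(n_lambda1_candidates) or not len(lambda2_candidates):
        raise ParameterError("candidate lists must be nonempty")
    rows = []
    for n_l1 in n_lambda1_candidates:
        for l2 in lambda2_candidates:
            comparisons = cohort_group_tests(
                records, n_lambda1=int(n_l1), lambda2=float(l2),
                measures=measures, n_perm=n_perm, seed=seed, **pipeline_opts,
            )
            for comp in comparisons:
                rows.append(
                    {"n_lambda1": int(n_l1), "lambda2": float(l2),
                     "measure": comp.measure, "p_value": comp.p_value,
                     "statistic": comp.statistic, "method": comp.method}
                )
    return pd.DataFrame(rows)


def best_cell(table: pd.DataFrame, measure: str) -> pd.Series:
    sub = table[table["measure"] == measure]
    return sub.loc[sub["p_value"].idxmin()]
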