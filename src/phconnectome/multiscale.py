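"""Regularization sweep and multiscale integration.

Instead of committing to one sparsity level, the model is fitted over a
uniform grid of L1 strengths lambda1 in [0, 0.9].  The resulting stack of
binary networks is integrated into edge appearance probabilities
``p_ij = (# networks containing edge ij) / n`` and converted to the distance
network ``d_ij = sqrt(1 - p_ij^2)`` that seeds the graph filtration: edges
that survive heavy regularization get small distances and enter the
filtration early.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path

from .cohort import ParameterError
from .network import (
    PenaltyMatrix,
    binarize,
    fit_column,
    standardize_bold,
    uniform_penalty,
)


@dataclass
class NetworkGroup:
    """Binary adjacencies indexed by a strictly increasing lambda1 grid."""

    lambdas: np.ndarray
    adjacencies: list[np.ndarray]

    @property
    def n(self) -> int:
        return len(self.adjacencies)

    def validate(self) -> "NetworkGroup":
        if np.any(np.diff(self.lambdas) <= 0):
            raise ParameterError("lambdas must be strictly increasing")
        if len(self.adjacencies) != len(self.lambdas):
            raise ParameterError("one adjacency per lambda required")
        return self


@dataclass
class DistanceNetwork:
    """Appearance probabilities p and filtration distances d = sqrt(1 - p^2)."""

    p: np.ndarray
    d: np.ndarray


def lambda_grid(n_lambda1: int, lambda_range=(0.0, 0.9)) -> np.ndarray:
    if n_lambda1 < 2:
        raise ParameterError("n_lambda1 must be >= 2")
    lo, hi = lambda_range
    if not hi > lo >= 0:
        raise ParameterError("lambda_range must satisfy 0 <= lo < hi")
    return np.linspace(lo, hi, n_lambda1)


def _sweep_lasso_path(xs: np.ndarray, d: np.ndarray, lambdas: np.ndarray, tol: float):
    """Fast sweep for lambda2 = 0 via coordinate-descent lasso paths.

    Our objective 0.5||y - Xb||^2 + l1 * sum_j w_j |b_j| maps onto sklearn's
    (1/2T)||y - X'theta||^2 + alpha ||theta||_1 with columns scaled by 1/w_j
    and alpha = l1 / T; the support (all we keep) is invariant to the column
    rescaling b_j = theta_j / w_j.
    """
    t, m = xs.shape
    supports = np.zeros((len(lambdas), m, m), dtype=bool)
    pos_idx = np.flatnonzero(lambdas > 0)
    zero_idx = np.flatnonzero(lambdas <= 0)
    alphas = lambdas[pos_idx][::-1] / t  # sklearn wants decreasing
    for i in range(m):
        others = np.delete(np.arange(m), i)
        w = d[others, i]
        x_scaled = xs[:, others] / w
        if len(pos_idx):
            path_alphas, coefs, _ = lasso_path(x_scaled, xs[:, i], alphas=alphas)
            order = np.argsort(path_alphas)  # increasing alpha == increasing lambda
            for rank, k in enumerate(pos_idx):
                # path coefficients live in the rescaled space: b_j = theta_j / w_j
                supports[k, others, i] = np.abs(coefs[:, order[rank]]) > tol * w
        if len(zero_idx):
            beta, *_ = np.linalg.lstsq(xs[:, others], xs[:, i], rcond=None)
            for k in zero_idx:
                supports[k, others, i] = np.abs(beta) > tol
    return supports


def sweep_lambda1(
    bold: np.ndarray,
    pen: PenaltyMatrix | None,
    n_lambda1: int,
    lambda2: float = 0.0,
    lambda_range=(0.0, 0.9),
    fused_pairs: str = "all",
    binarize_tol: float = 1e-6,
    **solver_opts,
) -> NetworkGroup:
    """Fit + binarize the network at each lambda1 on a uniform grid.

    With lambda2 = 0 the sweep is a weighted lasso path (coordinate descent,
    warm-started internally by sklearn); with lambda2 > 0 each column is
    solved by ADMM, warm-started in increasing lambda1 order.
    """
    lambdas = lambda_grid(n_lambda1, lambda_range)
    xs = standardize_bold(np.asarray(bold, dtype=float))
    m = xs.shape[1]
    d = pen.d if pen is not None else uniform_penalty(m).d

    if lambda2 == 0.0 and fused_pairs == "all":
        supp = _sweep_lasso_path(xs, d, lambdas, binarize_tol)
        adjacencies = []
        for k in range(len(lambdas)):
            adj = (supp[k] | supp[k].T).astype(np.int8)
            np.fill_diagonal(adj, 0)
            adjacencies.append(adj)
        return NetworkGroup(lambdas, adjacencies).validate()

    coef_stack = np.zeros((len(lambdas), m, m))
    for i in range(m):
        others = np.delete(np.arange(m), i)
        warm = None
        for k, lam1 in enumerate(lambdas):
            fit = fit_column(
                xs[:, i], xs[:, others], d[others, i], lam1, lambda2,
                warm_start=warm, **solver_opts,
            )
            coef_stack[k, others, i] = fit.beta
            warm = fit.beta  # primal warm start for the next lambda1
    adjacencies = [binarize(coef_stack[k], binarize_tol) for k in range(len(lambdas))]
    return NetworkGroup(lambdas, adjacencies).validate()


def integrate(group: NetworkGroup) -> DistanceNetwork:
    """Edge appearance probabilities and the distance transform."""
    if group.n == 0:
        raise ParameterError("network group is empty")
    p = np.mean([a.astype(float) for a in group.adjacencies], axis=0)
    d = np.sqrt(1.0 - p**2)
    np.fill_diagonal(d, 0.0)
    return DistanceNetwork(p=p, d=d)


class MultiscaleDistance(BaseEstimator):
    """Estimator form of the sweep: fit(X) -> distances_ ready for filtration.

    Attributes
    ----------
    group_ : NetworkGroup
    probabilities_ : ndarray, edge appearance probabilities
    distances_ : ndarray, filtration distance network
    """

    def __init__(
        self,
        n_lambda1: int = 20,
        lambda2: float = 0.0,
        penalty: PenaltyMatrix | None = None,
        lambda_range=(0.0, 0.9),
        fused_pairs: str = "all",
        binarize_tol: float = 1e-6,
    ):
        self.n_lambda1 = n_lambda1
        self.lambda2 = lambda2
        self.penalty = penalty
        self.lambda_range = lambda_range
        self.fused_pairs = fused_pairs
        self.binarize_tol = binarize_tol

    def fit(self, X: np.ndarray, y=None):
        group = sweep_lambda1(
            X, self.penalty, self.n_lambda1, self.lambda2,
            self.lambda_range, self.fused_pairs, self.binarize_tol,
        )
        dn = integrate(group)
        self.group_ = group
        self.probabilities_ = dn.p
        self.distances_ = dn.d
        self.n_features_in_ = X.shape[1]
        return self
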