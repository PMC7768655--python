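"""Per-subject brain-network construction.

Three network models are provided:

* :func:`pearson_fc` — the classic pairwise Pearson functional-connectivity
  baseline;
* the structural matrix itself (the SC baseline needs no model);
* :class:`FusedNetworkRegression` — the fused multimodal model.  Each
  region's standardized BOLD series is regressed on all other regions with an
  L1 penalty whose per-coefficient weight ``D_ji = exp(-rho_ji^2 / sigma)``
  decreases with structural connection strength ``rho_ji`` (strong anatomy
  => cheap functional edge), plus a generalized fused-lasso term
  ``(lambda2/2) * sum_{(u,v)} |beta_u - beta_v|`` shrinking coefficient
  differences within the column toward zero.

The column subproblem

    min_b 0.5 ||y - X b||^2 + lambda1 * sum_j D_j |b_j|
                            + (lambda2/2) * sum_{(u,v)} |b_u - b_v|

is a generalized lasso, solved by ADMM on the splitting ``z = F b`` where F
stacks the weighted identity and the pairwise difference operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .cohort import ParameterError, SubjectRecord


# ---------------------------------------------------------------------------
# standardization and baselines


def standardize_bold(bold: np.ndarray) -> np.ndarray:
    """Center each column and scale it to unit L2 norm.

    On unit-norm columns cross products are plain correlations, so absolute
    L1 penalties in [0, 0.9] sweep the support from dense to (near-)empty and
    one grid is comparable across subjects.
    """
    x = np.asarray(bold, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(x, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return x / safe


def pearson_fc(bold: np.ndarray) -> np.ndarray:
    """Pearson correlation network with unit diagonal.

    Constant columns get zero correlations (with a warning) instead of NaN.
    """
    x = np.asarray(bold, dtype=float)
    if x.shape[0] < 3:
        raise ParameterError("need at least 3 time points for correlations")
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s); correlations set to 0",
            UserWarning, stacklevel=2,
        )
        x = x.copy()
        x[:, constant] = np.random.default_rng(0).standard_normal((x.shape[0], int(constant.sum())))
        r = np.corrcoef(x, rowvar=False)
        r[constant, :] = 0.0
        r[:, constant] = 0.0
        np.fill_diagonal(r, 1.0)
        return r
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# structural penalty


@dataclass(frozen=True)
class PenaltyMatrix:
    """SC-derived L1 weights ``d_ji = exp(-rho_ji^2 / sigma)``; diagonal unused."""

    d: np.ndarray
    sigma: float


def penalty_sigma(sc_matrices: list[np.ndarray], mode: str = "within_subject") -> float:
    """Data-driven bandwidth for the penalty kernel.

    ``within_subject`` (default): the variance of each subject's off-diagonal
    SC elements, averaged over subjects — of the same order as typical
    squared weights, so the kernel spreads over (0, 1] and genuinely blends
    the modalities.  ``across_subject``: the per-edge variance taken across
    subjects, averaged over edges; with small subject-level variability this
    collapses the kernel to a near-binary structural mask.
    """
    stack = np.stack([np.asarray(s, dtype=float) for s in sc_matrices])
    m = stack.shape[1]
    off = ~np.eye(m, dtype=bool)
    if mode == "within_subject":
        sigma = float(np.mean([s[off].var(ddof=1) for s in stack]))
    elif mode == "across_subject":
        var = stack.var(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros((m, m))
        sigma = float(var[off].mean())
    else:
        raise ParameterError("mode must be 'within_subject' or 'across_subject'")
    if sigma <= 0:
        raise ParameterError(
            "auto sigma is non-positive (no SC variability); supply sigma explicitly"
        )
    return sigma


def penalty_matrix(sc, sigma="auto", cohort_sc=None, d_floor: float = 1e-3) -> PenaltyMatrix:
    """Build the penalty matrix for one subject's SC.

    ``sigma='auto'`` computes the bandwidth from ``cohort_sc`` (a list of SC
    matrices).  Entries are in (0, 1]: absent structural connections
    (rho = 0) get the maximal weight 1.  ``d_floor`` bounds the weights away
    from zero: below it a coefficient is effectively unpenalized on the
    lambda grid anyway, and exactly-zero weights would break the
    weighted-lasso column rescaling.
    """
    sc = np.asarray(sc, dtype=float)
    if sigma == "auto":
        if cohort_sc is None:
            raise ParameterError("sigma='auto' requires cohort_sc")
        sigma = penalty_sigma(cohort_sc)
    sigma = float(sigma)
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    d = np.maximum(np.exp(-(sc**2) / sigma), d_floor)
    np.fill_diagonal(d, 0.0)  # self-regression excluded; diagonal unused
    return PenaltyMatrix(d=d, sigma=sigma)


def uniform_penalty(n_rois: int) -> PenaltyMatrix:
    """All-ones weights: reduces the fused model to an unweighted lasso."""
    d = np.ones((n_rois, n_rois))
    np.fill_diagonal(d, 0.0)
    return PenaltyMatrix(d=d, sigma=np.inf)


# ---------------------------------------------------------------------------
# ADMM column solver


@dataclass
class ColumnFit:
    beta: np.ndarray
    objective: float
    converged: bool
    n_iter: int


def _pair_index(n: int, pairs) -> np.ndarray:
    if pairs is None:
        iu = np.triu_indices(n, k=1)
        return np.column_stack(iu)
    return np.asarray(pairs, dtype=int)


def column_objective(y, X, beta, weights, lambda1, lambda2, pairs=None) -> float:
    """Objective of the column subproblem at ``beta``."""
    pr = _pair_index(X.shape[1], pairs)
    resid = y - X @ beta
    obj = 0.5 * float(resid @ resid) + lambda1 * float(np.abs(beta) @ weights)
    if lambda2 > 0 and len(pr):
        obj += 0.5 * lambda2 * float(np.abs(beta[pr[:, 0]] - beta[pr[:, 1]]).sum())
    return obj


def fit_column(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    lambda1: float,
    lambda2: float,
    pairs=None,
    rho: float = 1.0,
    max_iter: int = 5000,
    abstol: float = 1e-6,
    reltol: float = 1e-4,
    warm_start=None,
) -> ColumnFit:
    """Solve one region's generalized fused-lasso regression by ADMM.

    ``pairs`` is the index set of the fused term over the n = X.shape[1]
    coefficients (default: all unordered pairs).  ``warm_start`` may carry
    ``(beta, z, u)`` from a neighbouring regularization value.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    weights = np.asarray(weights, dtype=float)
    if lambda1 < 0 or lambda2 < 0:
        raise ParameterError("lambda1 and lambda2 must be nonnegative")

    pr = _pair_index(n, pairs)

    # rows of F: lambda1-weighted identity, then (lambda2/2)-scaled differences
    blocks = []
    if lambda1 > 0:
        blocks.append(np.diag(lambda1 * weights))
    if lambda2 > 0 and len(pr):
        d_op = np.zeros((len(pr), n))
        d_op[np.arange(len(pr)), pr[:, 0]] = 0.5 * lambda2
        d_op[np.arange(len(pr)), pr[:, 1]] = -0.5 * lambda2
        blocks.append(d_op)

    if not blocks:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        obj = column_objective(y, X, beta, weights, lambda1, lambda2, pairs)
        return ColumnFit(beta, obj, True, 0)

    f_op = np.vstack(blocks)
    m_rows = f_op.shape[0]
    gram = X.T @ X + rho * (f_op.T @ f_op)
    # tiny ridge guards rank deficiency when T < M and lambda1 == 0
    gram += 1e-12 * np.eye(n)
    cho = scipy.linalg.cho_factor(gram)
    xty = X.T @ y

    if warm_start is None:
        beta = np.zeros(n)
        z = np.zeros(m_rows)
        u = np.zeros(m_rows)
    elif isinstance(warm_start, tuple):
        beta, z, u = (np.array(a, dtype=float) for a in warm_start)
    else:  # primal-only warm start
        beta = np.array(warm_start, dtype=float)
        z = f_op @ beta
        u = np.zeros(m_rows)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta = scipy.linalg.cho_solve(cho, xty + rho * (f_op.T @ (z - u)))
        fb = f_op @ beta
        z_old = z
        z = np.sign(fb + u) * np.maximum(np.abs(fb + u) - 1.0 / rho, 0.0)
        u = u + fb - z

        r_norm = np.linalg.norm(fb - z)
        s_norm = np.linalg.norm(rho * (f_op.T @ (z - z_old)))
        eps_pri = np.sqrt(m_rows) * abstol + reltol * max(
            np.linalg.norm(fb), np.linalg.norm(z)
        )
        eps_dual = np.sqrt(n) * abstol + reltol * np.linalg.norm(rho * (f_op.T @ u))
        if r_norm <= eps_pri and s_norm <= eps_dual:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"ADMM did not converge in {max_iter} iterations "
            f"(lambda1={lambda1}, lambda2={lambda2})",
            UserWarning, stacklevel=2,
        )
    obj = column_objective(y, X, beta, weights, lambda1, lambda2, pairs)
    return ColumnFit(beta, obj, converged, it)


# ---------------------------------------------------------------------------
# whole-network estimator


@dataclass
class CoefficientNetwork:
    """M x M coefficient matrix B; column i holds region i's regression."""

    b: np.ndarray
    lambda1: float
    lambda2: float
    objective_values: np.ndarray
    converged: np.ndarray


class FusedNetworkRegression(BaseEstimator):
    """Sparse multimodal network model (sklearn-style estimator).

    Parameters
    ----------
    lambda1 : float
        L1 strength; with ``penalty=None`` and ``lambda2=0`` this is a plain
        lasso network.
    lambda2 : float
        Generalized fused-lasso strength on within-column coefficient
        differences.
    penalty : PenaltyMatrix or None
        SC-derived per-coefficient L1 weights; None means all ones.
    fused_pairs : {"all", "sc"}
        Pair set of the fused term: every unordered coefficient pair, or only
        structurally connected pairs (requires ``penalty`` built from SC with
        ``sc_matrix`` passed to :meth:`fit`).
    standardize : bool
        Center/unit-norm columns before fitting (recommended; the lambda grid
        assumes it).

    Attributes
    ----------
    coef_net_ : ndarray of shape (M, M)
        Coefficient matrix, zero diagonal; ``coef_net_[j, i]`` is the weight
        of region j in region i's regression.
    objective_values_, converged_ : per-column solver diagnostics.
    """

    def __init__(
        self,
        lambda1: float = 0.3,
        lambda2: float = 0.0,
        penalty: PenaltyMatrix | None = None,
        fused_pairs: str = "all",
        standardize: bool = True,
        rho: float = 1.0,
        max_iter: int = 5000,
        abstol: float = 1e-6,
        reltol: float = 1e-4,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.penalty = penalty
        self.fused_pairs = fused_pairs
        self.standardize = standardize
        self.rho = rho
        self.max_iter = max_iter
        self.abstol = abstol
        self.reltol = reltol

    def fit(self, X: np.ndarray, y=None, sc_matrix: np.ndarray | None = None):
        """Fit all M per-region regressions of the BOLD matrix ``X`` (T x M)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be a T x M matrix")
        m = X.shape[1]
        if self.fused_pairs not in ("all", "sc"):
            raise ParameterError("fused_pairs must be 'all' or 'sc'")
        xs = standardize_bold(X) if self.standardize else X

        d = self.penalty.d if self.penalty is not None else uniform_penalty(m).d
        if d.shape != (m, m):
            raise ParameterError("penalty shape does not match data")

        b = np.zeros((m, m))
        objs = np.zeros(m)
        conv = np.zeros(m, dtype=bool)
        for i in range(m):
            others = np.delete(np.arange(m), i)
            pairs = None
            if self.fused_pairs == "sc":
                if sc_matrix is None:
                    raise ParameterError("fused_pairs='sc' requires sc_matrix")
                sub = np.asarray(sc_matrix)[np.ix_(others, others)]
                uu, vv = np.where(np.triu(sub, k=1) > 0)
                pairs = np.column_stack([uu, vv])
            fit = fit_column(
                xs[:, i], xs[:, others], d[others, i],
                self.lambda1, self.lambda2, pairs=pairs,
                rho=self.rho, max_iter=self.max_iter,
                abstol=self.abstol, reltol=self.reltol,
            )
            b[others, i] = fit.beta
            objs[i] = fit.objective
            conv[i] = fit.converged
        self.coef_net_ = b
        self.objective_values_ = objs
        self.converged_ = conv
        self.n_features_in_ = m
        return self

    def network_(self) -> CoefficientNetwork:
        return CoefficientNetwork(
            self.coef_net_, self.lambda1, self.lambda2,
            self.objective_values_, self.converged_,
        )


def fit_network(
    record: SubjectRecord,
    pen: PenaltyMatrix | None,
    lambda1: float,
    lambda2: float,
    **solver_opts,
) -> CoefficientNetwork:
    """Functional wrapper over :class:`FusedNetworkRegression` for one subject."""
    est = FusedNetworkRegression(
        lambda1=lambda1, lambda2=lambda2, penalty=pen, **solver_opts
    )
    est.fit(record.bold, sc_matrix=record.sc)
    return est.network_()


def binarize(net, tol: float = 1e-6) -> np.ndarray:
    """Symmetric 0/1 support: edge (i, j) present iff either direction's
    coefficient exceeds ``tol`` in magnitude (OR rule)."""
    if tol <= 0:
        raise ParameterError("tol must be positive")
    b = net.b if isinstance(net, CoefficientNetwork) else np.asarray(net, dtype=float)
    adj = ((np.abs(b) > tol) | (np.abs(b.T) > tol)).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj
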