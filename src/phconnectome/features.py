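"""Analyzable features from barcodes.

beta-0 barcodes become smooth component-count curves: the step function of
bars alive at each threshold is fitted with an order-4 (cubic) B-spline
basis under a second-derivative roughness penalty, and the derivative curve
— which magnifies merge events — is the default object for distance-based
group comparison.

beta-1 barcodes become persistence landscapes: layer k at position x is the
k-th largest tent value min(x - b, d - x) over bars (b, d).  Landscapes are
kept as exact piecewise-linear breakpoint lists; means and Lp distances are
computed exactly (no grid approximation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.interpolate
import scipy.linalg
from scipy.spatial.distance import cityblock, euclidean, seuclidean

from .cohort import ParameterError
from .topology import DEATH_CAP, Barcode

DEFAULT_GRID = np.linspace(0.0, 1.0, 1000)


# ---------------------------------------------------------------------------
# beta-0 curves


def beta0_step_function(barcode: Barcode, grid: np.ndarray | None = None) -> np.ndarray:
    """Number of components alive at each grid threshold.

    A bar counts at eps when birth <= eps < death; bars capped at death 1
    (never merged) count throughout, including at eps = 1.
    """
    if barcode.dim != 0:
        raise ParameterError("beta0_step_function needs a dimension-0 barcode")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    births = barcode.bars[:, 0][:, None]
    deaths = barcode.bars[:, 1][:, None]
    eps = grid[None, :]
    alive = (births <= eps) & ((eps < deaths) | (deaths >= DEATH_CAP))
    return alive.sum(axis=0).astype(float)


@dataclass
class Beta0Curve:
    grid: np.ndarray
    values: np.ndarray
    derivative: np.ndarray
    coefficients: np.ndarray
    smoothing_lambda: float
    basis_order: int = 4


_BASIS_CACHE: dict = {}


def _bspline_system(grid: np.ndarray, n_interior_knots: int):
    """Design matrices (value, first derivative) and the exact
    second-derivative roughness Gram matrix for a cubic B-spline basis."""
    key = (grid.shape[0], float(grid[0]), float(grid[-1]), n_interior_knots)
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    k = 3  # cubic => order 4
    lo, hi = float(grid[0]), float(grid[-1])
    interior = np.linspace(lo, hi, n_interior_knots + 2)[1:-1]
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    n_basis = len(t) - k - 1

    phi = scipy.interpolate.BSpline.design_matrix(grid, t, k).toarray()
    eye = np.eye(n_basis)
    splines = [scipy.interpolate.BSpline(t, eye[j], k) for j in range(n_basis)]
    dphi = np.column_stack([s.derivative(1)(grid) for s in splines])

    # exact Gram of second derivatives: piecewise linear, so 2-point
    # Gauss-Legendre per knot span integrates the products exactly
    spans = np.unique(t)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    xs, ws = [], []
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        xs.extend(0.5 * (a + b) + half * gauss)
        ws.extend([half, half])
    xs = np.asarray(xs)
    ws = np.asarray(ws)
    d2 = np.column_stack([s.derivative(2)(xs) for s in splines])
    rough = (d2 * ws[:, None]).T @ d2
    _BASIS_CACHE[key] = (t, phi, dphi, rough)
    return _BASIS_CACHE[key]


def fda_smooth(
    step_values: np.ndarray,
    grid: np.ndarray | None = None,
    smoothing_lambda: float = 1e-4,
    n_interior_knots: int = 40,
) -> Beta0Curve:
    """Penalized B-spline fit of the beta-0 step function.

    Minimizes SSE + lambda * integral of the squared second derivative.  As
    lambda -> infinity the fit collapses onto the penalty's null space, i.e.
    a straight line; lambda = 0 interpolates within the spline space.
    """
    if smoothing_lambda < 0:
        raise ParameterError("smoothing_lambda must be nonnegative")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    y = np.asarray(step_values, dtype=float)
    if y.shape != grid.shape:
        raise ParameterError("step_values must match the grid")
    _, phi, dphi, rough = _bspline_system(grid, n_interior_knots)
    lhs = phi.T @ phi + smoothing_lambda * rough
    rhs = phi.T @ y
    try:
        coef = scipy.linalg.solve(lhs, rhs, assume_a="pos")
    except scipy.linalg.LinAlgError:
        warnings.warn("ill-conditioned smoothing system; adding ridge", UserWarning)
        coef = scipy.linalg.solve(lhs + 1e-8 * np.eye(lhs.shape[0]), rhs)
    return Beta0Curve(
        grid=grid,
        values=phi @ coef,
        derivative=dphi @ coef,
        coefficients=coef,
        smoothing_lambda=smoothing_lambda,
    )


def curve_distance(
    c1: Beta0Curve,
    c2: Beta0Curve,
    metric: str = "cityblock",
    on: str = "derivative",
    variance: np.ndarray | None = None,
) -> float:
    """Distance between two fitted curves (derivative vectors by default).

    ``seuclidean`` requires ``variance``: the per-grid-point variance taken
    across the cohort being compared.
    """
    if c1.grid.shape != c2.grid.shape or not np.allclose(c1.grid, c2.grid):
        raise ParameterError("curves must share one grid")
    if on not in ("derivative", "values"):
        raise ParameterError("on must be 'derivative' or 'values'")
    a = getattr(c1, on if on == "values" else "derivative")
    b = getattr(c2, on if on == "values" else "derivative")
    if metric == "cityblock":
        return float(cityblock(a, b))
    if metric == "euclidean":
        return float(euclidean(a, b))
    if metric == "seuclidean":
        if variance is None:
            raise ParameterError("seuclidean requires a cohort variance vector")
        v = np.maximum(np.asarray(variance, dtype=float), 1e-12)
        return float(seuclidean(a, b, v))
    raise ParameterError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# persistence landscapes


@dataclass
class Landscape:
    """Layers as exact piecewise-linear breakpoint lists (x, value)."""

    layers: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __call__(self, x, k: int = 0) -> np.ndarray:
        """Evaluate layer k (0-based) at x; zero outside support/for missing
        layers."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if k >= len(self.layers):
            return np.zeros_like(x)
        bx, by = self.layers[k]
        return np.interp(x, bx, by, left=0.0, right=0.0)


def _tent_values(bars: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(n_bars, n_x) tent heights min(x - b, d - x), clipped at 0."""
    b = bars[:, 0][:, None]
    d = bars[:, 1][:, None]
    return np.maximum(np.minimum(x[None, :] - b, d - x[None, :]), 0.0)


def landscape(barcode: Barcode | np.ndarray) -> Landscape:
    """Exact persistence landscape of a dimension-1 barcode.

    Tent functions are linear between critical abscissae (all births, deaths
    and pairwise midpoints (b_i + d_j)/2), and their pointwise ranking is
    constant on each open interval, so sampling the k-th largest at the
    critical points is exact.
    """
    bars = barcode.bars if isinstance(barcode, Barcode) else np.asarray(
        barcode, dtype=float
    ).reshape(-1, 2)
    if isinstance(barcode, Barcode) and barcode.dim != 1:
        raise ParameterError("landscape needs a dimension-1 barcode")
    if len(bars) == 0:
        return Landscape(layers=[])
    births, deaths = bars[:, 0], bars[:, 1]
    crit = np.unique(
        np.concatenate([births, deaths, ((births[:, None] + deaths[None, :]) / 2).ravel()])
    )
    vals = _tent_values(bars, crit)
    ranked = -np.sort(-vals, axis=0)  # descending along bars
    layers = []
    for k in range(len(bars)):
        yk = ranked[k]
        if not np.any(yk > 0):
            break
        layers.append((crit.copy(), yk))
    return Landscape(layers=layers)


def _merged_breakpoints(l1: Landscape, l2: Landscape, k: int) -> np.ndarray:
    xs = []
    for land in (l1, l2):
        if k < land.n_layers:
            xs.append(land.layers[k][0])
    if not xs:
        return np.array([0.0, 1.0])
    return np.unique(np.concatenate(xs))


def mean_landscape(landscapes: list[Landscape]) -> Landscape:
    """Layer-wise pointwise mean; missing layers count as zero."""
    if not landscapes:
        raise ParameterError("need at least one landscape")
    n_layers = max(l.n_layers for l in landscapes)
    layers = []
    for k in range(n_layers):
        xs = np.unique(
            np.concatenate(
                [l.layers[k][0] for l in landscapes if k < l.n_layers]
            )
        )
        ys = np.mean([l(xs, k) for l in landscapes], axis=0)
        layers.append((xs, ys))
    return Landscape(layers=layers)


def _segment_lp(x0, x1, a0, a1, p) -> float:
    """Integral of |h|^p over [x0, x1] for the linear h with h(x0)=a0, h(x1)=a1,
    where a0 and a1 have a common sign (or are zero)."""
    if x1 <= x0:
        return 0.0
    h0, h1 = abs(a0), abs(a1)
    # near-equal endpoints: the closed form cancels catastrophically, and the
    # midpoint rule is exact to O((h1 - h0)^2)
    if abs(h1 - h0) <= 1e-9 * max(h0, h1, 1.0):
        return (x1 - x0) * ((h0 + h1) / 2.0) ** p
    # |h| is linear from h0 to h1 here
    slope = (h1 - h0) / (x1 - x0)
    return (h1 ** (p + 1) - h0 ** (p + 1)) / ((p + 1) * slope)


def landscape_distance(l1: Landscape, l2: Landscape, p: float = 2.0) -> float:
    """Lp distance: (sum_k integral |lambda_k - lambda'_k|^p)^(1/p), exact
    piecewise-linear integration; p = inf gives the sup over layers and x."""
    if not (p >= 1):
        raise ParameterError("p must satisfy 1 <= p <= inf")
    n_layers = max(l1.n_layers, l2.n_layers)
    if n_layers == 0:
        return 0.0
    if np.isinf(p):
        best = 0.0
        for k in range(n_layers):
            xs = _merged_breakpoints(l1, l2, k)
            diff = np.abs(l1(xs, k) - l2(xs, k))
            best = max(best, float(diff.max()))
        return best
    total = 0.0
    for k in range(n_layers):
        xs = _merged_breakpoints(l1, l2, k)
        diff = l1(xs, k) - l2(xs, k)
        for x0, x1, a0, a1 in zip(xs[:-1], xs[1:], diff[:-1], diff[1:]):
            if a0 * a1 < 0:  # split at the zero crossing
                xz = x0 + (x1 - x0) * a0 / (a0 - a1)
                total += _segment_lp(x0, xz, a0, 0.0, p)
                total += _segment_lp(xz, x1, 0.0, a1, p)
            else:
                total += _segment_lp(x0, x1, a0, a1, p)
    return float(total ** (1.0 / p))


def landscape_feature_vector(
    land: Landscape, n_layers: int = 5, n_points: int = 200
) -> np.ndarray:
    """Fixed-length subject feature: the first ``n_layers`` layers sampled on
    a uniform grid over [0, 1], concatenated (used for DWG/DBG panels)."""
    xs = np.linspace(0.0, 1.0, n_points)
    return np.concatenate([land(xs, k) for k in range(n_layers)])
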