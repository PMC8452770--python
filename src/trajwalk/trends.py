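"""Affinity-diffusion imputation and lineage-weighted expression trends.

Imputation multiplies the feature matrix by powers of the row-normalized
KNN affinity matrix, denoising each feature toward its neighbourhood mean.
Trend curves are penalized weighted B-spline fits of a feature against
per-cell pseudotime, with the per-cell lineage probabilities as weights so
that cells likely to belong to the lineage dominate the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .errors import DataError, ParameterError
from .graphs import FeatureMatrix, SingleCellKNNGraph


def impute_features(
    X: FeatureMatrix, g: SingleCellKNNGraph, t_steps: int
) -> FeatureMatrix:
    """Diffuse each feature ``t_steps`` times over the row-normalized affinities.

    ``t_steps = 0`` returns the input unchanged; rows of isolated cells are
    left untouched (with a warning).  Constant features are fixed points of
    the diffusion, and per-component feature ranges can only shrink.
    """
    if t_steps < 0:
        raise ParameterError(f"t_steps must be >= 0, got {t_steps}")
    V = X.dense().astype(float)
    if t_steps == 0:
        return FeatureMatrix(V.copy(), X.cell_ids, X.feature_ids)
    A = g.adjacency
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    isolated = rowsum == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated cell(s): rows left unchanged", stacklevel=2
        )
    inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, rowsum))
    T = sp.diags(inv) @ A
    out = V.copy()
    for _ in range(t_steps):
        nxt = T @ out
        nxt[isolated] = out[isolated]
        out = nxt
    return FeatureMatrix(out, X.cell_ids, X.feature_ids)


@dataclass
class TrendCurve:
    """A smoothed expression trend along pseudotime for one lineage."""

    grid: np.ndarray
    fitted: np.ndarray
    lineage: str = ""
    n_knots: int = 10
    degree: int = 3
    penalty: float = 0.0


def _bspline_basis(t: np.ndarray, knots_inner: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = knots_inner[0], knots_inner[-1]
    full = np.concatenate([[lo] * degree, knots_inner, [hi] * degree])
    nb = len(full) - degree - 1
    B = np.empty((len(t), nb))
    tc = np.clip(t, lo, hi)
    for j in range(nb):
        c = np.zeros(nb)
        c[j] = 1.0
        B[:, j] = BSpline(full, c, degree, extrapolate=False)(tc)
    B = np.nan_to_num(B)
    return B, full


def lineage_trend(
    feature: np.ndarray,
    t_cells: np.ndarray,
    w_cells: np.ndarray,
    lineage: str = "",
    n_grid: int = 100,
    n_knots: int = 10,
    degree: int = 3,
    penalty: float | str = "gcv",
) -> TrendCurve:
    """Weighted penalized B-spline trend of a feature against pseudotime.

    Cubic B-splines with ``n_knots`` uniform interior knots spanning the
    pseudotime range of the positively weighted cells; a second-difference
    penalty on the coefficients is selected by generalized cross-validation
    (``penalty="gcv"``) or fixed to a given value.  The curve is evaluated on
    a uniform grid of ``n_grid`` points over that same range; no
    extrapolation beyond it is performed.  Linear signals are in the penalty
    null space, so straight-line trends are recovered exactly.
    """
    y = np.asarray(feature, dtype=float)
    t = np.asarray(t_cells, dtype=float)
    w = np.asarray(w_cells, dtype=float)
    if not (len(y) == len(t) == len(w)):
        raise DataError("feature, pseudotime and weights must have equal length")
    if np.any(w < 0):
        raise DataError("lineage weights must be nonnegative")
    if not np.any(w > 0):
        raise DataError(f"all-zero lineage weights for lineage {lineage!r}")
    supp = w > 0
    lo, hi = t[supp].min(), t[supp].max()
    if hi <= lo:
        grid = np.full(n_grid, lo)
        avg = float(np.average(y[supp], weights=w[supp]))
        return TrendCurve(grid, np.full(n_grid, avg), lineage, n_knots, degree, 0.0)
    knots = np.linspace(lo, hi, n_knots)
    B, _ = _bspline_basis(t[supp], knots, degree)
    yw, ww = y[supp], w[supp]
    BtWB = B.T @ (B * ww[:, None])
    BtWy = B.T @ (yw * ww)
    nb = B.shape[1]
    D = np.diff(np.eye(nb), n=2, axis=0)
    Pen = D.T @ D
    scale = np.trace(BtWB) / max(np.trace(Pen), 1e-12)

    def solve(lam: float) -> tuple[np.ndarray, float]:
        M = BtWB + lam * Pen + 1e-10 * scale * np.eye(nb)
        coef = np.linalg.solve(M, BtWy)
        # GCV with weighted hat-matrix trace
        Minv = np.linalg.inv(M)
        edf = float(np.trace(Minv @ BtWB))
        resid = yw - B @ coef
        rss = float(np.sum(ww * resid ** 2))
        m = float(np.sum(ww > 0))
        gcv = m * rss / max(m - edf, 1e-9) ** 2
        return coef, gcv

    if penalty == "gcv":
        lams = scale * np.logspace(-6, 2, 17)
        best = min(((solve(l)[1], l) for l in lams))
        lam = best[1]
    else:
        lam = float(penalty)
    coef, _ = solve(lam)
    grid = np.linspace(lo, hi, n_grid)
    Bg, _ = _bspline_basis(grid, knots, degree)
    fitted = Bg @ coef
    return TrendCurve(grid, fitted, lineage, n_knots, degree, float(lam))
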