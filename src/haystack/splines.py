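"""Spline regression with cross-validated flexibility selection.

Two one-dimensional smoothers are provided for calibrating the permutation
null: natural cubic splines (``ns``, the default) and B-splines (``bs``).
For ``ns`` the degrees of freedom (number of basis columns) are searched over
1..10; for ``bs`` the polynomial degree 1..5 and df 1..10 are searched
jointly. Selection minimizes tenfold cross-validated mean squared prediction
error, with ties broken toward the least flexible candidate.

The natural cubic basis uses the truncated-power construction with
boundary knots at the data extremes and interior knots at quantiles: with
knots xi_1 < ... < xi_K (K = df + 1),

    N_1(x) = x,   N_{k+1}(x) = d_k(x) - d_{K-1}(x),
    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k),

which is linear beyond the boundary knots. df = 1 reduces to a straight
line. B-spline design matrices come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .types import HaystackError

NS_DF_RANGE = range(1, 11)
BS_DF_RANGE = range(1, 11)
BS_DEGREE_RANGE = range(1, 6)
N_FOLDS = 10


def _ns_knots(x: np.ndarray, df: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if df == 1:
        return np.array([lo, hi])
    interior = np.quantile(x, np.arange(1, df) / df)
    knots = np.unique(np.concatenate([[lo], interior, [hi]]))
    return knots


def _ns_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    K = len(knots)
    cols = [np.ones_like(x), x]
    if K > 2:
        xiK = knots[-1]
        xiKm1 = knots[-2]

        def d(xi):
            num = np.clip(x - xi, 0, None) ** 3 - np.clip(x - xiK, 0, None) ** 3
            return num / (xiK - xi)

        dlast = d(xiKm1)
        for k in range(K - 2):
            cols.append(d(knots[k]) - dlast)
    return np.column_stack(cols)


def _bs_knot_vector(x: np.ndarray, df: int, degree: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    n_interior = df - degree
    interior = (
        np.quantile(x, np.arange(1, n_interior + 1) / (n_interior + 1))
        if n_interior > 0
        else np.array([])
    )
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


@dataclass
class SplineRegression:
    """Least-squares spline fit y ~ s(x); callable after :meth:`fit`."""

    kind: str = "ns"  # "ns" | "bs"
    df: int = 3
    degree: int = 3  # bs only
    _knots: np.ndarray = field(default=None, repr=False)
    _coef: np.ndarray = field(default=None, repr=False)
    _const: float | None = field(default=None, repr=False)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SplineRegression":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.min() == x.max():
            # zero predictor span: constant model
            self._const = float(y.mean())
            return self
        X = self._design_fit(x)
        self._coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return self

    def _design_fit(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "ns":
            self._knots = _ns_knots(x, self.df)
            return _ns_design(x, self._knots)
        if self.kind == "bs":
            if self.df < self.degree:
                raise HaystackError("bs requires df >= degree")
            self._knots = _bs_knot_vector(x, self.df, self.degree)
            return self._design_predict(x, clip=False)
        raise HaystackError(f"unknown spline kind {self.kind!r}")

    def _design_predict(self, x: np.ndarray, clip: bool = True) -> np.ndarray:
        if self.kind == "ns":
            return _ns_design(x, self._knots)
        t = self._knots
        deg = self.degree
        if clip:
            x = np.clip(x, t[deg], t[-deg - 1])
        B = BSpline.design_matrix(x, t, deg, extrapolate=True).toarray()
        return np.column_stack([np.ones(len(x)), B])

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self._const is not None:
            return np.full(x.shape, self._const)
        if self._coef is None:
            raise HaystackError("spline not fitted")
        return self._design_predict(x) @ self._coef

    __call__ = predict


def _cv_folds(n: int, seed: int, n_folds: int = N_FOLDS) -> list[np.ndarray]:
    idx = np.random.default_rng(seed).permutation(n)
    return [idx[k::n_folds] for k in range(n_folds)]


def _cv_mse(x, y, folds, kind, df, degree) -> float:
    errs = []
    for test in folds:
        if len(test) == 0:
            continue
        train = np.setdiff1d(np.arange(len(x)), test)
        if len(train) <= df + 1:
            return np.inf
        try:
            model = SplineRegression(kind=kind, df=df, degree=degree).fit(
                x[train], y[train]
            )
            pred = model.predict(x[test])
        except (HaystackError, np.linalg.LinAlgError, ValueError):
            return np.inf
        if not np.all(np.isfinite(pred)):
            return np.inf
        errs.append(np.mean((pred - y[test]) ** 2))
    return float(np.mean(errs)) if errs else np.inf


def fit_spline_cv(
    x: np.ndarray, y: np.ndarray, kind: str = "ns", seed: int = 42
) -> SplineRegression:
    """Fit y ~ spline(x) with flexibility chosen by tenfold cross-validation.

    Folds are assigned by a seeded shuffle; the candidate with minimal mean
    squared prediction error wins, ties going to the smaller (degree, df).
    The winner is refitted on all data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise HaystackError("x and y length mismatch")
    if len(x) < N_FOLDS + 2:
        raise HaystackError(
            f"need at least {N_FOLDS + 2} points for {N_FOLDS}-fold selection"
        )
    if x.min() == x.max():
        return SplineRegression(kind=kind, df=1).fit(x, y)
    folds = _cv_folds(len(x), seed)
    if kind == "ns":
        candidates = [(3, df) for df in NS_DF_RANGE]
    elif kind == "bs":
        candidates = [
            (deg, df) for deg in BS_DEGREE_RANGE for df in BS_DF_RANGE if df >= deg
        ]
    else:
        raise HaystackError(f"unknown spline kind {kind!r}")
    best, best_mse = None, np.inf
    for deg, df in candidates:
        mse = _cv_mse(x, y, folds, kind, df, deg)
        if mse < best_mse - 1e-15:
            best, best_mse = (deg, df), mse
    if best is None:
        raise HaystackError("no spline candidate could be fitted")
    deg, df = best
    return SplineRegression(kind=kind, df=df, degree=deg).fit(x, y)
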