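"""Cubic smoothing splines parameterized by equivalent degrees of freedom.

All smoothing in this package follows the R ``smooth.spline`` convention:
the amount of smoothing is specified as the *equivalent degrees of freedom*
(edf), defined as the trace of the linear smoother matrix that maps observed
values to fitted values.  The smoother itself is a penalized cubic B-spline
regression with the exact integrated-squared-second-derivative penalty, whose
minimizer coincides with the classical natural cubic smoothing spline when
knots are placed at the data sites.

With design matrix ``N`` (cubic B-splines at the data sites) and penalty
Gram matrix ``Omega`` (inner products of second derivatives), the fit for
penalty ``lam`` is ``theta = (N'N + lam*Omega)^-1 N' y`` and

    df(lam) = tr[ N (N'N + lam*Omega)^-1 N' ]

which is strictly decreasing in ``lam``; the lambda matching a requested df
is found by scalar root finding on log-lambda.  Sites are rescaled to [0, 1]
internally (df is invariant under that) to keep the linear algebra well
conditioned, and factorizations are cached per (site grid, df) because the
pipeline smooths many response vectors on identical grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.optimize import brentq

__all__ = ["SplineBasis", "SmoothingSpline", "smooth", "get_basis"]

_GAUSS2 = np.array([-1.0, 1.0]) / np.sqrt(3.0)  # 2-pt Gauss, exact for quadratics


def _knot_sites(z_unique: np.ndarray, n_data: int, nknots: int | None) -> np.ndarray:
    """Knot sites: all distinct sites, thinned so the basis stays identifiable."""
    m_max = max(4, n_data - 2)  # basis dim = len(knots) + 2 must not exceed n
    if nknots is None:
        nknots = min(len(z_unique), m_max)
    nknots = max(4, min(nknots, len(z_unique), m_max))
    if nknots == len(z_unique):
        return z_unique
    idx = np.unique(np.round(np.linspace(0, len(z_unique) - 1, nknots)).astype(int))
    return z_unique[idx]


class SplineBasis:
    """Precomputed design/penalty structure for one set of sites.

    Reusable across many response vectors on the same grid.
    """

    def __init__(self, x: np.ndarray, nknots: int | None = None):
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("x must be 1-D")
        xu = np.unique(x)
        if len(xu) < 4:
            raise ValueError("need at least 4 distinct sites")
        self.x0 = float(xu[0])
        self.span = float(xu[-1] - xu[0])
        self.n = len(x)
        z = (x - self.x0) / self.span
        u = _knot_sites((xu - self.x0) / self.span, self.n, nknots)
        # clamped cubic knot vector: basis dimension m = len(u) + 2
        self.t = np.r_[[u[0]] * 4, u[1:-1], [u[-1]] * 4]
        self.m = len(self.t) - 4
        self.N = BSpline.design_matrix(np.clip(z, 0.0, 1.0), self.t, 3).toarray()
        self.Omega = self._penalty_gram(u)
        self.NtN = self.N.T @ self.N
        self._lam_cache: dict[float, tuple[float, object]] = {}

    def _penalty_gram(self, u: np.ndarray) -> np.ndarray:
        # second derivatives of cubic B-splines are piecewise linear -> the
        # integrand is piecewise quadratic, integrated exactly by 2-pt Gauss
        mid = 0.5 * (u[:-1] + u[1:])
        half = 0.5 * (u[1:] - u[:-1])
        pts = (mid[:, None] + half[:, None] * _GAUSS2[None, :]).ravel()
        w = np.repeat(half, 2)
        d2 = BSpline(self.t, np.eye(self.m), 3).derivative(2)
        B2 = d2(pts)  # (npts, m)
        return (B2 * w[:, None]).T @ B2

    def _system(self, lam: float) -> np.ndarray:
        A = self.NtN + lam * self.Omega
        # tiny relative ridge guards rank deficiency at lam ~ 0
        A[np.diag_indices_from(A)] += 1e-12 * np.trace(A) / self.m
        return A

    def edf(self, lam: float) -> float:
        X = solve(self._system(lam), self.NtN, assume_a="pos")
        return float(np.trace(X))

    def lam_for_df(self, df: float) -> float:
        df = min(df, self.m)
        if not df > 2.0:
            raise ValueError(f"df must exceed 2, got {df}")
        if self.edf(1e-14) <= df:
            return 0.0
        f = lambda loglam: self.edf(np.exp(loglam)) - df
        lo, hi = -30.0, 10.0
        while f(hi) > 0 and hi < 60:
            hi += 10
        while f(lo) < 0 and lo > -60:
            lo -= 10
        return float(np.exp(brentq(f, lo, hi, xtol=1e-9)))

    def _factor_for_df(self, df: float):
        key = round(float(df), 9)
        hit = self._lam_cache.get(key)
        if hit is None:
            lam = self.lam_for_df(df)
            factor = cho_factor(self._system(lam))
            hit = (lam, factor, self.edf(lam))
            if len(self._lam_cache) > 32:
                self._lam_cache.clear()
            self._lam_cache[key] = hit
        return hit

    def fit(self, y: np.ndarray, df: float | None = None,
            lam: float | None = None) -> "SmoothingSpline":
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("y length must match sites")
        if lam is None:
            if df is None:
                raise ValueError("specify df or lam")
            lam, factor, edf = self._factor_for_df(df)
        else:
            factor = cho_factor(self._system(lam))
            edf = self.edf(lam)
        theta = cho_solve(factor, self.N.T @ y)
        fitted = self.N @ theta
        rss = float(np.sum((y - fitted) ** 2))
        return SmoothingSpline(
            spline=BSpline(self.t.copy(), theta, 3),
            x0=self.x0, span=self.span,
            fitted=fitted, rss=rss, edf=edf, lam=lam, n=self.n,
        )


@dataclass
class SmoothingSpline:
    """A fitted df-parameterized cubic smoothing spline."""

    spline: BSpline          # on the internal [0, 1] abscissa
    x0: float
    span: float
    fitted: np.ndarray
    rss: float
    edf: float
    lam: float
    n: int
    _deriv: BSpline | None = field(default=None, repr=False)

    def _z(self, x: np.ndarray) -> np.ndarray:
        return np.clip((np.asarray(x, float) - self.x0) / self.span, 0.0, 1.0)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.spline(self._z(x))

    def derivative(self, x: np.ndarray, nu: int = 1) -> np.ndarray:
        if nu == 1:
            if self._deriv is None:
                self._deriv = self.spline.derivative(1)
            return self._deriv(self._z(x)) / self.span
        return self.spline.derivative(nu)(self._z(x)) / self.span ** nu

    @property
    def see(self) -> float:
        """Standard error of the estimate: sqrt(RSS / (n - edf))."""
        dof = self.n - self.edf
        if dof <= 0:
            return float("nan")
        return float(np.sqrt(self.rss / dof))


_basis_cache: dict[tuple, SplineBasis] = {}


def get_basis(x: np.ndarray, nknots: int | None = None) -> SplineBasis:
    """Cached :class:`SplineBasis` for a site vector (grids recur constantly)."""
    key = (np.round(np.asarray(x, float), 12).tobytes(), nknots)
    basis = _basis_cache.get(key)
    if basis is None:
        if len(_basis_cache) > 64:
            _basis_cache.clear()
        basis = SplineBasis(np.asarray(x, float), nknots)
        _basis_cache[key] = basis
    return basis


def smooth(x: np.ndarray, y: np.ndarray, df: float,
           nknots: int | None = None) -> SmoothingSpline:
    """Fit a cubic smoothing spline to (x, y) at the given equivalent df."""
    return get_basis(x, nknots).fit(y, df=df)
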