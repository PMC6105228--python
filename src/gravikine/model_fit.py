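"""Per-timepoint regression of the GP and sine-law bending models.

At each observation time the response field (dC/dt, or LRL) is regressed on
arc length via

    GP model:    response = -beta * sin A(s)  -  gamma * C(s)
    sine law:    response = -beta * sin A(s)

by ordinary least squares (no intercept by default, matching the model
form).  Models are compared by AIC computed from the Gaussian likelihood
with the variance profiled out,

    AIC = n * log(2*pi*RSS/n) + n + 2*(k + 1)

where k counts regression coefficients (the +1 is the variance); only AIC
differences matter and both models share the convention.  The adjusted R^2
for intercept-free fits uses the *uncentered* total sum of squares (values
are not comparable with centered R^2).

``scan_sine_segments`` finds the contiguous stretches of the organ over
which LRL follows the sine law: every window on the sampling grid at least
``min_len`` mm long is fit with LRL = -beta*sinA and windows exceeding the
R^2 threshold are merged into maximal segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .tsmap import TSMap

__all__ = [
    "FitResult", "SineSegment", "fit_gp", "fit_sine", "compare_models",
    "scan_sine_segments", "beta_map", "fit_series",
]

DEG = np.pi / 180.0


@dataclass
class FitResult:
    model: str                 # "GP" or "sine"
    response: str              # "dCdt" or "LRL"
    t: float
    beta: float
    gamma: float | None
    beta_se: float
    gamma_se: float | None
    beta_p: float
    gamma_p: float | None
    aic: float
    adj_r2: float
    n: int
    s_min: float
    collinear: bool = False

    @property
    def beta_significant(self) -> bool:
        return self.beta_p <= 0.05

    @property
    def gamma_significant(self) -> bool:
        return self.gamma_p is not None and self.gamma_p <= 0.05


@dataclass
class SineSegment:
    t: float
    s_start: float
    s_end: float
    beta: float
    r2: float

    @property
    def length(self) -> float:
        return self.s_end - self.s_start


def _aic(n: int, rss: float, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(2 * np.pi * rss / n) + n + 2 * (k + 1)


def _ols_fit(y: np.ndarray, X: np.ndarray, names: list[str],
             include_intercept: bool) -> tuple:
    if include_intercept:
        X = sm.add_constant(X, prepend=False)
    res = sm.OLS(y, X).fit()
    collinear = np.linalg.cond(X) > 1e8
    rss = float(res.ssr)
    k = X.shape[1]
    return res, _aic(len(y), rss, k), float(res.rsquared_adj), collinear


def _prepare(response, A_deg, C, s, s_min):
    y = np.asarray(response, float)
    A = np.asarray(A_deg, float) * DEG
    s = np.asarray(s, float)
    ok = np.isfinite(y) & np.isfinite(A) & (s > s_min)
    if C is not None:
        C = np.asarray(C, float)
        ok &= np.isfinite(C)
        return y[ok], A[ok], C[ok], int(ok.sum())
    return y[ok], A[ok], None, int(ok.sum())


def fit_gp(response: np.ndarray, A_deg: np.ndarray, C: np.ndarray,
           s: np.ndarray, s_min: float = 0.0, t: float = 0.0,
           response_tag: str = "dCdt", include_intercept: bool = False) -> FitResult:
    """Least-squares fit of response = -beta*sinA - gamma*C over s > s_min."""
    y, A, Cv, n = _prepare(response, A_deg, C, s, s_min)
    if n < 4:
        raise ValueError(f"need >= 4 valid samples beyond s_min (got {n})")
    X = np.column_stack([-np.sin(A), -Cv])
    res, aic, adj_r2, coll = _ols_fit(y, X, ["beta", "gamma"], include_intercept)
    return FitResult(model="GP", response=response_tag, t=t,
                     beta=float(res.params[0]), gamma=float(res.params[1]),
                     beta_se=float(res.bse[0]), gamma_se=float(res.bse[1]),
                     beta_p=float(res.pvalues[0]), gamma_p=float(res.pvalues[1]),
                     aic=aic, adj_r2=adj_r2, n=n, s_min=s_min, collinear=coll)


def fit_sine(response: np.ndarray, A_deg: np.ndarray, s: np.ndarray,
             s_min: float = 0.0, t: float = 0.0, response_tag: str = "dCdt",
             include_intercept: bool = False) -> FitResult:
    """As :func:`fit_gp` with the curvature regressor removed (gamma = 0)."""
    y, A, _, n = _prepare(response, A_deg, None, s, s_min)
    if n < 3:
        raise ValueError(f"need >= 3 valid samples beyond s_min (got {n})")
    X = (-np.sin(A))[:, None]
    res, aic, adj_r2, coll = _ols_fit(y, X, ["beta"], include_intercept)
    return FitResult(model="sine", response=response_tag, t=t,
                     beta=float(res.params[0]), gamma=None,
                     beta_se=float(res.bse[0]), gamma_se=None,
                     beta_p=float(res.pvalues[0]), gamma_p=None,
                     aic=aic, adj_r2=adj_r2, n=n, s_min=s_min, collinear=coll)


def compare_models(gp: FitResult, sine: FitResult) -> dict:
    """Select the model with lower AIC; also reports the adjusted-R^2 ordering."""
    if gp.response != sine.response or gp.t != sine.t or gp.n != sine.n:
        raise ValueError("fits must share response, timepoint and samples")
    selected = "GP" if gp.aic < sine.aic else "sine"
    return {
        "selected": selected,
        "delta_aic": gp.aic - sine.aic,
        "higher_adj_r2": "GP" if gp.adj_r2 > sine.adj_r2 else "sine",
    }


def fit_series(field: TSMap, A_field: TSMap, C_field: TSMap,
               s_min: float = 0.0, response_tag: str = "dCdt",
               include_intercept: bool = False,
               min_n: int = 8) -> list[dict]:
    """Fit both models at every timepoint of a t-s response field."""
    out = []
    for i, t in enumerate(field.t):
        y = field.values[i]
        ok = field.mask[i] & A_field.mask[i] & C_field.mask[i] & (field.s > s_min)
        if ok.sum() < min_n:
            continue
        try:
            gp = fit_gp(y[ok], A_field.values[i][ok], C_field.values[i][ok],
                        field.s[ok], s_min=0.0, t=float(t),
                        response_tag=response_tag, include_intercept=include_intercept)
            sine = fit_sine(y[ok], A_field.values[i][ok], field.s[ok],
                            s_min=0.0, t=float(t), response_tag=response_tag,
                            include_intercept=include_intercept)
        except ValueError:
            continue
        out.append({"t": float(t), "gp": gp, "sine": sine,
                    **compare_models(gp, sine)})
    return out


def _window_stats(x: np.ndarray, y: np.ndarray):
    """Prefix sums for O(1) centered single-regressor window fits."""
    z = np.zeros(1)
    return (np.concatenate([z, np.cumsum(x)]),
            np.concatenate([z, np.cumsum(y)]),
            np.concatenate([z, np.cumsum(x * x)]),
            np.concatenate([z, np.cumsum(y * y)]),
            np.concatenate([z, np.cumsum(x * y)]))


def _window_fit(stats, i: int, j: int):
    """Slope and centered r^2 of y ~ a + b*x on the index window [i, j)."""
    cx, cy, cxx, cyy, cxy = stats
    m = j - i
    sx, sy = cx[j] - cx[i], cy[j] - cy[i]
    sxx = cxx[j] - cxx[i] - sx * sx / m
    syy = cyy[j] - cyy[i] - sy * sy / m
    sxy = cxy[j] - cxy[i] - sx * sy / m
    if sxx <= 0 or syy <= 0:
        return np.nan, 0.0
    return sxy / sxx, sxy * sxy / (sxx * syy)


def scan_sine_segments(s: np.ndarray, lrl: np.ndarray, A_deg: np.ndarray,
                       min_len: float = 0.76, r2_min: float = 0.95,
                       t: float = 0.0) -> list[SineSegment]:
    """Maximal organ segments over which LRL follows -beta*sinA with R^2 > r2_min.

    All contiguous windows on the sampling grid spanning at least ``min_len``
    mm are tested with a linear regression of LRL on -sin A (slope beta,
    centered R^2 — an intercept-free uncentered R^2 would also accept
    stretches of constant LRL, which the scan must reject); retained windows
    are merged into maximal non-extendable segments and each merged segment
    is refit to report its beta.
    """
    s = np.asarray(s, float)
    ok = np.isfinite(lrl) & np.isfinite(A_deg)
    segments: list[SineSegment] = []
    # operate on each contiguous valid run independently
    edges = np.nonzero(np.diff(np.concatenate([[0], ok.astype(int), [0]])))[0]
    for a, b in zip(edges[::2], edges[1::2]):
        ss, yy = s[a:b], np.asarray(lrl[a:b], float)
        x = -np.sin(np.asarray(A_deg[a:b], float) * DEG)
        n = len(ss)
        if n < 3:
            continue
        stats = _window_stats(x, yy)
        covered = np.zeros(n, dtype=bool)
        for i in range(n):
            for j in range(n, i, -1):
                if ss[j - 1] - ss[i] < min_len:
                    break
                _, r2 = _window_fit(stats, i, j)
                if r2 > r2_min:
                    covered[i:j] = True
                    break  # any shorter passing window from i is contained here
        runs = np.nonzero(np.diff(np.concatenate([[0], covered.astype(int), [0]])))[0]
        for ra, rb in zip(runs[::2], runs[1::2]):
            if ss[rb - 1] - ss[ra] < min_len:
                continue
            beta, r2 = _window_fit(stats, ra, rb)
            segments.append(SineSegment(t=t, s_start=float(ss[ra]),
                                        s_end=float(ss[rb - 1]),
                                        beta=float(beta), r2=float(r2)))
    return segments


def beta_map(segments_by_frame: dict[float, list[SineSegment]],
             s: np.ndarray) -> TSMap:
    """t-s map valued by segment beta over segment cells, masked elsewhere."""
    times = np.array(sorted(segments_by_frame))
    vals = np.full((len(times), len(s)), np.nan)
    for i, t in enumerate(times):
        for seg in segments_by_frame[t]:
            sel = (s >= seg.s_start - 1e-9) & (s <= seg.s_end + 1e-9)
            vals[i, sel] = seg.beta
    return TSMap(t=times, s=s, values=vals, mask=np.isfinite(vals),
                 name="beta (sine-law segments)", units="per log10 unit")
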