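"""Deflection-angle / curvature / curvature-rate fields and trough analysis.

For each frame the local deflection angle A(s) is the signed angle between
the midline tangent and the upward vertical (degrees; positive toward the
initial turning side; unwrapped along s).  Curvature C = dA/ds is obtained as
the first derivative of a cubic smoothing spline of A against s with
equivalent df equal to half the sample count, which is also the convention
used for the temporal smoothing: at each fixed s the observed C(t) series is
smoothed at df = n/2, the smoothed values are the "predicted C", their
derivative is dC/dt, and SEE = sqrt(RSS / (n - df)) quantifies the smoothing
residual at that s.

Troughs (valleys) and heights (positive regions) of a t-s field are traced
by linking per-row temporal extrema across adjacent arc-length rows, and each
traced path is assigned the deflection-angle contour it follows, rounded to
a configurable resolution (5 degrees by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema

from .midline import MidlineCurve
from .splines import get_basis
from .tsmap import TSMap

__all__ = [
    "deflection_angle", "curvature", "curvature_rate", "see_ratio_map",
    "build_fields", "TroughPath", "detect_extremal_paths", "align_with_angle",
]

DEG = np.pi / 180.0


def deflection_angle(midline: MidlineCurve, turning_sign: float = 1.0) -> np.ndarray:
    """Signed deflection angle from vertical along the midline, degrees.

    Tangents come from centred differences of the resampled points; the sign
    is positive toward the turning side (+x by default) and the series is
    unwrapped so it stays continuous along s.
    """
    pts = midline.points
    if len(pts) < 3:
        raise ValueError("need at least 3 midline points")
    d = midline.tangents
    if d is None:
        d = np.gradient(pts, midline.s, axis=0, edge_order=2)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate (zero-length) tangent on midline")
    a = np.arctan2(turning_sign * d[:, 0], d[:, 1])
    return np.unwrap(a) / DEG


def curvature(s: np.ndarray, A_deg: np.ndarray, df: float | None = None):
    """Smooth A(s) and differentiate: returns (C mm^-1, smoothed A deg).

    df defaults to half the sample count (the package-wide smoothing rule).
    Angles are converted to radians internally so C carries units of mm^-1.
    """
    s = np.asarray(s, float)
    A = np.asarray(A_deg, float)
    n = len(s)
    if n < 8:
        return np.full(n, np.nan), np.full(n, np.nan)
    if df is None:
        df = n / 2.0
    fit = get_basis(s).fit(A * DEG, df=df)
    C = fit.derivative(s)
    return C, fit(s) / DEG


def curvature_rate(t: np.ndarray, C_obs: np.ndarray, mask: np.ndarray | None = None,
                   df_frac: float = 0.5):
    """Temporal smoothing of C(s, t) per fixed s.

    C_obs has shape (nt, ns).  Returns (C_pred, dCdt, SEE) where C_pred and
    dCdt are (nt, ns) arrays and SEE is (ns,).  Rows of s with fewer than 8
    valid timepoints are masked (NaN).
    """
    t = np.asarray(t, float)
    C_obs = np.asarray(C_obs, float)
    if mask is None:
        mask = np.isfinite(C_obs)
    nt, ns = C_obs.shape
    C_pred = np.full_like(C_obs, np.nan)
    dCdt = np.full_like(C_obs, np.nan)
    see = np.full(ns, np.nan)
    for j in range(ns):
        ok = mask[:, j] & np.isfinite(C_obs[:, j])
        n = int(ok.sum())
        if n < 8:
            continue
        fit = get_basis(t[ok]).fit(C_obs[ok, j], df=n * df_frac)
        C_pred[ok, j] = fit(t[ok])
        dCdt[ok, j] = fit.derivative(t[ok])
        see[j] = fit.see
    return C_pred, dCdt, see


def see_ratio_map(t: np.ndarray, s: np.ndarray, see: np.ndarray,
                  C_obs: np.ndarray, mask: np.ndarray | None = None) -> TSMap:
    """log10(SEE(s) / |observed C(s, t)|), masked where C = 0 or SEE missing."""
    C_obs = np.asarray(C_obs, float)
    if mask is None:
        mask = np.isfinite(C_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log10(see[None, :] / np.abs(C_obs))
    ok = mask & np.isfinite(vals)
    return TSMap(t=t, s=s, values=np.where(ok, vals, np.nan), mask=ok,
                 name="log10(SEE/|C|)")


def build_fields(midlines: list[MidlineCurve], turning_sign: float = 1.0,
                 step: float | None = None,
                 tip_margin: float = 0.3) -> dict[str, TSMap]:
    """Assemble A, C, predicted C, dC/dt and SEE-ratio maps from a midline series.

    The common s grid spans the longest frame; rows beyond a frame's length
    are masked, so validity is monotone in s within each frame.  The last
    ``tip_margin`` mm of every frame are masked too: the principal-curve fit
    has little leverage at its free tip end, so tangent estimates there are
    unreliable (the clamped base is kept — masking it would break the
    monotone-validity contract — and fits exclude it via ``s_min``).
    """
    times = np.array([m.frame_time for m in midlines])
    step = step or float(np.median(np.diff(midlines[0].s)))
    ns = max(len(m.s) for m in midlines)
    s = np.arange(ns) * step
    nt = len(midlines)
    n_trim = int(round(tip_margin / step))

    A = np.full((nt, ns), np.nan)
    C = np.full((nt, ns), np.nan)
    for i, m in enumerate(midlines):
        n = len(m.s)
        a = deflection_angle(m, turning_sign)
        c, a_s = curvature(m.s, a)
        if n_trim > 0:
            a_s[n - n_trim:] = np.nan
            c[n - n_trim:] = np.nan
        A[i, :n] = a_s
        C[i, :n] = c
    mask = np.isfinite(C)
    C_pred, dCdt, see = curvature_rate(times, C, mask)
    return {
        "A": TSMap(t=times, s=s, values=A, mask=np.isfinite(A), name="A", units="deg"),
        "C": TSMap(t=times, s=s, values=C, mask=mask, name="C", units="mm^-1"),
        "C_pred": TSMap(t=times, s=s, values=C_pred, mask=np.isfinite(C_pred),
                        name="predicted C", units="mm^-1"),
        "dCdt": TSMap(t=times, s=s, values=dCdt, mask=np.isfinite(dCdt),
                      name="dC/dt", units="mm^-1 h^-1"),
        "see_ratio": see_ratio_map(times, s, see, C, mask),
    }


# ---------------------------------------------------------------------------
# trough / height detection and angle alignment

@dataclass
class TroughPath:
    """An extremal path of a t-s field: ordered (t, s) vertices with values."""

    t: np.ndarray
    s: np.ndarray
    values: np.ndarray
    polarity: str                  # "trough" or "height"
    aligned_angle: float | None = None   # degrees, multiple of the resolution
    alignment_residual: float | None = None

    @property
    def extent(self) -> float:
        return float(self.s[-1] - self.s[0])


def detect_extremal_paths(field: TSMap, polarity: str = "trough",
                          min_extent: float = 0.5, depth_frac: float = 0.3,
                          max_gap_rows: int = 2) -> list[TroughPath]:
    """Trace troughs (or heights) of a t-s field across arc-length rows.

    Per s row, local minima over t deeper than depth_frac of the global
    minimum are found (maxima for heights); extrema in adjacent rows are
    linked by nearest-t continuity with gaps of up to ``max_gap_rows`` rows,
    ties going to the deeper extremum.  Paths spanning less than
    ``min_extent`` mm of s are dropped.
    """
    if polarity not in ("trough", "height"):
        raise ValueError("polarity must be 'trough' or 'height'")
    v = field.values if polarity == "trough" else -field.values
    finite = np.isfinite(v)
    if not finite.any():
        return []
    global_min = np.nanmin(v)
    if global_min >= 0:
        return []
    threshold = depth_frac * global_min  # negative

    dt_med = float(np.median(np.diff(field.t)))
    # candidate extrema per s row (column j): local minima of v[:, j] over t
    candidates: dict[int, list[tuple[float, float]]] = {}
    for j in range(len(field.s)):
        col = v[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 3:
            continue
        idx = np.nonzero(ok)[0]
        sub = col[idx]
        loc = argrelextrema(sub, np.less_equal, order=1)[0]
        loc = [i for i in loc if sub[i] <= threshold]
        if loc:
            candidates[j] = [(field.t[idx[i]], sub[i]) for i in loc]

    paths: list[dict] = []
    active: list[dict] = []
    for j in range(len(field.s)):
        # retire paths whose gap to this row already exceeds the allowance
        still = []
        for p in active:
            (paths if j - p["last_row"] > max_gap_rows else still).append(p)
        active = still
        cands = candidates.get(j, [])
        used = [False] * len(cands)
        for p in active:
            best, best_cost = None, None
            for i, (tc, vc) in enumerate(cands):
                if used[i]:
                    continue
                cost = abs(tc - p["last_t"])
                if cost > (max_gap_rows + 1) * dt_med:
                    continue
                if best is None or cost < best_cost - 1e-12 or (
                        abs(cost - best_cost) <= 1e-12 and vc < cands[best][1]):
                    best, best_cost = i, cost
            if best is not None:
                tc, vc = cands[best]
                used[best] = True
                p["t"].append(tc)
                p["s"].append(field.s[j])
                p["v"].append(vc)
                p["last_t"], p["last_row"] = tc, j
        for i, (tc, vc) in enumerate(cands):
            if not used[i]:
                active.append({"t": [tc], "s": [field.s[j]], "v": [vc],
                               "last_t": tc, "last_row": j})
    paths.extend(active)

    out = []
    sign = 1.0 if polarity == "trough" else -1.0
    for p in paths:
        s_arr = np.asarray(p["s"])
        if s_arr[-1] - s_arr[0] < min_extent:
            continue
        out.append(TroughPath(t=np.asarray(p["t"]), s=s_arr,
                              values=sign * np.asarray(p["v"]), polarity=polarity))
    out.sort(key=lambda q: q.t[0])
    return out


def align_with_angle(path: TroughPath, A_field: TSMap,
                     resolution: float = 5.0) -> TroughPath:
    """Assign the deflection-angle contour a path follows.

    A is read bilinearly at each path vertex; the aligned angle is the median
    rounded to the nearest multiple of ``resolution`` and the residual is the
    RMS deviation of the vertex angles from it.  Returns the path with
    ``aligned_angle`` and ``alignment_residual`` filled in.
    """
    a = A_field.sample(path.t, path.s)
    a = a[np.isfinite(a)]
    if len(a) == 0:
        raise ValueError("path vertices fall outside the angle-field mask")
    aligned = resolution * np.round(np.median(a) / resolution)
    residual = float(np.sqrt(np.mean((a - aligned) ** 2)))
    path.aligned_angle = float(aligned)
    path.alignment_residual = residual
    return path
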