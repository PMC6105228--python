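"""Midline recovery from bright-field frames.

The organ's median is reconstructed per frame in four steps: binarize the
silhouette, split its outline into the two flank contours at the points of
maximal geodesic separation inside the mask, form the cloud of midpoints
between the flanks, and fit a principal curve (Hastie-Stuetzle) through the
cloud at a prescribed equivalent df.  The fitted curve is finally resampled
at a fixed arc-length step (19.9 um by default) from the base, carrying the
local organ width along.

Coordinates: rasters are indexed (row, col); physical image coordinates are
x = col * scale, y = (H - 1 - row) * scale in mm, so +y points up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from skimage import filters, measure

from .splines import smooth

__all__ = [
    "ContourPair", "MidpointCloud", "PrincipalCurve", "MidlineCurve",
    "binarize", "extract_contours", "midpoints", "fit_principal_curve",
    "resample_median", "extract_midline",
]


class MidlineError(RuntimeError):
    pass


def project_onto_polyline(poly: np.ndarray, pts: np.ndarray):
    """Project points onto a polyline: (arc-length ordinates, squared distances).

    Vectorized nearest-vertex lookup followed by exact projection onto the
    two segments adjacent to that vertex; equivalent to (but much faster
    than) per-point geometric projection for densely sampled polylines.
    """
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    tree = cKDTree(poly)
    _, j = tree.query(pts)
    lam = np.empty(len(pts))
    d2 = np.empty(len(pts))
    cand = np.stack([np.clip(j - 1, 0, len(seg) - 1),
                     np.clip(j, 0, len(seg) - 1)], axis=1)  # (n, 2) segment ids
    a = poly[cand]                       # (n, 2, 2)
    v = seg[cand]                        # (n, 2, 2)
    vv = np.maximum(np.einsum("nkj,nkj->nk", v, v), 1e-30)
    tpar = np.clip(np.einsum("nkj,nkj->nk", pts[:, None, :] - a, v) / vv, 0.0, 1.0)
    proj = a + tpar[..., None] * v
    dd = np.sum((pts[:, None, :] - proj) ** 2, axis=2)
    pick = np.argmin(dd, axis=1)
    rows = np.arange(len(pts))
    d2 = dd[rows, pick]
    seg_id = cand[rows, pick]
    lam = cum[seg_id] + tpar[rows, pick] * seg_len[seg_id]
    return lam, d2, proj[rows, pick]


@dataclass
class ContourPair:
    """The two flank polylines of the organ outline, each ordered base->tip."""

    side1: np.ndarray  # (n1, 2) mm
    side2: np.ndarray  # (n2, 2) mm
    base_end: np.ndarray  # (2,) mm
    tip_end: np.ndarray


@dataclass
class MidpointCloud:
    points: np.ndarray        # (n, 2) mm
    local_width: np.ndarray   # (n,) mm flank separation


@dataclass
class PrincipalCurve:
    """Arc-length parameterized smooth curve through a point cloud.

    ``tangents`` are unit tangents evaluated analytically from the
    coordinate smoothing splines; differentiating the resampled points
    instead would re-introduce chord-scale noise that the spline removed.
    """

    s: np.ndarray             # dense arc-length grid (mm), strictly increasing
    points: np.ndarray        # (n, 2) positions at s
    df: float
    mean_sq_dist: float       # mean squared orthogonal distance of the cloud
    converged: bool = True
    tangents: np.ndarray | None = None  # (n, 2) unit tangents at s

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def __call__(self, s: np.ndarray) -> np.ndarray:
        x = np.interp(s, self.s, self.points[:, 0])
        y = np.interp(s, self.s, self.points[:, 1])
        return np.column_stack([x, y])

    def tangent(self, s: np.ndarray) -> np.ndarray:
        if self.tangents is None:
            d = np.gradient(self.points, self.s, axis=0)
        else:
            d = np.column_stack([np.interp(s, self.s, self.tangents[:, 0]),
                                 np.interp(s, self.s, self.tangents[:, 1])])
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def reversed(self) -> "PrincipalCurve":
        return PrincipalCurve(s=self.s[-1] - self.s[::-1],
                              points=self.points[::-1].copy(),
                              df=self.df, mean_sq_dist=self.mean_sq_dist,
                              converged=self.converged,
                              tangents=None if self.tangents is None
                              else -self.tangents[::-1].copy())


@dataclass
class MidlineCurve:
    """The median resampled every ``step`` mm from the base (s = 0)."""

    s: np.ndarray
    points: np.ndarray
    width: np.ndarray
    frame_time: float = 0.0
    tangents: np.ndarray | None = None  # (n, 2) unit tangents, base->tip

    @property
    def length(self) -> float:
        return float(self.s[-1])


def binarize(frame: np.ndarray, threshold_method: str = "otsu") -> np.ndarray:
    """Threshold a bright frame; keep the largest component, fill holes."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise MidlineError("expected a single-channel raster")
    if threshold_method == "otsu":
        thr = filters.threshold_otsu(frame)
    elif threshold_method == "mean":
        thr = frame.mean()
    else:
        raise MidlineError(f"unknown threshold method {threshold_method!r}")
    mask = frame > thr
    if not mask.any() or np.ptp(frame) == 0:
        raise MidlineError("no foreground found in frame")
    lab, n = ndimage.label(mask)
    if n == 0:
        raise MidlineError("no foreground found in frame")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    borders = (mask[0].any() + mask[-1].any() + mask[:, 0].any() + mask[:, -1].any())
    if borders >= 3:
        raise MidlineError("foreground touches 3 or more raster borders")
    return mask


def _geodesic_endpoints(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Approximate the geodesic diameter endpoints of the mask (two sweeps)."""
    rows, cols = np.nonzero(mask)
    n = len(rows)
    index = -np.ones(mask.shape, dtype=np.int64)
    index[rows, cols] = np.arange(n)
    src, dst, wgt = [], [], []
    for dr, dc, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < mask.shape[0]) & (c2 >= 0) & (c2 < mask.shape[1])
        ok[ok] &= mask[r2[ok], c2[ok]]
        src.append(np.arange(n)[ok])
        dst.append(index[r2[ok], c2[ok]])
        wgt.append(np.full(ok.sum(), w))
    g = coo_matrix((np.concatenate(wgt), (np.concatenate(src), np.concatenate(dst))),
                   shape=(n, n))
    g = g + g.T

    def farthest(i0: int) -> int:
        d = dijkstra(g, directed=False, indices=i0)
        d[~np.isfinite(d)] = -1
        return int(np.argmax(d))

    a = farthest(0)
    b = farthest(a)
    return (np.array([rows[a], cols[a]]), np.array([rows[b], cols[b]]))


def _to_xy(rc: np.ndarray, shape: tuple[int, int], scale_mm: float) -> np.ndarray:
    """(row, col) raster coordinates -> physical (x, y) mm, +y up."""
    rc = np.atleast_2d(rc)
    return np.column_stack([rc[:, 1] * scale_mm, (shape[0] - 1 - rc[:, 0]) * scale_mm])


def extract_contours(mask: np.ndarray, scale_mm: float,
                     anchor: np.ndarray | None = None,
                     image: np.ndarray | None = None,
                     level: float | None = None) -> ContourPair:
    """Split the organ outline into the two flank polylines.

    The outline is cut at the contour vertices nearest the two ends of the
    mask's geodesic diameter (robust for bent, partially hooked organs).
    The base is the end nearest ``anchor`` (mm); with no anchor, the end
    nearest the raster border is used.

    When the grayscale ``image`` is supplied, the outline is traced as the
    iso-intensity contour at ``level`` (the binarization threshold) restricted
    to the masked component, which recovers sub-pixel edge positions from the
    gradual intensity falloff at the organ boundary; otherwise the binary
    mask outline is used.
    """
    props = measure.regionprops(mask.astype(np.uint8))[0]
    minor = max(props.axis_minor_length, 1.0)
    if props.axis_major_length / minor < 3.0:
        raise MidlineError("mask is not rod-like (aspect ratio < 3)")
    if image is not None:
        if level is None:
            level = filters.threshold_otsu(np.asarray(image))
        keep = ndimage.binary_dilation(mask, iterations=2)
        img = np.where(keep, np.asarray(image, float), level - 1.0)
        contours = measure.find_contours(img, level)
    else:
        contours = measure.find_contours(mask.astype(float), 0.5)
    outline = max(contours, key=len)
    if np.allclose(outline[0], outline[-1]):
        outline = outline[:-1]

    end_a, end_b = _geodesic_endpoints(mask)
    ia = int(np.argmin(np.sum((outline - end_a) ** 2, axis=1)))
    ib = int(np.argmin(np.sum((outline - end_b) ** 2, axis=1)))
    if ia > ib:
        ia, ib = ib, ia
        end_a, end_b = end_b, end_a
    side1 = outline[ia:ib + 1]
    side2 = np.concatenate([outline[ib:], outline[:ia + 1]])[::-1]  # also a->b

    xy_a = _to_xy(end_a, mask.shape, scale_mm)[0]
    xy_b = _to_xy(end_b, mask.shape, scale_mm)[0]
    if anchor is not None:
        da, db = np.linalg.norm(xy_a - anchor), np.linalg.norm(xy_b - anchor)
    else:
        h, w = mask.shape
        border = lambda rc: min(rc[0], h - 1 - rc[0], rc[1], w - 1 - rc[1])
        da, db = border(end_a), border(end_b)
    s1 = _to_xy(side1, mask.shape, scale_mm)
    s2 = _to_xy(side2, mask.shape, scale_mm)
    if da <= db:
        base, tip = xy_a, xy_b
    else:
        base, tip = xy_b, xy_a
        s1, s2 = s1[::-1], s2[::-1]
    return ContourPair(side1=s1, side2=s2, base_end=base, tip_end=tip)


def midpoints(pair: ContourPair, merge_tol: float | None = None,
              min_width_frac: float = 0.85) -> MidpointCloud:
    """Midpoints between the flanks by nearest-point correspondence.

    Midpoints whose flank separation falls below ``min_width_frac`` of the
    median are dropped: they arise from pairings across the rounded end caps
    of the silhouette, sit beyond the organ's true midline ends, and would
    otherwise flex the principal-curve fit near its boundaries.
    """
    if LineString(pair.side1).crosses(LineString(pair.side2)):
        raise MidlineError("contour sides cross")

    def one_pass(src: np.ndarray, target: np.ndarray):
        _, d2, proj = project_onto_polyline(target, src)
        w = np.sqrt(d2)
        keep = w > 0
        return 0.5 * (src[keep] + proj[keep]), w[keep]

    p1, w1 = one_pass(pair.side1, pair.side2)
    p2, w2 = one_pass(pair.side2, pair.side1)
    pts = np.vstack([p1, p2])
    widths = np.concatenate([w1, w2])
    if min_width_frac > 0:
        good = widths >= min_width_frac * np.median(widths)
        if good.sum() >= 10:
            pts, widths = pts[good], widths[good]
    if merge_tol is None:
        seg = np.linalg.norm(np.diff(pair.side1, axis=0), axis=1)
        merge_tol = float(np.median(seg)) / 4.0
    # merge near-duplicates: greedy grid hash on merge_tol cells
    keep = np.ones(len(pts), dtype=bool)
    tree = cKDTree(pts)
    for i, js in enumerate(tree.query_ball_point(pts, merge_tol)):
        if not keep[i]:
            continue
        for j in js:
            if j > i:
                keep[j] = False
    return MidpointCloud(points=pts[keep], local_width=widths[keep])


def fit_principal_curve(cloud: MidpointCloud | np.ndarray, df: float = 10,
                        tol: float = 1e-4, max_iter: int = 30,
                        dense_factor: int = 3) -> PrincipalCurve:
    """Hastie-Stuetzle principal curve at a prescribed equivalent df.

    Starts from the first principal component, then alternates projection of
    every point onto the current curve (giving arc-length ordinates) with
    coordinate-wise cubic smoothing-spline fits against those ordinates.
    Stops when the mean squared orthogonal distance changes by less than
    ``tol`` relatively, or after ``max_iter`` iterations (flagged).
    """
    pts = cloud.points if isinstance(cloud, MidpointCloud) else np.asarray(cloud)
    n = len(pts)
    if n < 10:
        raise MidlineError("need at least 10 points for a principal curve")
    nknots = min(n, max(30, int(2.5 * df) + 6))

    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    lam = (pts - center) @ vt[0]
    order = np.argsort(lam)
    curve = center + np.sort(lam)[:, None] * vt[0]
    dense = curve

    msd_prev = np.inf
    converged = False
    tang = None
    for _ in range(max_iter):
        lam, d2, _ = project_onto_polyline(dense, pts)
        msd = float(d2.mean())
        if msd_prev < np.inf and abs(msd_prev - msd) <= tol * max(msd_prev, 1e-12):
            converged = True
            break
        msd_prev = msd
        # jitter exact ties in the ordinate so the basis stays well posed
        if len(np.unique(lam)) < 8:
            lam = lam + np.linspace(0, 1e-9, len(lam))
        sx = smooth(lam, pts[:, 0], df=min(df, n - 2), nknots=nknots)
        sy = smooth(lam, pts[:, 1], df=min(df, n - 2), nknots=nknots)
        grid = np.linspace(lam.min(), lam.max(), max(dense_factor * n, 200))
        dense = np.column_stack([sx(grid), sy(grid)])
        tang = np.column_stack([sx.derivative(grid), sy.derivative(grid)])

    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    keep = np.concatenate([[True], seg > 1e-12])
    if tang is not None:
        tang = tang[keep] / np.linalg.norm(tang[keep], axis=1, keepdims=True)
    return PrincipalCurve(s=s[keep], points=dense[keep], df=df,
                          mean_sq_dist=msd_prev, converged=converged,
                          tangents=tang)


def resample_median(curve: PrincipalCurve, cloud: MidpointCloud,
                    step: float = 0.0199, base_point: np.ndarray | None = None,
                    frame_time: float = 0.0, k_width: int = 3,
                    trim: float = 0.0) -> MidlineCurve:
    """Resample the curve every ``step`` mm from the base (s = 0).

    ``base_point`` decides orientation: the curve end nearest it becomes
    s = 0.  Local width at each sample is the mean width of the ``k_width``
    nearest midpoints.  ``trim`` mm are dropped from both ends before
    resampling — the silhouette of a round-capped organ extends about one
    radius beyond each true midline end, so trimming the cap radius aligns
    s = 0 with the organ base.
    """
    if curve.length < 5 * step + 2 * trim:
        raise MidlineError("curve shorter than 5 resampling steps")
    if base_point is not None:
        d0 = np.linalg.norm(curve.points[0] - base_point)
        d1 = np.linalg.norm(curve.points[-1] - base_point)
        if d1 < d0:
            curve = curve.reversed()
    s = trim + np.arange(0.0, curve.length - 2 * trim + step * 1e-6, step)
    pts = curve(s)
    tangents = curve.tangent(s)
    s = s - trim
    tree = cKDTree(cloud.points)
    _, idx = tree.query(pts, k=min(k_width, len(cloud.points)))
    width = cloud.local_width[np.atleast_2d(idx)].mean(axis=1)
    return MidlineCurve(s=s, points=pts, width=width, frame_time=frame_time,
                        tangents=tangents)


def extract_midline(frame: np.ndarray, scale_mm: float,
                    anchor: np.ndarray | None = None, df: float = 10,
                    step: float = 0.0199, frame_time: float = 0.0,
                    threshold_method: str = "otsu",
                    cap_trim: bool = False) -> tuple[MidlineCurve, ContourPair, MidpointCloud]:
    """Full per-frame chain: binarize -> contours -> midpoints -> curve -> resample.

    Cap-region midpoints are filtered out by :func:`midpoints`; with
    ``cap_trim`` an additional half-width is dropped from both curve ends.
    """
    mask = binarize(frame, threshold_method)
    pair = extract_contours(mask, scale_mm, anchor=anchor, image=frame)
    cloud = midpoints(pair)
    curve = fit_principal_curve(cloud, df=df)
    trim = 0.5 * float(np.median(cloud.local_width)) if cap_trim else 0.0
    mid = resample_median(curve, cloud, step=step, base_point=pair.base_end,
                          frame_time=frame_time, trim=trim)
    return mid, pair, cloud
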