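"""Reporter-luminescence sampling along the median and the flank insets.

At every parameterized midline point M_i a line normal to the median is
drawn; its nearest intersections with the two smoothed inset contours (each
lying 1/8 of the local organ diameter inside the surface) give the sampling
points V_i (convex flank) and C_i (concave flank).  Intensities are read
from the luminescence raster by bilinear interpolation, exposure-normalized
to counts per minute, smoothed along s at df = n/2, and summarized by the
log ratio LRL = log10(L_c / L_v) — a measure of differential reporter
activity across the organ.

Flank identity (which lab-frame side is convex) is decided once per
recording from the |C|-weighted mean curvature over all frames, so the LRL
sign convention cannot flip between frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .midline import ContourPair, MidlineCurve, MidpointCloud, PrincipalCurve, fit_principal_curve
from .tsmap import TSMap

__all__ = [
    "LumProfiles", "assign_sides", "label_flanks", "inset_contour",
    "sample_profiles", "smooth_profiles", "lrl_map", "luminescence_frame",
]

DEG = np.pi / 180.0


class SideError(RuntimeError):
    pass


@dataclass
class LumProfiles:
    """L_m, L_v, L_c (cpm) and LRL along s for one frame; invalid rows masked."""

    s: np.ndarray
    L_m: np.ndarray
    L_v: np.ndarray
    L_c: np.ndarray
    valid: np.ndarray
    frame_time: float = 0.0
    concave_sign: int = 1

    @property
    def lrl(self) -> np.ndarray:
        ok = self.valid & (self.L_c > 0) & (self.L_v > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            # difference of logs (not log of ratio) so that swapping the
            # flanks negates LRL bit-exactly
            out = np.log10(self.L_c) - np.log10(self.L_v)
        return np.where(ok, out, np.nan)


def assign_sides(C_values: np.ndarray, mask: np.ndarray | None = None) -> int:
    """Concave-side orientation from the |C|-weighted mean curvature.

    Returns +1 when the concave flank lies on the +1 side of the signed
    normal offset convention (the counter-clockwise normal of the base->tip
    tangent), -1 for the other side.  Raises for a never-bending recording.
    """
    C = np.asarray(C_values, float)
    if mask is not None:
        C = np.where(mask, C, np.nan)
    w = np.abs(C)
    tot = np.nansum(w)
    if not np.isfinite(tot) or tot <= 0:
        raise SideError("no dominant bend: recording never curves")
    m = np.nansum(w * C) / tot
    if abs(m) < 1e-9:
        raise SideError("no dominant bend: weighted mean curvature is zero")
    return 1 if m < 0 else -1


def _normals(midline: MidlineCurve) -> np.ndarray:
    d = midline.tangents
    if d is None:
        d = np.gradient(midline.points, midline.s, axis=0)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    return np.column_stack([-d[:, 1], d[:, 0]])  # CCW normal of the tangent


def label_flanks(midline: MidlineCurve, pair: ContourPair,
                 concave_sign: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (concave flank polyline, convex flank polyline)."""
    normals = _normals(midline)
    tree = cKDTree(midline.points)

    def mean_offset(poly: np.ndarray) -> float:
        _, idx = tree.query(poly)
        off = np.einsum("ij,ij->i", poly - midline.points[idx], normals[idx])
        return float(np.mean(off))

    o1 = mean_offset(pair.side1)
    if o1 * concave_sign > 0:
        return pair.side1, pair.side2
    return pair.side2, pair.side1


def inset_contour(flank: np.ndarray, midline: MidlineCurve,
                  fraction: float = 1.0 / 8.0, df: float = 60.0) -> PrincipalCurve:
    """Smoothed contour located ``fraction`` of the local diameter inside the flank.

    Each flank vertex is moved toward the midline by fraction x local
    diameter (the flank separation at the nearest midline point) and the
    moved points are fit by principal-curve analysis at the given df.
    """
    tree = cKDTree(midline.points)
    dist, idx = tree.query(flank)
    widths = midline.width[idx]
    inset_dist = fraction * widths
    if np.any(inset_dist >= dist + 1e-12):
        bad = np.argmax(inset_dist - dist)
        raise SideError(f"inset of {inset_dist[bad]:.4f} mm crosses the midline "
                        f"(flank only {dist[bad]:.4f} mm away)")
    direction = midline.points[idx] - flank
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    pts = flank + direction * inset_dist[:, None]
    return fit_principal_curve(MidpointCloud(points=pts, local_width=widths),
                               df=min(df, len(pts) - 2))


def _bilinear(raster: np.ndarray, pts_mm: np.ndarray, scale_mm: float) -> np.ndarray:
    h = raster.shape[0]
    cols = pts_mm[:, 0] / scale_mm
    rows = (h - 1) - pts_mm[:, 1] / scale_mm
    return map_coordinates(raster.astype(float), np.vstack([rows, cols]),
                           order=1, mode="nearest")


def sample_profiles(lum_raster: np.ndarray, scale_mm: float,
                    midline: MidlineCurve,
                    inset_concave: PrincipalCurve, inset_convex: PrincipalCurve,
                    exposure_min: float = 1.0,
                    concave_sign: int = 1) -> LumProfiles:
    """Raw L_m / L_v / L_c profiles for one frame (counts per minute).

    At each midline sample the normal line is intersected with both inset
    curves; rows where either intersection is missing within 2x the local
    width are masked rather than extrapolated.
    """
    normals = _normals(midline)
    tangents = np.column_stack([normals[:, 1], -normals[:, 0]])
    n = len(midline.s)
    pc = np.full((n, 2), np.nan)
    pv = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)

    def crossings(curve_pts: np.ndarray, out: np.ndarray):
        """Nearest crossing of each normal line with a dense inset polyline."""
        tree = cKDTree(curve_pts)
        hit = np.zeros(n, dtype=bool)
        for i in range(n):
            reach = 2.0 * midline.width[i]
            idx = tree.query_ball_point(midline.points[i], reach)
            if len(idx) < 2:
                continue
            idx = np.sort(idx)
            # signed distance of inset points from the normal line at M_i
            f = (curve_pts[idx] - midline.points[i]) @ tangents[i]
            contig = np.nonzero(np.diff(idx) == 1)[0]
            sgn = f[contig] * f[contig + 1]
            cross = contig[sgn <= 0]
            if len(cross) == 0:
                continue
            a = curve_pts[idx[cross]]
            b = curve_pts[idx[cross] + 1]
            fa, fb = f[cross], f[cross + 1]
            w = np.where(np.abs(fa - fb) > 1e-30, fa / (fa - fb), 0.5)
            pts = a + w[:, None] * (b - a)
            d = np.linalg.norm(pts - midline.points[i], axis=1)
            k = int(np.argmin(d))
            if d[k] <= reach:
                out[i] = pts[k]
                hit[i] = True
        return hit

    valid = crossings(inset_concave.points, pc) & crossings(inset_convex.points, pv)

    L_m = _bilinear(lum_raster, midline.points, scale_mm) / exposure_min
    L_c = np.full(n, np.nan)
    L_v = np.full(n, np.nan)
    if valid.any():
        L_c[valid] = _bilinear(lum_raster, pc[valid], scale_mm) / exposure_min
        L_v[valid] = _bilinear(lum_raster, pv[valid], scale_mm) / exposure_min
    return LumProfiles(s=midline.s.copy(), L_m=L_m, L_v=L_v, L_c=L_c,
                       valid=valid, frame_time=midline.frame_time,
                       concave_sign=concave_sign)


def smooth_profiles(raw: LumProfiles, df_frac: float = 0.5) -> LumProfiles:
    """Smooth each intensity profile along s at df = n/2; recompute LRL after."""
    from .splines import get_basis

    out = LumProfiles(s=raw.s.copy(), L_m=raw.L_m.copy(), L_v=raw.L_v.copy(),
                      L_c=raw.L_c.copy(), valid=raw.valid.copy(),
                      frame_time=raw.frame_time, concave_sign=raw.concave_sign)
    for name in ("L_m", "L_v", "L_c"):
        y = getattr(out, name)
        ok = raw.valid & np.isfinite(y) if name != "L_m" else np.isfinite(y)
        n = int(ok.sum())
        if n < 8:
            continue
        fit = get_basis(raw.s[ok]).fit(y[ok], df=n * df_frac)
        y2 = np.full_like(y, np.nan)
        y2[ok] = fit(raw.s[ok])
        setattr(out, name, y2)
    return out


def lrl_map(profiles: list[LumProfiles], step: float | None = None) -> dict[str, TSMap]:
    """Assemble LRL / L_m / L_v / L_c t-s maps from per-frame profiles."""
    signs = {p.concave_sign for p in profiles}
    if len(signs) > 1:
        raise SideError("inconsistent side labels across frames")
    times = np.array([p.frame_time for p in profiles])
    step = step or float(np.median(np.diff(profiles[0].s)))
    ns = max(len(p.s) for p in profiles)
    s = np.arange(ns) * step
    nt = len(profiles)
    fields = {k: np.full((nt, ns), np.nan) for k in ("LRL", "L_m", "L_v", "L_c")}
    for i, p in enumerate(profiles):
        n = len(p.s)
        if not np.allclose(p.s, s[:n], atol=step * 0.01):
            raise SideError("profile s grids are not on the common grid")
        fields["LRL"][i, :n] = p.lrl
        fields["L_m"][i, :n] = p.L_m
        fields["L_v"][i, :n] = p.L_v
        fields["L_c"][i, :n] = p.L_c
    return {k: TSMap(t=times, s=s, values=v, mask=np.isfinite(v), name=k)
            for k, v in fields.items()}


def luminescence_frame(lum_raster: np.ndarray, scale_mm: float,
                       midline: MidlineCurve, pair: ContourPair,
                       concave_sign: int, fraction: float = 1.0 / 8.0,
                       df_inset: float = 60.0, exposure_min: float = 1.0,
                       smooth: bool = True) -> LumProfiles:
    """Full per-frame chain: label flanks -> insets -> sample -> smooth."""
    flank_c, flank_v = label_flanks(midline, pair, concave_sign)
    ins_c = inset_contour(flank_c, midline, fraction=fraction, df=df_inset)
    ins_v = inset_contour(flank_v, midline, fraction=fraction, df=df_inset)
    raw = sample_profiles(lum_raster, scale_mm, midline, ins_c, ins_v,
                          exposure_min=exposure_min, concave_sign=concave_sign)
    return smooth_profiles(raw) if smooth else raw
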