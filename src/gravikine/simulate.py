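"""Forward simulation of graviproprioceptive bending and synthetic imaging.

A clamped rod-like organ (an etiolated hypocotyl) is turned to ``base_angle``
degrees from the vertical at t = 0.  Its curvature field then evolves by the
graviproprioception (GP) law

    dC(s,t)/dt = -beta * sin A(s,t) - gamma * C(s,t)

where ``A`` is the local deflection angle from the vertical (degrees at the
interface, radians internally), ``C = dA/ds`` the curvature, ``s`` arc length
from the clamped base, ``beta`` the graviception gain and ``gamma`` the
proprioceptive (curvature-sensing) decay.  ``gamma = 0`` reduces the law to
the classical sine law.  The deflection angle is recovered each step as

    A(s,t) = base_angle + integral_0^s C(s', t) ds'

so the base stays clamped.  Integration is explicit Euler on a fixed s grid
with a small inner step; frames are emitted on the imaging cadence.

The module also renders the trajectory into bright-field silhouettes and
luminescence count rasters with a known transverse log-ratio field, standing
in for raw microscope recordings with exact ground truth attached.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "GPParams", "SimGrid", "RodTrajectory", "LumModel", "FrameSeries",
    "simulate_gp_rod", "render_frames", "write_fixture", "load_fixture",
]

DEG = np.pi / 180.0


@dataclass
class GPParams:
    """Parameters of the GP bending law for one simulated organ.

    beta : curvature-rate gain per unit sin(A), mm^-1 h^-1
    gamma : proprioceptive decay rate, h^-1
    base_angle : clamped deflection at the base, degrees (90 = horizontal)
    initial_curvature : C(s, 0), mm^-1; scalar or array on the s grid
    length : rod length, mm
    elongation_rate : uniform relative growth rate, h^-1 (0 = non-growing)
    response_fn : gravitropic response kernel g(A_rad); default sin.  The
        driving term is -beta * g(A); a kernel peaked at a designed angle A*
        lets tests construct bending responses centred on a known A*.
    process_noise_sd : sd of white-noise perturbation of dC/dt
        (mm^-1 h^-1 per sqrt(h)); 0 keeps the run fully deterministic.
    """

    beta: float
    gamma: float
    base_angle: float = 90.0
    initial_curvature: float | np.ndarray = 0.0
    length: float = 4.0
    elongation_rate: float = 0.0
    response_fn: Callable[[np.ndarray], np.ndarray] | None = None
    process_noise_sd: float = 0.0

    def __post_init__(self):
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")
        if self.length <= 0:
            raise ValueError("length must be positive")


@dataclass
class SimGrid:
    """Discretization: spatial step, inner Euler step, imaging cadence."""

    ds: float = 0.0199          # mm; matches the downstream 19.9-um sampling
    dt_inner: float = 0.005     # h
    frame_interval: float = 0.170  # h
    t_end: float = 6.10         # h

    def __post_init__(self):
        if self.ds <= 0:
            raise ValueError("ds must be positive")
        if self.dt_inner > self.frame_interval:
            raise ValueError("dt_inner must not exceed frame_interval")


@dataclass
class RodTrajectory:
    """Ground-truth midline/angle/curvature fields at the frame times.

    Shapes: times (nt,); s (ns,); A, C, dCdt (nt, ns); points (nt, ns, 2) in
    mm with the base at the origin, +y vertical up, +x the turning side.
    A is in degrees, C in mm^-1, dCdt in mm^-1 h^-1.
    """

    times: np.ndarray
    s: np.ndarray
    A: np.ndarray
    C: np.ndarray
    dCdt: np.ndarray
    points: np.ndarray
    params: GPParams
    grid: SimGrid

    @property
    def n_frames(self) -> int:
        return len(self.times)


class SimulationUnstable(RuntimeError):
    pass


def _angle_from_curvature(C: np.ndarray, ds: float, base_rad: float) -> np.ndarray:
    # trapezoid cumulative integral of C from the base
    inc = 0.5 * (C[1:] + C[:-1]) * ds
    return base_rad + np.concatenate([[0.0], np.cumsum(inc)])


def _midline_points(A_rad: np.ndarray, ds: float) -> np.ndarray:
    tx, ty = np.sin(A_rad), np.cos(A_rad)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (tx[1:] + tx[:-1]) * ds)])
    y = np.concatenate([[0.0], np.cumsum(0.5 * (ty[1:] + ty[:-1]) * ds)])
    return np.column_stack([x, y])


def simulate_gp_rod(params: GPParams, grid: SimGrid | None = None,
                    seed: int = 0, c_max: float = 50.0) -> RodTrajectory:
    """Integrate the GP law and return ground-truth fields at frame times.

    Deterministic for given inputs; ``seed`` only matters when
    ``params.process_noise_sd`` > 0.  Raises :class:`SimulationUnstable`
    when |C| exceeds ``c_max`` (suggesting a smaller ``dt_inner``).
    """
    grid = grid or SimGrid()
    rng = np.random.default_rng(seed)
    g = params.response_fn or np.sin

    ns = int(round(params.length / grid.ds)) + 1
    s = np.arange(ns) * grid.ds
    C = np.broadcast_to(np.asarray(params.initial_curvature, float), (ns,)).copy()
    base_rad = params.base_angle * DEG
    ds = grid.ds

    n_frames = int(np.floor(grid.t_end / grid.frame_interval + 1e-9)) + 1
    n_sub = max(1, int(round(grid.frame_interval / grid.dt_inner)))
    dt = grid.frame_interval / n_sub

    times = np.empty(n_frames)
    A_out = np.empty((n_frames, ns))
    C_out = np.empty((n_frames, ns))
    R_out = np.empty((n_frames, ns))
    P_out = np.empty((n_frames, ns, 2))

    t = 0.0
    for k in range(n_frames):
        A_rad = _angle_from_curvature(C, ds, base_rad)
        rate = -params.beta * g(A_rad) - params.gamma * C
        times[k] = t
        A_out[k] = A_rad / DEG
        C_out[k] = C
        R_out[k] = rate
        P_out[k] = _midline_points(A_rad, ds)
        if k == n_frames - 1:
            break
        for _ in range(n_sub):
            A_rad = _angle_from_curvature(C, ds, base_rad)
            rate = -params.beta * g(A_rad) - params.gamma * C
            if params.process_noise_sd > 0:
                rate = rate + rng.normal(0.0, params.process_noise_sd / np.sqrt(dt), ns)
            C = C + dt * rate
            if params.elongation_rate > 0:
                # uniform stretch dilutes curvature and lengthens the grid
                f = 1.0 + params.elongation_rate * dt
                C /= f
                ds *= f
            if np.max(np.abs(C)) > c_max:
                raise SimulationUnstable(
                    f"|C| exceeded {c_max} mm^-1 at t={t:.3f} h; "
                    "reduce dt_inner or check parameters")
            t += dt

    if params.elongation_rate > 0:
        s = np.arange(ns) * ds  # final grid; fields stay on material nodes
    return RodTrajectory(times=times, s=s, A=A_out, C=C_out, dCdt=R_out,
                         points=P_out, params=params, grid=grid)


# ---------------------------------------------------------------------------
# rendering

@dataclass
class LumModel:
    """Luminescence ground-truth model for rendering.

    The longitudinal profile emulates a reporter-activity bump that drifts
    basipetally (toward the base) over hours; the transverse profile is
    log-linear across the rod width, pinned so that log10 of the intensity at
    the concave 1/8-inset point over the convex 1/8-inset point equals
    ``lrl_true(s, t)`` exactly before noise.

    By default lrl_true(s,t) = -kappa * sin A(s, t - tau), a delayed
    sine-of-angle differential-expression response (kappa = 0.5, tau = 1.5 h;
    the organ is vertical before turning, so lrl_true = 0 for t < tau).
    """

    rod_diameter: float = 0.25           # mm
    background: float = 5.0              # counts
    base_level: float = 400.0            # counts at the midline, baseline
    bump_amplitude: float = 1.5          # relative height of the moving bump
    bump_width: float = 0.5              # mm (Gaussian sd)
    bump_speed: float = 0.33             # mm/h basipetal drift
    bump_floor: float = 1.2              # mm; the bump stops here
    lrl_kappa: float = 0.5
    lrl_tau: float = 1.5                 # h
    read_noise_sd: float = 2.0           # counts
    poisson_noise: bool = True
    exposure_min: float = 1.0
    lrl_fn: Callable[[np.ndarray, float], np.ndarray] | None = None
    longitudinal_fn: Callable[[np.ndarray, float], np.ndarray] | None = None

    def __post_init__(self):
        if self.rod_diameter <= 0:
            raise ValueError("rod_diameter must be positive")
        if self.background <= 0 or self.base_level <= 0:
            raise ValueError("intensities must be strictly positive")

    def longitudinal(self, s: np.ndarray, t: float, length: float) -> np.ndarray:
        if self.longitudinal_fn is not None:
            return self.longitudinal_fn(s, t)
        peak = max(self.bump_floor, 0.8 * length - self.bump_speed * t)
        return self.base_level * (
            1.0 + self.bump_amplitude * np.exp(-0.5 * ((s - peak) / self.bump_width) ** 2))

    def lrl(self, traj: RodTrajectory, s: np.ndarray, t: float) -> np.ndarray:
        if self.lrl_fn is not None:
            return self.lrl_fn(s, t)
        t_lag = t - self.lrl_tau
        if t_lag < 0:
            return np.zeros_like(s)  # vertical before turning
        k = int(np.clip(np.searchsorted(traj.times, t_lag), 0, len(traj.times) - 1))
        A_lag = np.interp(s, traj.s, traj.A[k])
        return -self.lrl_kappa * np.sin(A_lag * DEG)


@dataclass
class FrameSeries:
    """Rendered bright-field and luminescence rasters plus geometry metadata.

    Image physical coordinates: x = col * scale, y = (H-1-row) * scale (mm),
    i.e. +y is up in the displayed image.  ``origin_mm`` maps simulation
    world coordinates into this frame: img = world - origin.
    """

    bright: np.ndarray            # (nt, H, W) float32
    lum: np.ndarray               # (nt, H, W) float32 counts
    pixel_scale: float            # um / pixel
    times: np.ndarray             # h
    origin_mm: np.ndarray         # (2,)
    gravity_up: tuple[float, float] = (0.0, 1.0)  # in image physical coords
    exposure_min: float = 1.0
    concave_sign: int = 1

    @property
    def scale_mm(self) -> float:
        return self.pixel_scale / 1000.0

    def world_to_image(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) - self.origin_mm


class RodOutOfFrame(RuntimeError):
    pass


def _dominant_concave_sign(traj: RodTrajectory) -> int:
    w = np.abs(traj.C)
    m = float(np.sum(w * traj.C) / max(np.sum(w), 1e-12))
    # centre of curvature lies along -C * N_ccw; upward bending (C<0) puts the
    # concave flank on the +N_ccw side
    return 1 if m <= 0 else -1


def render_frames(traj: RodTrajectory, lum: LumModel | None = None,
                  pixel_scale: float = 16.0, shape: tuple[int, int] = (512, 512),
                  seed: int = 0, noise: bool = True,
                  origin_jitter: bool = True) -> FrameSeries:
    """Render silhouette and luminescence rasters for every frame.

    The bright frame is a filled constant-width band swept along the midline
    over a dark background, with one-pixel anti-aliased edges so sub-pixel
    midline positions survive binarization.  The luminescence frame carries
    the exact transverse log-ratio field of ``lum`` before noise.

    ``origin_jitter`` offsets the whole recording by a seeded sub-pixel
    amount, emulating the arbitrary placement of a specimen on the sensor
    grid; replicate recordings then sample different rasterizations.
    """
    lum = lum or LumModel()
    rng = np.random.default_rng(seed)
    H, W = shape
    scale = pixel_scale / 1000.0  # mm per pixel
    r = lum.rod_diameter / 2.0
    u_inset = 0.75 * r  # 1/8-diameter inset from each surface

    pts_all = traj.points.reshape(-1, 2)
    lo, hi = pts_all.min(axis=0), pts_all.max(axis=0)
    margin = lum.rod_diameter
    span = hi - lo + 2 * margin
    fov = np.array([(W - 1) * scale, (H - 1) * scale])
    if np.any(span > fov):
        # find the first offending frame for the diagnostic
        for k in range(traj.n_frames):
            ext = traj.points[k].max(axis=0) - traj.points[k].min(axis=0) + 2 * margin
            if np.any(ext > fov):
                raise RodOutOfFrame(f"rod leaves the raster at frame {k} "
                                    f"(extent {ext} mm vs field {fov} mm)")
        raise RodOutOfFrame("rod trajectory exceeds the raster field of view")
    origin = lo - margin - (fov - span) / 2.0
    if origin_jitter:
        origin = origin + rng.uniform(-0.5, 0.5, 2) * scale

    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    px = np.column_stack([cols.ravel() * scale,
                          (H - 1 - rows.ravel()) * scale])  # image physical mm

    concave_sign = _dominant_concave_sign(traj)
    bright = np.empty((traj.n_frames, H, W), dtype=np.float32)
    lum_out = np.empty_like(bright)
    bg_bright, amp_bright = 20.0, 200.0

    # dense midline for distance queries (spacing << pixel)
    fine_step = min(scale / 3.0, traj.grid.ds / 2.0)
    s_fine = np.arange(0.0, traj.s[-1] + fine_step / 2, fine_step)

    for k in range(traj.n_frames):
        mid = traj.points[k] - origin
        fx = np.interp(s_fine, traj.s, mid[:, 0])
        fy = np.interp(s_fine, traj.s, mid[:, 1])
        fine = np.column_stack([fx, fy])
        A_fine = np.interp(s_fine, traj.s, traj.A[k]) * DEG
        tree = cKDTree(fine)
        # coarse prefilter: EDT to rasterized midline samples narrows the
        # pixels that need an exact nearest-point query
        occ = np.ones((H, W), dtype=bool)
        rr = np.clip(np.round((H - 1) - fine[:, 1] / scale).astype(int), 0, H - 1)
        cc = np.clip(np.round(fine[:, 0] / scale).astype(int), 0, W - 1)
        occ[rr, cc] = False
        edt = ndimage.distance_transform_edt(occ)
        cand = np.nonzero(edt.ravel() * scale <= r + 4 * scale)[0]
        d = np.full(px.shape[0], np.inf)
        idx = np.zeros(px.shape[0], dtype=np.intp)
        d[cand], idx[cand] = tree.query(px[cand], workers=-1)
        near = d <= r + 2 * scale
        frac = np.clip((r - d) / scale + 0.5, 0.0, 1.0)

        b = bg_bright + (amp_bright - bg_bright) * frac
        if noise:
            b = b + rng.normal(0.0, 1.0, b.shape)
        bright[k] = b.reshape(H, W).astype(np.float32)

        counts = np.full(px.shape[0], lum.background)
        sel = np.where(near & (frac > 0))[0]
        if sel.size:
            i = idx[sel]
            s_near = s_fine[i]
            # signed transverse offset along the CCW normal of the tangent
            n_ccw = np.column_stack([-np.cos(A_fine[i]), np.sin(A_fine[i])])
            u = np.einsum("ij,ij->i", px[sel] - fine[i], n_ccw)
            u_c = u * concave_sign  # + toward the concave flank
            L0 = lum.longitudinal(s_near, traj.times[k], traj.s[-1])
            lrl = lum.lrl(traj, s_near, traj.times[k])
            inten = L0 * np.power(10.0, 0.5 * lrl * (u_c / u_inset))
            f = frac[sel]
            counts[sel] = lum.background * (1 - f) + inten * f
        if noise:
            if lum.poisson_noise:
                counts = rng.poisson(np.clip(counts, 0, None)).astype(float)
            if lum.read_noise_sd > 0:
                counts = counts + rng.normal(0.0, lum.read_noise_sd, counts.shape)
        lum_out[k] = counts.reshape(H, W).astype(np.float32)

    return FrameSeries(bright=bright, lum=lum_out, pixel_scale=pixel_scale,
                       times=traj.times.copy(), origin_mm=origin,
                       exposure_min=lum.exposure_min, concave_sign=concave_sign)


# ---------------------------------------------------------------------------
# fixture I/O

def _params_dict(obj) -> dict:
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if callable(v):
            d[f.name] = getattr(v, "__name__", "custom")
        elif isinstance(v, np.ndarray):
            d[f.name] = v.tolist()
        else:
            d[f.name] = v
    return d


def write_fixture(frames: FrameSeries, traj: RodTrajectory, lum: LumModel,
                  path: str | Path, seed: int | None = None) -> dict:
    """Write TIFF series, ground-truth tables and a YAML manifest.

    Returns the manifest dict.  Bit-reproducible for a fixed seed because all
    stochastic draws happen upstream under explicit generators.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "bright.tif", frames.bright)
    tifffile.imwrite(path / "lum.tif", frames.lum)

    rows = []
    for k, t in enumerate(traj.times):
        lrl = lum.lrl(traj, traj.s, float(t))
        for j, s in enumerate(traj.s):
            rows.append((t, s, traj.A[k, j], traj.C[k, j], traj.dCdt[k, j], lrl[j]))
    truth = pd.DataFrame(rows, columns=["t", "s", "A", "C", "dCdt", "lrl"])
    truth.to_csv(path / "ground_truth.csv", index=False)

    mid = []
    for k, t in enumerate(traj.times):
        img = frames.world_to_image(traj.points[k])
        for j, s in enumerate(traj.s):
            mid.append((t, s, img[j, 0], img[j, 1]))
    pd.DataFrame(mid, columns=["t", "s", "x", "y"]).to_csv(
        path / "ground_truth_midline.csv", index=False)

    manifest = {
        "seed": seed,
        "pixel_scale_um": frames.pixel_scale,
        "origin_mm": frames.origin_mm.tolist(),
        "exposure_min": frames.exposure_min,
        "concave_sign": int(frames.concave_sign),
        "times_h": frames.times.tolist(),
        "gp_params": _params_dict(traj.params),
        "sim_grid": _params_dict(traj.grid),
        "lum_model": _params_dict(lum),
    }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def load_fixture(path: str | Path) -> tuple[FrameSeries, pd.DataFrame, dict]:
    """Read a fixture directory back: (frames, ground-truth table, manifest)."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    frames = FrameSeries(
        bright=tifffile.imread(path / "bright.tif"),
        lum=tifffile.imread(path / "lum.tif"),
        pixel_scale=manifest["pixel_scale_um"],
        times=np.asarray(manifest["times_h"]),
        origin_mm=np.asarray(manifest["origin_mm"]),
        exposure_min=manifest.get("exposure_min", 1.0),
        concave_sign=manifest.get("concave_sign", 1),
    )
    truth = pd.read_csv(path / "ground_truth.csv")
    return frames, truth, manifest
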