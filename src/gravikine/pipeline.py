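"""End-to-end orchestration: simulate -> midline -> kinematics -> luminescence -> fits.

Every stage writes its tables under the run directory and the run is fully
described by a provenance manifest (config, seeds, package version), so a
rerun with the same seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .kinematics import align_with_angle, build_fields, detect_extremal_paths
from .luminescence import assign_sides, lrl_map, luminescence_frame
from .midline import extract_midline
from .model_fit import beta_map, fit_series, scan_sine_segments
from .plotting import render_map
from .simulate import (FrameSeries, GPParams, LumModel, SimGrid, load_fixture,
                       render_frames, simulate_gp_rod, write_fixture)

log = logging.getLogger("gravikine")

__all__ = ["run_pipeline", "simulate_stage", "extract_stage", "kinematics_stage",
           "luminescence_stage", "fit_stage"]


def simulate_stage(cfg: RunConfig, out: Path) -> tuple[FrameSeries, dict]:
    params = GPParams(beta=cfg.beta, gamma=cfg.gamma, base_angle=cfg.base_angle,
                      length=cfg.length)
    grid = SimGrid(frame_interval=cfg.frame_interval, t_end=cfg.t_end)
    traj = simulate_gp_rod(params, grid, seed=cfg.seed)
    lum = LumModel(rod_diameter=cfg.rod_diameter)
    frames = render_frames(traj, lum, pixel_scale=cfg.pixel_scale or 16.0,
                           shape=cfg.raster, seed=cfg.seed, noise=cfg.noise)
    manifest = write_fixture(frames, traj, lum, out / "fixture", seed=cfg.seed)
    log.info("simulated %d frames (beta=%.3g, gamma=%.3g)",
             traj.n_frames, cfg.beta, cfg.gamma)
    return frames, manifest


def extract_stage(frames: FrameSeries, cfg: RunConfig,
                  anchor0: np.ndarray | None = None):
    """Per-frame midline extraction with a stable base across the series."""
    scale_mm = frames.scale_mm
    midlines, pairs = [], []
    anchor = anchor0
    for k in range(len(frames.times)):
        try:
            mid, pair, _cloud = extract_midline(
                frames.bright[k], scale_mm, anchor=anchor, df=cfg.df_median,
                step=cfg.step_mm, frame_time=float(frames.times[k]),
                threshold_method=cfg.threshold_method)
        except Exception as exc:
            raise RuntimeError(f"midline extraction failed at frame {k}: {exc}") from exc
        anchor = mid.points[0]  # subsequent frames anchor on this base
        midlines.append(mid)
        pairs.append(pair)
    return midlines, pairs


def kinematics_stage(midlines, cfg: RunConfig):
    """A/C/dCdt/SEE-ratio fields with the turning side oriented positive."""
    from .kinematics import deflection_angle

    a0 = deflection_angle(midlines[0])
    sign = 1.0 if np.nanmean(a0) >= 0 else -1.0
    fields = build_fields(midlines, turning_sign=sign, step=cfg.step_mm,
                          tip_margin=cfg.tip_margin)
    troughs = detect_extremal_paths(fields["dCdt"], "trough",
                                    min_extent=cfg.trough_min_extent,
                                    depth_frac=cfg.trough_depth_frac)
    heights = detect_extremal_paths(fields["dCdt"], "height",
                                    min_extent=cfg.trough_min_extent,
                                    depth_frac=cfg.trough_depth_frac)
    for p in troughs + heights:
        align_with_angle(p, fields["A"], resolution=cfg.align_resolution)
    return fields, troughs, heights, sign


def luminescence_stage(frames: FrameSeries, midlines, pairs, fields, cfg: RunConfig):
    concave_sign = assign_sides(fields["C"].values, fields["C"].mask)
    profiles = []
    for k, (mid, pair) in enumerate(zip(midlines, pairs)):
        profiles.append(luminescence_frame(
            frames.lum[k], frames.scale_mm, mid, pair, concave_sign,
            fraction=cfg.inset_fraction, df_inset=cfg.df_inset,
            exposure_min=frames.exposure_min))
    maps = lrl_map(profiles, step=cfg.step_mm)
    return profiles, maps, concave_sign


def fit_stage(fields, lum_maps, cfg: RunConfig):
    fits_dcdt = fit_series(fields["dCdt"], fields["A"], fields["C"],
                           s_min=cfg.s_min, response_tag="dCdt",
                           include_intercept=cfg.include_intercept)
    fits_lrl = fit_series(lum_maps["LRL"], fields["A"], fields["C"],
                          s_min=cfg.s_min, response_tag="LRL",
                          include_intercept=cfg.include_intercept)
    lrl = lum_maps["LRL"]
    segments = {}
    for i, t in enumerate(lrl.t):
        segments[float(t)] = scan_sine_segments(
            lrl.s, lrl.values[i], fields["A"].values[i],
            min_len=cfg.min_segment_mm, r2_min=cfg.r2_min, t=float(t))
    bmap = beta_map(segments, lrl.s)
    return fits_dcdt, fits_lrl, segments, bmap


def _fit_table(rows) -> pd.DataFrame:
    recs = []
    for r in rows:
        for m in ("gp", "sine"):
            f = r[m]
            recs.append(dict(t=f.t, model=f.model, response=f.response,
                             beta=f.beta, gamma=f.gamma, beta_se=f.beta_se,
                             gamma_se=f.gamma_se, beta_p=f.beta_p,
                             gamma_p=f.gamma_p, aic=f.aic, adj_r2=f.adj_r2,
                             n=f.n, selected=r["selected"]))
    return pd.DataFrame(recs)


_TROUGH_COLS = ["path", "polarity", "t", "s", "value", "aligned_angle", "residual"]


def _trough_table(paths) -> pd.DataFrame:
    recs = []
    for i, p in enumerate(paths):
        for t, s, v in zip(p.t, p.s, p.values):
            recs.append(dict(path=i, polarity=p.polarity, t=t, s=s, value=v,
                             aligned_angle=p.aligned_angle,
                             residual=p.alignment_residual))
    return pd.DataFrame(recs, columns=_TROUGH_COLS)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline per the config; returns the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        if cfg.simulate:
            frames, sim_manifest = simulate_stage(cfg, out)
            anchor0 = frames.world_to_image(np.zeros(2))
        else:
            frames, _truth, sim_manifest = load_fixture(cfg.input_dir)
            if cfg.pixel_scale is not None:
                frames.pixel_scale = cfg.pixel_scale
            anchor0 = None

        midlines, pairs = extract_stage(frames, cfg, anchor0)
        md = pd.concat([
            pd.DataFrame({"t": m.frame_time, "s": m.s, "x": m.points[:, 0],
                          "y": m.points[:, 1], "width": m.width})
            for m in midlines])
        md.to_csv(out / "midlines.csv", index=False)

        fields, troughs, heights, turning_sign = kinematics_stage(midlines, cfg)
        for name, f in fields.items():
            f.save_csv(out / f"map_{name}.csv")
        _trough_table(troughs + heights).to_csv(out / "trough_paths.csv", index=False)
        render_map(fields["dCdt"], out / "map_dCdt.png", a_overlay=fields["A"],
                   trough_paths=troughs + heights)
        render_map(fields["C"], out / "map_C.png")
        render_map(fields["A"], out / "map_A.png")

        profiles, lum_maps, concave_sign = luminescence_stage(
            frames, midlines, pairs, fields, cfg)
        pd.concat([
            pd.DataFrame({"t": p.frame_time, "s": p.s, "L_m": p.L_m,
                          "L_v": p.L_v, "L_c": p.L_c, "LRL": p.lrl,
                          "valid": p.valid})
            for p in profiles]).to_csv(out / "profiles.csv", index=False)
        for name in ("LRL", "L_m"):
            lum_maps[name].save_csv(out / f"map_{name}.csv")
        render_map(lum_maps["LRL"], out / "map_LRL.png", a_overlay=fields["A"])

        fits_dcdt, fits_lrl, segments, bmap = fit_stage(fields, lum_maps, cfg)
        _fit_table(fits_dcdt).to_csv(out / "fits_dCdt.csv", index=False)
        _fit_table(fits_lrl).to_csv(out / "fits_LRL.csv", index=False)
        pd.DataFrame([dict(t=seg.t, s_start=seg.s_start, s_end=seg.s_end,
                           beta=seg.beta, r2=seg.r2)
                      for segs in segments.values() for seg in segs],
                     columns=["t", "s_start", "s_end", "beta", "r2"]
                     ).to_csv(out / "sine_segments.csv", index=False)
        bmap.save_csv(out / "map_beta_segments.csv")
        render_map(bmap, out / "map_beta_segments.png", cmap="plasma")

        manifest = {
            "gravikine_version": __version__,
            "config": cfg.to_dict(),
            "turning_sign": float(turning_sign),
            "concave_sign": int(concave_sign),
            "simulation": sim_manifest,
            "n_frames": len(midlines),
        }
        with open(out / "manifest.yaml", "w") as f:
            yaml.safe_dump(manifest, f, sort_keys=False)
        log.info("pipeline complete: %s", out)
        return out
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
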