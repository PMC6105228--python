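"""GP-rod simulator and renderer: analytic limits, consistency, round trips."""

import numpy as np
import pytest

from gravikine.simulate import (GPParams, LumModel, RodOutOfFrame, SimGrid,
                                SimulationUnstable, load_fixture, render_frames,
                                simulate_gp_rod, write_fixture)

DEG = np.pi / 180.0


def integrate_angle(traj, k):
    c = traj.C[k]
    ds = np.diff(traj.s)
    inc = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * ds)])
    return traj.A[k, 0] + inc / DEG


def test_no_driving_term_stays_straight():
    traj = simulate_gp_rod(GPParams(beta=0.0, gamma=0.0), SimGrid(t_end=1.0))
    assert np.allclose(traj.A, 90.0)
    assert np.allclose(traj.C, 0.0)


def test_initial_curvature_rate_is_minus_beta_at_horizontal():
    traj = simulate_gp_rod(GPParams(beta=0.7, gamma=0.0), SimGrid(t_end=0.5))
    assert np.allclose(traj.dCdt[0], -0.7)  # sin(90 deg) = 1 everywhere


def test_angle_curvature_consistency(gp_traj):
    """A(s) - A(0) must equal the integral of C for every frame (< 0.1 deg)."""
    for k in range(gp_traj.n_frames):
        assert np.abs(integrate_angle(gp_traj, k) - gp_traj.A[k]).max() < 0.1


def test_base_stays_clamped(gp_traj):
    assert np.allclose(gp_traj.A[:, 0], 90.0)
    assert np.allclose(gp_traj.points[:, 0], 0.0)


def test_convergence_on_inner_step():
    p = GPParams(beta=0.4, gamma=1.5)
    a = simulate_gp_rod(p, SimGrid(dt_inner=0.005))
    b = simulate_gp_rod(p, SimGrid(dt_inner=0.0025))
    assert np.abs(a.C - b.C).max() < 0.005 * np.abs(a.C).max()


def test_reference_run_agrees_with_fine_integration():
    """Tip relaxes toward vertical; trajectory matches a 10x finer reference."""
    p = GPParams(beta=0.4, gamma=1.5, length=4.0)
    run = simulate_gp_rod(p, SimGrid(dt_inner=0.01, t_end=6.0))
    ref = simulate_gp_rod(p, SimGrid(dt_inner=0.001, t_end=6.0))
    assert np.abs(run.C - ref.C).max() < 0.01 * np.abs(ref.C).max()
    tip = run.A[:, -1]
    assert tip[-1] < 45.0  # decreased toward vertical
    assert np.abs(tip[-8:] - tip[-1]).max() < 5.0  # no sustained oscillation growth


def test_linearization_small_times():
    traj = simulate_gp_rod(GPParams(beta=0.4, gamma=0.0, length=4.0), SimGrid())
    for i, t in enumerate(traj.times):
        if not 0 < t <= 0.1 / 0.4:
            continue
        expected = -0.4 * t
        assert np.abs(traj.C[i] - expected).max() < 0.02 * abs(expected)


def test_instability_raises_with_diagnostic():
    with pytest.raises(SimulationUnstable, match="dt_inner"):
        simulate_gp_rod(GPParams(beta=500.0, gamma=0.0),
                        SimGrid(dt_inner=0.1, frame_interval=0.1, t_end=6.0))


def test_process_noise_only_with_flag():
    p_det = GPParams(beta=0.4, gamma=1.5)
    a = simulate_gp_rod(p_det, seed=1)
    b = simulate_gp_rod(p_det, seed=2)
    assert np.array_equal(a.C, b.C)  # deterministic without noise
    p_sto = GPParams(beta=0.4, gamma=1.5, process_noise_sd=0.01)
    c = simulate_gp_rod(p_sto, seed=1)
    d = simulate_gp_rod(p_sto, seed=2)
    assert not np.array_equal(c.C, d.C)


# ---------------------------------------------------------------------------
# rendering

def _transverse_profile(frames, traj, k, s_probe):
    """Sample the luminescence raster along the normal at arc position s."""
    from scipy.ndimage import map_coordinates
    j = np.argmin(np.abs(traj.s - s_probe))
    m = frames.world_to_image(traj.points[k])[j]
    a = traj.A[k, j] * DEG
    n = np.array([-np.cos(a), np.sin(a)])
    offs = np.linspace(-0.09, 0.09, 41)
    pts = m[None, :] + offs[:, None] * n[None, :]
    h = frames.lum.shape[1]
    scale = frames.scale_mm
    rows = (h - 1) - pts[:, 1] / scale
    cols = pts[:, 0] / scale
    vals = map_coordinates(frames.lum[k].astype(float), np.vstack([rows, cols]),
                           order=1)
    return offs, vals


def test_zero_lrl_renders_symmetric():
    traj = simulate_gp_rod(GPParams(beta=0.3, gamma=1.0, length=3.0),
                           SimGrid(t_end=1.0))
    lum = LumModel(lrl_fn=lambda s, t: np.zeros_like(s))
    frames = render_frames(traj, lum, pixel_scale=16.0, shape=(256, 256),
                           seed=0, noise=False, origin_jitter=False)
    offs, vals = _transverse_profile(frames, traj, 3, 1.5)
    assert np.abs(vals - vals[::-1]).max() < 0.02 * vals.max()


def test_constant_lrl_round_trip():
    """log10 ratio at the 1/8-inset points equals lrl_true before noise."""
    traj = simulate_gp_rod(GPParams(beta=0.3, gamma=1.0, length=3.0),
                           SimGrid(t_end=1.0))
    lum = LumModel(lrl_fn=lambda s, t: np.full_like(s, -0.3))
    frames = render_frames(traj, lum, pixel_scale=16.0, shape=(256, 256),
                           seed=0, noise=False, origin_jitter=False)
    u = 0.75 * lum.rod_diameter / 2.0
    offs, vals = _transverse_profile(frames, traj, 3, 1.5)
    hi = np.interp(+u * frames.concave_sign, offs, vals)
    lo = np.interp(-u * frames.concave_sign, offs, vals)
    assert np.log10(hi / lo) == pytest.approx(-0.3, abs=0.02)


def test_rod_leaving_raster_names_frame():
    traj = simulate_gp_rod(GPParams(beta=0.4, gamma=1.5, length=4.0), SimGrid())
    with pytest.raises(RodOutOfFrame):
        render_frames(traj, LumModel(), pixel_scale=16.0, shape=(64, 64), seed=0)


def test_fixture_round_trip_is_bit_reproducible(tmp_path, gp_traj, lum_model,
                                                rendered):
    m1 = write_fixture(rendered, gp_traj, lum_model, tmp_path / "a", seed=7)
    frames2, truth, m2 = load_fixture(tmp_path / "a")
    assert np.array_equal(frames2.bright, rendered.bright)
    assert np.array_equal(frames2.lum, rendered.lum)
    assert m1["seed"] == m2["seed"] == 7
    assert {"t", "s", "A", "C", "dCdt", "lrl"} <= set(truth.columns)
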