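"""Angle/curvature fields, trough tracing and angle alignment."""

import numpy as np
import pytest

from gravikine.kinematics import (align_with_angle, curvature, curvature_rate,
                                  deflection_angle, detect_extremal_paths,
                                  see_ratio_map)
from gravikine.midline import MidlineCurve
from gravikine.tsmap import TSMap

DEG = np.pi / 180.0


def straight_midline(direction, n=60, step=0.0199):
    s = np.arange(n) * step
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return MidlineCurve(s=s, points=np.outer(s, d), width=np.full(n, 0.25))


def test_vertical_midline_has_zero_angle():
    assert np.abs(deflection_angle(straight_midline([0, 1]))).max() < 1e-9


def test_horizontal_midline_is_90_degrees():
    assert deflection_angle(straight_midline([1, 0])) == pytest.approx(90.0)


def test_quarter_circle_angle_linear_in_s():
    r = 2.0
    s = np.arange(0.0, r * np.pi / 2, 0.0199)
    phi = s / r
    pts = r * np.column_stack([np.sin(phi), 1 - np.cos(phi)])  # horizontal -> vertical
    mid = MidlineCurve(s=s, points=pts, width=np.full_like(s, 0.25))
    A = deflection_angle(mid)
    expected = 90.0 - s / r / DEG
    assert np.abs(A - expected).max() < 0.05


def test_curvature_of_linear_angle_profile():
    s = np.arange(0.0, 3.0, 0.0199)
    k = 0.7  # rad / mm
    A = (1.0 + k * s) / DEG
    C, A_s = curvature(s, A)
    assert np.abs(C - k).max() < 1e-5
    assert np.abs(A_s - A).max() < 1e-5


@pytest.mark.parametrize("r", [0.5, 1.0, 2.0, 5.0, 10.0])
def test_circle_curvature_within_one_percent(r):
    from gravikine.studies import circle_arc_midline
    arc = circle_arc_midline(r, arc_len=min(3.0, 1.4 * r))
    A = deflection_angle(arc)
    C, _ = curvature(arc.s, A)
    assert np.abs(np.abs(C) - 1 / r).max() * r < 0.01


def test_curvature_insufficient_samples_masked():
    C, A_s = curvature(np.arange(5) * 0.02, np.zeros(5))
    assert np.all(np.isnan(C))


def test_curvature_rate_constant_and_linear():
    t = np.arange(36) * 0.17
    const = np.tile(0.3, (36, 4))
    C_pred, dCdt, see = curvature_rate(t, const)
    assert np.abs(dCdt).max() < 1e-6
    assert np.all(see < 1e-8)
    lin = np.outer(0.05 * t - 0.2, np.ones(4))
    _, dCdt, _ = curvature_rate(t, lin)
    assert np.abs(dCdt - 0.05).max() < 1e-5


def test_see_ratio_masks_zero_curvature():
    t = np.arange(10) * 0.17
    s = np.arange(4) * 0.0199
    C = np.ones((10, 4))
    C[3, 2] = 0.0
    m = see_ratio_map(t, s, np.full(4, 0.1), C)
    assert not m.mask[3, 2]
    assert m.mask[0, 0]
    assert m.values[0, 0] == pytest.approx(-1.0)  # log10(0.1 / 1)


def test_constructed_gaussian_trough_traced():
    """A single valley t0(s) linear in s is recovered as one path."""
    t = np.arange(40) * 0.17
    s = np.arange(80) * 0.0199
    t0 = 1.0 + 1.5 * s
    vals = -np.exp(-((t[:, None] - t0[None, :]) / 0.5) ** 2)
    field = TSMap(t=t, s=s, values=vals)
    paths = detect_extremal_paths(field, "trough", min_extent=0.5)
    assert len(paths) == 1
    p = paths[0]
    assert np.abs(p.t - (1.0 + 1.5 * p.s)).max() < 0.17 + 1e-9


def test_alignment_on_exact_contour():
    t = np.arange(30) * 0.17
    s = np.arange(60) * 0.0199
    A = np.full((30, 60), 75.0)
    a_map = TSMap(t=t, s=s, values=A)
    from gravikine.kinematics import TroughPath
    p = TroughPath(t=t[5:25], s=s[5:25], values=-np.ones(20), polarity="trough")
    align_with_angle(p, a_map)
    assert p.aligned_angle == 75.0
    assert p.alignment_residual == pytest.approx(0.0, abs=1e-9)


def test_two_vertex_degenerate_path():
    t = np.arange(30) * 0.17
    s = np.arange(60) * 0.0199
    A = np.tile(np.linspace(60, 80, 60), (30, 1))
    a_map = TSMap(t=t, s=s, values=A)
    from gravikine.kinematics import TroughPath
    p = TroughPath(t=t[[3, 4]], s=s[[10, 40]], values=-np.ones(2),
                   polarity="trough")
    align_with_angle(p, a_map)
    a_vals = a_map.sample(p.t, p.s)
    assert p.aligned_angle == 5 * round(np.median(a_vals) / 5)
    expected = np.sqrt(np.mean((a_vals - p.aligned_angle) ** 2))
    assert p.alignment_residual == pytest.approx(expected, rel=1e-6)


def test_sine_law_simulation_has_single_trough_no_height(gp_traj):
    """With gamma=0 bending never reverses: one trough, no height paths."""
    from gravikine.simulate import GPParams, SimGrid, simulate_gp_rod
    traj = simulate_gp_rod(GPParams(beta=0.3, gamma=0.0, length=3.0),
                           SimGrid(t_end=3.0))
    # restrict to the period before the tip passes the vertical, after which
    # sin A < 0 legitimately reverses the bending response
    below = np.nonzero(traj.A[:, -1] < 0)[0]
    last = below[0] if len(below) else traj.n_frames
    _, dCdt, _ = curvature_rate(traj.times[:last], traj.C[:last])
    field = TSMap(t=traj.times[:last], s=traj.s, values=dCdt)
    troughs = detect_extremal_paths(field, "trough", min_extent=0.5)
    heights = detect_extremal_paths(field, "height", min_extent=0.5)
    assert len(troughs) >= 1
    assert len(heights) == 0


def test_gp_simulation_develops_height_after_trough(gp_traj):
    """Strong proprioception de-curves the organ: a positive dC/dt region."""
    _, dCdt, _ = curvature_rate(gp_traj.times, gp_traj.C)
    field = TSMap(t=gp_traj.times, s=gp_traj.s, values=dCdt)
    heights = detect_extremal_paths(field, "height", min_extent=0.3)
    assert len(heights) >= 1
    trough = detect_extremal_paths(field, "trough", min_extent=0.3)
    assert min(p.t.min() for p in trough) < min(p.t.min() for p in heights)


def test_mask_monotone_in_s(extracted):
    m = extracted["fields"]["C"].mask
    for row in m:
        valid = np.nonzero(row)[0]
        if len(valid):
            assert row[: valid[-1] + 1].all()


def test_fixture_curvature_accuracy(extracted, gp_traj):
    """Extracted C matches simulator ground truth: RMS < 5% of max |C|."""
    C = extracted["fields"]["C"]
    errs = []
    for i in range(4, len(C.t)):
        ok = C.mask[i] & (C.s > 0.5)
        truth = np.interp(C.s[ok], gp_traj.s, gp_traj.C[i])
        errs.append(np.sqrt(np.mean((C.values[i][ok] - truth) ** 2)))
    assert np.median(errs) < 0.05 * np.abs(gp_traj.C).max()


def test_fixture_curvature_rate_accuracy(extracted, gp_traj):
    """dC/dt matches ground truth away from early times and the basal zone."""
    d = extracted["fields"]["dCdt"]
    errs = []
    for i, t in enumerate(d.t):
        if t < 0.75:
            continue
        ok = d.mask[i] & (d.s > 0.5)
        truth = np.interp(d.s[ok], gp_traj.s, gp_traj.dCdt[i])
        errs.append(np.sqrt(np.mean((d.values[i][ok] - truth) ** 2)))
    assert np.median(errs) < 0.10 * np.abs(gp_traj.dCdt).max()


def test_reconstruction_integral_of_C_matches_smoothed_A(extracted):
    A, C = extracted["fields"]["A"], extracted["fields"]["C"]
    for i in range(len(A.t)):
        ok = A.mask[i] & C.mask[i]
        if ok.sum() < 3:
            continue
        s, a, c = A.s[ok], A.values[i][ok], C.values[i][ok]
        inc = np.concatenate([[0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(s))])
        assert np.abs(inc / DEG - (a - a[0])).max() < 0.5
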