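"""Midline recovery: binarization, contours, midpoints, principal curves."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from gravikine.midline import (MidlineError, MidpointCloud, binarize,
                               extract_contours, extract_midline,
                               fit_principal_curve, midpoints, resample_median)


def band_frame(shape=(128, 128), y0=64.0, half=8.0, amp=200.0, bg=20.0):
    """Horizontal bright band: analytic silhouette for binarize checks."""
    rows = np.arange(shape[0])[:, None] * np.ones(shape)[0]
    d = np.abs(np.arange(shape[0])[:, None] - y0) * np.ones((1, shape[1]))
    frac = np.clip(half - d + 0.5, 0, 1)
    return bg + (amp - bg) * frac


def test_binarize_area_matches_analytic_band():
    frame = band_frame()
    mask = binarize(frame)
    assert mask.sum() == pytest.approx(17 * 128, rel=0.05)


def test_binarize_blank_frame_errors():
    with pytest.raises(MidlineError, match="no foreground"):
        binarize(np.zeros((64, 64)))


def test_binarize_idempotent_on_mask():
    frame = band_frame()
    mask = binarize(frame)
    again = binarize(mask.astype(float) * 100 + 1)
    assert np.array_equal(mask, again)


def test_non_rodlike_mask_rejected():
    disk = np.zeros((64, 64))
    yy, xx = np.mgrid[:64, :64]
    disk[(yy - 32) ** 2 + (xx - 32) ** 2 < 20 ** 2] = 200.0
    mask = binarize(disk + 10)
    with pytest.raises(MidlineError, match="aspect"):
        extract_contours(mask, 0.016)


def test_midpoints_between_parallel_lines():
    y = np.linspace(0, 1, 50)
    side1 = np.column_stack([np.zeros(50), y])
    side2 = np.column_stack([np.full(50, 0.2), y])
    from gravikine.midline import ContourPair
    pair = ContourPair(side1=side1, side2=side2,
                       base_end=side1[0], tip_end=side1[-1])
    cloud = midpoints(pair, min_width_frac=0.0)
    assert np.abs(cloud.points[:, 0] - 0.1).max() < 1e-9
    assert np.abs(cloud.local_width - 0.2).max() < 1e-9


def test_midpoints_between_concentric_arcs():
    """Midpoints of arcs at radii r +/- w/2 fall on the radius-r arc."""
    r, w = 2.0, 0.25
    phi = np.linspace(0.1, 1.2, 80)
    inner = (r - w / 2) * np.column_stack([np.cos(phi), np.sin(phi)])
    outer = (r + w / 2) * np.column_stack([np.cos(phi), np.sin(phi)])
    from gravikine.midline import ContourPair
    pair = ContourPair(side1=inner, side2=outer,
                       base_end=inner[0], tip_end=inner[-1])
    cloud = midpoints(pair, min_width_frac=0.0)
    radii = np.linalg.norm(cloud.points, axis=1)
    interior = (np.arctan2(cloud.points[:, 1], cloud.points[:, 0]) > 0.15) & \
               (np.arctan2(cloud.points[:, 1], cloud.points[:, 0]) < 1.15)
    assert np.abs(radii[interior] - r).max() < 5e-3


def test_crossing_sides_rejected():
    from gravikine.midline import ContourPair
    a = np.array([[0.0, 0.0], [1.0, 1.0]])
    b = np.array([[0.0, 1.0], [1.0, 0.0]])
    pair = ContourPair(side1=a, side2=b, base_end=a[0], tip_end=a[-1])
    with pytest.raises(MidlineError, match="cross"):
        midpoints(pair)


def test_principal_curve_recovers_straight_segment():
    t = np.linspace(0, 3, 60)
    pts = np.column_stack([t, 0.5 * t])
    curve = fit_principal_curve(MidpointCloud(pts, np.full(60, 0.2)), df=5)
    _, d2, _ = __import__("gravikine.midline", fromlist=["project_onto_polyline"]
                          ).project_onto_polyline(curve.points, pts)
    assert np.sqrt(d2.max()) < 1e-6


def test_principal_curve_on_noisy_quadratic_arc():
    rng = np.random.default_rng(5)
    px = 0.016
    t = np.linspace(0, 3, 300)
    pts = np.column_stack([t, 0.15 * t ** 2])
    noisy = pts + rng.normal(0, 0.5 * px, pts.shape)
    curve = fit_principal_curve(MidpointCloud(noisy, np.full(300, 0.2)), df=10)
    from gravikine.midline import project_onto_polyline
    _, d2, _ = project_onto_polyline(curve.points, pts)
    assert np.sqrt(d2.mean()) < 0.5 * px


def test_resample_spacing_and_orientation():
    t = np.linspace(0, 2.5, 200)
    pts = np.column_stack([t, np.zeros_like(t)])
    cloud = MidpointCloud(pts, np.full(200, 0.25))
    curve = fit_principal_curve(cloud, df=5)
    mid = resample_median(curve, cloud, base_point=np.array([2.5, 0.0]))
    assert np.allclose(np.diff(mid.s), 0.0199, rtol=0.01)
    assert mid.s[0] == 0.0
    assert np.linalg.norm(mid.points[0] - [2.5, 0.0]) < 0.05  # base at anchor


@pytest.mark.parametrize("df", [10.0, 20.0])
def test_fixture_midline_accuracy_noiseless(rendered_clean, gp_traj, df):
    """End-to-end midline RMS error < 1 pixel on noiseless frames (df 10 & 20)."""
    px = rendered_clean.scale_mm
    k = 10
    anchor = rendered_clean.world_to_image(np.zeros(2))
    mid, pair, cloud = extract_midline(rendered_clean.bright[k], px,
                                       anchor=anchor, df=df)
    gt = rendered_clean.world_to_image(gp_traj.points[k])
    d, _ = cKDTree(gt).query(mid.points)
    assert np.sqrt((d ** 2).mean()) < px


def test_fixture_midline_accuracy_with_noise(rendered, gp_traj):
    """Midline RMS error < 2 pixels under the default noise model."""
    px = rendered.scale_mm
    anchor = rendered.world_to_image(np.zeros(2))
    for k in (0, 8, 20):
        mid, *_ = extract_midline(rendered.bright[k], px, anchor=anchor)
        gt = rendered.world_to_image(gp_traj.points[k])
        d, _ = cKDTree(gt).query(mid.points)
        assert np.sqrt((d ** 2).mean()) < 2 * px


def test_base_orientation_stable_across_series(extracted):
    """The base ends up at the clamped end in every frame of a series."""
    mids = extracted["midlines"]
    bases = np.array([m.points[0] for m in mids])
    spread = np.linalg.norm(bases - bases[0], axis=1)
    assert spread.max() < 0.2  # mm: base never jumps to the tip end
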