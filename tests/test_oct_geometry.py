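"""Geometric phenotype primitives against analytic surface sheets."""

import numpy as np
import pytest

from kerafam.oct.phenotype import PhenotypeConfig, irregularity_call
from kerafam.oct.surfaces import (
    DegenerateGeometryError,
    SurfaceError,
    SurfaceSheet,
    cct_and_acd,
    fit_sphere,
    meridional_curvature,
    pachymetry_map,
)


def sphere_sheet(radius_um, pitch=20.0, n=61, apex_z=100.0, label="anterior_cornea",
                 extra=None, center_xy=(0.0, 0.0)):
    g = (np.arange(n) - (n - 1) / 2) * pitch
    xx, yy = np.meshgrid(g, g)
    cz = apex_z + radius_um
    z = cz - np.sqrt(radius_um**2 - (xx - center_xy[0]) ** 2 - (yy - center_xy[1]) ** 2)
    if extra is not None:
        z = z + extra(xx, yy)
    return SurfaceSheet(z=z, mask=np.ones_like(z, bool), label=label,
                        lateral_pitch=pitch, frame_pitch=pitch)


# ---------------------------------------------------------------------------
# Pachymetry
# ---------------------------------------------------------------------------


def test_pachymetry_of_offset_surface_is_the_offset_exactly():
    ant = sphere_sheet(1500.0)
    post = SurfaceSheet(z=ant.z + 50.0, mask=ant.mask.copy(),
                        label="posterior_cornea",
                        lateral_pitch=ant.lateral_pitch, frame_pitch=ant.frame_pitch)
    thickness = pachymetry_map(ant, post)
    assert np.allclose(thickness.compressed(), 50.0, atol=1e-9)


def test_pachymetry_concentric_spheres_matches_closed_form():
    ant = sphere_sheet(1500.0)
    post = sphere_sheet(1450.0, apex_z=150.0, label="posterior_cornea")
    thickness = pachymetry_map(ant, post)
    n = ant.z.shape[0]
    center = (n - 1) // 2
    assert thickness[center, center] == pytest.approx(50.0, abs=1e-9)
    # closed form at 500 um lateral offset (grid pitch divides 500)
    col = center + int(500 / ant.lateral_pitch)
    expected = np.sqrt(1500.0**2 - 500.0**2) - np.sqrt(1450.0**2 - 500.0**2)
    assert thickness[center, col] == pytest.approx(expected, abs=1e-9)


def test_pachymetry_masks_propagate_and_grids_must_match():
    ant = sphere_sheet(1500.0)
    post = sphere_sheet(1450.0, apex_z=150.0)
    post.mask[:, 3] = False
    thickness = pachymetry_map(ant, post)
    assert thickness.mask[:, 3].all()
    mismatched = sphere_sheet(1450.0, pitch=10.0)
    with pytest.raises(SurfaceError, match="different grids"):
        pachymetry_map(ant, mismatched)


# ---------------------------------------------------------------------------
# CCT / ACD
# ---------------------------------------------------------------------------


def test_cct_and_acd_concentric_phantom():
    ant = sphere_sheet(1500.0)
    post = sphere_sheet(1450.0, apex_z=150.0, label="posterior_cornea")
    lens = sphere_sheet(1400.0, apex_z=450.0, label="anterior_lens")
    cct, acd = cct_and_acd(ant, post, lens)
    assert cct == pytest.approx(50.0, abs=1e-6)
    assert acd == pytest.approx(300.0, abs=1e-6)


def test_acd_is_missing_not_zero_without_lens():
    ant = sphere_sheet(1500.0)
    post = sphere_sheet(1450.0, apex_z=150.0)
    cct, acd = cct_and_acd(ant, post, None)
    assert cct == pytest.approx(50.0, abs=1e-6)
    assert acd is None


def test_apex_found_off_center_on_tilted_sheet():
    # shifting the sphere center moves the apex; CCT stays the apex thickness
    ant = sphere_sheet(1500.0, center_xy=(80.0, -40.0))
    post = sphere_sheet(1450.0, apex_z=150.0, center_xy=(80.0, -40.0))
    iy, ix = ant.apex()
    x, y = ant.x_coords()[ix], ant.y_coords()[iy]
    assert abs(x - 80.0) <= ant.lateral_pitch and abs(y + 40.0) <= ant.frame_pitch
    cct, _ = cct_and_acd(ant, post)
    assert cct == pytest.approx(50.0, abs=0.5)


# ---------------------------------------------------------------------------
# Sphere fitting
# ---------------------------------------------------------------------------


def test_fit_sphere_exact_recovery():
    sheet = sphere_sheet(1450.0)
    fit = fit_sphere(sheet)
    assert abs(fit.radius_um - 1450.0) < 0.1
    assert fit.rms_um < 1e-6
    assert fit.radius_mm == pytest.approx(1.45)


def test_fit_sphere_noisy_recovery_band(rng):
    """|R_hat - R| < 5 um with sigma = 2 um height noise, over 100 seeds."""
    base = sphere_sheet(1450.0)
    worst = 0.0
    for _ in range(100):
        noisy = SurfaceSheet(
            z=base.z + rng.normal(0, 2.0, base.z.shape),
            mask=base.mask.copy(), label=base.label,
            lateral_pitch=base.lateral_pitch, frame_pitch=base.frame_pitch,
        )
        worst = max(worst, abs(fit_sphere(noisy).radius_um - 1450.0))
    assert worst < 5.0


def test_fit_sphere_degenerate_inputs():
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(DegenerateGeometryError):
        fit_sphere(line)
    with pytest.raises(DegenerateGeometryError):
        fit_sphere(np.zeros((3, 3)))
    plane = np.array([[0, 0, 5], [1, 0, 5], [0, 1, 5], [1, 1, 5]], float)
    with pytest.raises(DegenerateGeometryError):
        fit_sphere(plane)


def test_fit_sphere_translation_equivariance():
    sheet = sphere_sheet(1500.0)
    pts = sheet.points()
    shift = np.array([123.0, -45.0, 67.0])
    a = fit_sphere(pts)
    b = fit_sphere(pts + shift)
    assert np.allclose(np.array(b.center_um) - np.array(a.center_um), shift, atol=1e-6)
    assert b.radius_um == pytest.approx(a.radius_um, abs=1e-6)


# ---------------------------------------------------------------------------
# Meridional curvature
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("radius_um", [1200.0, 1500.0, 1800.0])
@pytest.mark.parametrize("pitch", [10.0, 20.0, 40.0])
def test_sphere_curvature_constant_to_one_percent(radius_um, pitch):
    n = int(round(1200.0 / pitch)) + 1
    sheet = sphere_sheet(radius_um, pitch=pitch, n=n)
    cm = meridional_curvature(sheet)
    radii = cm.radii_mm[np.isfinite(cm.radii_mm)]
    assert radii.size > 0
    assert np.abs(radii - radius_um / 1000.0).max() / (radius_um / 1000.0) < 0.01


def test_paraboloid_curvature_closed_form():
    r0 = 1400.0
    pitch, n = 20.0, 61
    g = (np.arange(n) - (n - 1) / 2) * pitch
    xx, yy = np.meshgrid(g, g)
    z = 100.0 + (xx**2 + yy**2) / (2 * r0)
    sheet = SurfaceSheet(z=z, mask=np.ones_like(z, bool), label="anterior_cornea",
                         lateral_pitch=pitch, frame_pitch=pitch)
    cm = meridional_curvature(sheet, zone_radius_um=520.0)
    apex_col = np.argmin(np.abs(cm.r_um))
    assert np.nanmean(cm.radii_mm[:, apex_col]) == pytest.approx(1.4, rel=0.01)
    col = np.argmin(np.abs(cm.r_um - 500.0))
    r = cm.r_um[col]
    expected = (1 + (r / r0) ** 2) ** 1.5 * r0 / 1000.0
    assert np.nanmean(cm.radii_mm[:, col]) == pytest.approx(expected, rel=0.01)


def test_bump_curvature_perturbation_is_localized():
    bump_center = (100.0, -60.0)

    def bump(xx, yy):
        d2 = (xx - bump_center[0]) ** 2 + (yy - bump_center[1]) ** 2
        return -15.0 * np.exp(-d2 / (2 * 80.0**2))

    sheet = sphere_sheet(1500.0, extra=bump)
    cm = meridional_curvature(sheet, zone_radius_um=260.0)
    curvature = 1.0 / cm.radii_mm  # 1/mm; deviation is cleanest in curvature
    deviation = np.abs(curvature - 1.0 / 1.5)
    j, i = np.unravel_index(np.nanargmax(deviation), deviation.shape)
    x = cm.apex_xy_um[0] + cm.r_um[i] * np.cos(cm.angles_rad[j])
    y = cm.apex_xy_um[1] + cm.r_um[i] * np.sin(cm.angles_rad[j])
    dist = np.hypot(x - bump_center[0], y - bump_center[1])
    assert dist <= 1.5 * sheet.lateral_pitch


def test_zone_exceeding_data_warns_and_masks():
    sheet = sphere_sheet(1500.0, n=21)  # half-width 200 um
    with pytest.warns(UserWarning, match="exceeds the mapped area"):
        cm = meridional_curvature(sheet, zone_radius_um=400.0)
    assert np.isnan(cm.radii_mm).any()


# ---------------------------------------------------------------------------
# Irregularity
# ---------------------------------------------------------------------------


def test_irregularity_score_near_zero_on_perfect_sphere():
    res = irregularity_call(sphere_sheet(1500.0))
    assert res.score_um < 0.1
    assert not res.irregular


def test_irregularity_flags_bump_under_noise(rng):
    def bump(xx, yy):
        return -20.0 * np.exp(-(xx**2 + yy**2) / (2 * 100.0**2))

    base = sphere_sheet(1500.0, extra=bump)
    noisy = SurfaceSheet(z=base.z + rng.normal(0, 2.0, base.z.shape),
                         mask=base.mask.copy(), label=base.label,
                         lateral_pitch=base.lateral_pitch,
                         frame_pitch=base.frame_pitch)
    res = irregularity_call(noisy)
    assert res.irregular
    assert res.score_um > res.threshold_um


def test_irregularity_threshold_tracks_noise_floor():
    cfg = PhenotypeConfig(noise_floor_um=2.0, irregularity_k=3.0)
    assert cfg.irregularity_threshold_um == 6.0
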