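import math

import numpy as np
import pytest

from cxlsim.metrics import (
    BiconicFitError,
    ConeDetectionError,
    detect_cone,
    fit_biconic,
    kmax_metrics,
    min_pachymetry,
    tangential_curvature,
)
from cxlsim.synthetic import CorneaSpec, TopographyGrid, generate_cornea


def sphere_points(radius, half_width=3.0, n=61, scale=1.0):
    x = np.linspace(-half_width, half_width, n)
    xx, yy = np.meshgrid(x, x)
    zz = radius - np.sqrt(radius**2 - xx**2 - yy**2)
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return pts * scale


class TestTangentialCurvature:
    @pytest.mark.parametrize("radius,expected", [(7.5, 45.0), (6.75, 50.0)])
    def test_exact_sphere(self, radius, expected):
        cm = tangential_curvature(sphere_points(radius))
        assert np.nanmax(np.abs(cm.k_tg - expected)) < 0.02

    def test_scale_law(self):
        # scaling all coordinates by s multiplies K_tg by 1/s
        base = tangential_curvature(sphere_points(7.5)).k_tg
        for s in (0.9, 1.1):
            scaled = tangential_curvature(sphere_points(7.5, scale=s)).k_tg
            np.testing.assert_allclose(scaled, base / s, rtol=1e-3)

    def test_invalid_points_rejected(self):
        with pytest.raises(ValueError):
            tangential_curvature(np.zeros((5, 2)))


class TestKmaxMetrics:
    def test_constant_map(self):
        cm = tangential_curvature(sphere_points(7.5))
        kmax, loc, km3 = kmax_metrics(cm)
        assert abs(kmax - 45.0) < 0.02
        assert abs(km3 - 45.0) < 0.02

    def test_kmaxmean3_le_kmax(self, kc_grid):
        cm = tangential_curvature(kc_grid.anterior_points())
        kmax, _, km3 = kmax_metrics(cm)
        assert km3 <= kmax

    def test_planted_bump_location(self):
        spec = CorneaSpec(cone_center=(1.0, 0.5), noise_sd=0.0)
        g = generate_cornea(spec)
        cm = tangential_curvature(g.anterior_points())
        _, loc, _ = kmax_metrics(cm)
        assert abs(loc[0] - 1.0) <= spec.grid_spacing + 1e-9
        assert abs(loc[1] - 0.5) <= spec.grid_spacing + 1e-9


class TestBiconicFit:
    def test_exact_recovery(self):
        spec = CorneaSpec(r_flat=7.7, r_steep=7.3, q_flat=-0.2, q_steep=-0.2,
                          axis_flat=0.0, cone_amplitude=0.0)
        fit = fit_biconic(generate_cornea(spec).anterior_points())
        assert abs(fit.r_flat - 7.7) < 1e-3
        assert abs(fit.r_steep - 7.3) < 1e-3
        assert min(fit.axis, 180 - fit.axis) < 0.1
        assert fit.rms_residual < 1.0

    def test_exact_sphere_degenerate(self):
        fit = fit_biconic(sphere_points(7.7, half_width=4.2, n=85))
        assert abs(fit.r_flat - 7.7) < 1e-3
        assert abs(fit.r_steep - 7.7) < 1e-3
        assert abs(fit.cylinder) < 5e-3

    def test_sphere_index_matches_population(self):
        # R_flat = 7.7 mm -> sphere = (1.376-1)/(1e-3*7.7) = 48.8 D, inside
        # the reported population band 48.9 +/- 3.4 D
        spec = CorneaSpec(cone_amplitude=0.0)
        fit = fit_biconic(generate_cornea(spec).anterior_points())
        assert abs(fit.sphere - (1.376 - 1.0) / (1e-3 * 7.7)) < 0.05
        assert 48.9 - 3.4 < fit.sphere < 48.9 + 3.4

    def test_rotation_invariance(self):
        base = fit_biconic(generate_cornea(
            CorneaSpec(cone_amplitude=0.0, axis_flat=0.0)).anterior_points())
        rot = fit_biconic(generate_cornea(
            CorneaSpec(cone_amplitude=0.0, axis_flat=30.0)).anterior_points())
        assert abs(rot.axis - 30.0) < 0.1
        assert abs(rot.r_flat - base.r_flat) / base.r_flat < 5e-4
        assert abs(rot.r_steep - base.r_steep) / base.r_steep < 5e-4

    def test_derived_indices_consistent(self):
        fit = fit_biconic(generate_cornea(CorneaSpec()).anterior_points())
        assert fit.cylinder >= 0
        assert fit.sphere <= fit.spherical_equivalent <= fit.k_steep
        assert abs(fit.spherical_equivalent - (fit.sphere + fit.cylinder / 2)) < 1e-12

    def test_noise_robust_recovery(self):
        # |dR| < 0.02 mm under 5 µm elevation noise (generator oracle)
        for seed in range(50):
            spec = CorneaSpec(cone_amplitude=0.0, noise_sd=5.0, seed=seed)
            fit = fit_biconic(generate_cornea(spec).anterior_points())
            assert abs(fit.r_flat - 7.7) < 0.02
            assert abs(fit.r_steep - 7.3) < 0.02

    def test_not_enough_points(self):
        with pytest.raises(BiconicFitError):
            fit_biconic(np.random.default_rng(0).normal(size=(6, 3)))


class TestMinPachymetry:
    def make_uniform(self, value=500.0):
        x = np.linspace(-5, 5, 101)
        xx, yy = np.meshgrid(x, x)
        ant = np.where(np.hypot(xx, yy) <= 5, 0.1 * (xx**2 + yy**2) / 15.4, np.nan)
        return TopographyGrid(x=x, y=x, anterior=ant, posterior=ant + value / 1000.0,
                              spacing=0.1, diameter=10.0)

    def test_uniform(self):
        v, _ = min_pachymetry(self.make_uniform(500.0))
        assert abs(v - 500.0) < 1e-9

    def test_tie_break_smallest_radius(self):
        _, loc = min_pachymetry(self.make_uniform())
        assert loc == (0.0, 0.0)

    def test_planted_thinning(self):
        g = generate_cornea(CorneaSpec(cone_thinning=85.0, central_thickness=545.0))
        v, loc = min_pachymetry(g)
        assert abs(v - 460.0) < 0.5
        assert abs(loc[0] - 0.8) <= 0.1 + 1e-9
        assert abs(loc[1] + 0.6) <= 0.1 + 1e-9


class TestDetectCone:
    def test_member_fraction(self, kc_grid):
        cm = tangential_curvature(kc_grid.anterior_points())
        cone = detect_cone(cm)
        central = cm.valid & (cm.lateral_radius() <= 4.0)
        frac = len(cone.member_idx) / central.sum()
        assert abs(frac - 0.325) < 1.0 / central.sum() + 1e-3

    def test_planted_center(self):
        spec = CorneaSpec(cone_center=(1.0, 0.5))
        g = generate_cornea(spec)
        cone = detect_cone(tangential_curvature(g.anterior_points()))
        assert abs(cone.center[0] - 1.0) <= spec.grid_spacing + 1e-9
        assert abs(cone.center[1] - 0.5) <= spec.grid_spacing + 1e-9

    def test_constant_map_raises(self):
        # an exactly constant field has no strict percentile exceedance
        pts = sphere_points(7.5, half_width=4.2, n=85)
        from cxlsim.metrics import CurvatureMap
        n = len(pts)
        cm = CurvatureMap(points=pts, k_tg=np.full(n, 45.0),
                          radius=np.full(n, 7.5), valid=np.ones(n, bool))
        with pytest.raises(ConeDetectionError):
            detect_cone(cm)

    def test_boundary_distance_normalized(self, kc_grid):
        cone = detect_cone(tangential_curvature(kc_grid.anterior_points()))
        assert (cone.boundary_distance >= 0).all()
        assert (cone.boundary_distance <= 1).all()
        assert cone.normalized_distance(np.array([cone.center])) == pytest.approx(0.0)
        far = np.array([[cone.center[0] + 5.0, cone.center[1]]])
        assert cone.normalized_distance(far)[0] == pytest.approx(1.0)

    def test_members_inside_region(self, kc_grid):
        cm = tangential_curvature(kc_grid.anterior_points())
        cone = detect_cone(cm)
        r = np.hypot(cone.member_points[:, 0], cone.member_points[:, 1])
        assert (r <= 4.0 + 1e-9).all()
        assert (cm.k_tg[cone.member_idx] > cone.threshold).all()
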