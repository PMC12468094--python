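import math
import warnings

import numpy as np
import pytest

from cxlsim.fields import CXLProtocol, cxl_field, radial_sigma, weakening_field
from cxlsim.metrics import detect_cone, tangential_curvature
from cxlsim.synthetic import CorneaSpec, generate_cornea


@pytest.fixture(scope="module")
def cone():
    g = generate_cornea(CorneaSpec())
    return detect_cone(tangential_curvature(g.anterior_points()))


def at(field, x, y, depth_um=0.0):
    return float(field.at(np.array([[x, y]]), np.array([depth_um]))[0])


class TestWeakeningField:
    def test_center_reduction_57_percent(self, cone):
        f = weakening_field(cone, 0.429)
        m = at(f, *cone.center)
        assert (1.0 - m) * 100 == pytest.approx(57.1, abs=0.2)

    def test_linear_ramp_midpoint(self, cone):
        f = weakening_field(cone, 0.429)
        # multiplier at normalized distance 0.5 equals (0.429 + 1)/2
        angles = np.linspace(0, 2 * math.pi, 12, endpoint=False)
        edge = np.interp(angles, cone.edge_angles, cone.edge_radii, period=2 * math.pi)
        xy = np.column_stack([cone.center[0] + 0.5 * edge * np.cos(angles),
                              cone.center[1] + 0.5 * edge * np.sin(angles)])
        vals = f.at(xy, np.zeros(len(xy)))
        np.testing.assert_allclose(vals, 0.7145, atol=1e-6)

    def test_identity_for_alpha_one(self, cone):
        f = weakening_field(cone, 1.0)
        xy = np.random.default_rng(0).uniform(-4, 4, (50, 2))
        np.testing.assert_allclose(f.at(xy, np.zeros(50)), 1.0)

    def test_outside_cone_is_one(self, cone):
        f = weakening_field(cone, 0.429)
        assert at(f, cone.center[0] + 5.0, cone.center[1]) == pytest.approx(1.0)

    def test_constant_through_depth(self, cone):
        f = weakening_field(cone, 0.429)
        assert at(f, *cone.center, depth_um=0.0) == at(f, *cone.center, depth_um=400.0)

    def test_bounds(self, cone):
        f = weakening_field(cone, 0.429)
        xy = np.random.default_rng(1).uniform(-5, 5, (300, 2))
        vals = f.at(xy, np.zeros(300))
        assert (vals >= 0.429 - 1e-12).all() and (vals <= 1.0 + 1e-12).all()

    def test_empty_cone_warns_identity(self):
        with pytest.warns(UserWarning):
            f = weakening_field(None, 0.429)
        assert at(f, 0.0, 0.0) == 1.0

    def test_alpha_range(self, cone):
        with pytest.raises(ValueError):
            weakening_field(cone, 0.0)


class TestCXLField:
    def test_peak_multiplier(self):
        f = cxl_field(CXLProtocol.make("standard"))
        assert at(f, 0, 0) == pytest.approx(16.3)

    def test_radial_weight_at_90_percent(self):
        # weight 0.10 at 0.9 * 4.5 mm -> multiplier 1 + 15.3 * 0.10
        f = cxl_field(CXLProtocol.make("standard"))
        assert at(f, 0.9 * 4.5, 0.0) == pytest.approx(1.0 + 15.3 * 0.10, rel=1e-12)

    def test_unity_at_depth_cutoff(self):
        f = cxl_field(CXLProtocol.make("standard"))
        for r in (0.0, 1.0, 3.0):
            assert at(f, r, 0.0, depth_um=300.0) == pytest.approx(1.0)
            assert at(f, r, 0.0, depth_um=450.0) == pytest.approx(1.0)

    def test_elza_peak(self):
        f = cxl_field(CXLProtocol.make("custom_elza", cone_center=(0.0, 0.0)))
        assert at(f, 0, 0) == pytest.approx(1.33 * 16.3)

    def test_elza_deeper_central_zone(self):
        f = cxl_field(CXLProtocol.make("custom_elza", cone_center=(0.0, 0.0)))
        assert at(f, 0, 0, depth_um=350.0) > 1.0  # still active below 300 µm
        assert at(f, 0, 0, depth_um=400.0) == pytest.approx(1.0)

    def test_elza_dominates_standard(self):
        std = cxl_field(CXLProtocol.make("standard"))
        elza = cxl_field(CXLProtocol.make("custom_elza", cone_center=(0.0, 0.0)))
        rng = np.random.default_rng(2)
        xy = rng.uniform(-4.5, 4.5, (200, 2))
        depths = rng.uniform(0, 500, 200)
        assert (elza.at(xy, depths) >= std.at(xy, depths) - 1e-12).all()

    def test_monotone_in_r_and_depth(self):
        f = cxl_field(CXLProtocol.make("standard"))
        rs = np.linspace(0, 4.5, 40)
        vals_r = f.at(np.column_stack([rs, np.zeros_like(rs)]), np.zeros_like(rs))
        assert (np.diff(vals_r) <= 1e-12).all()
        ds = np.linspace(0, 300, 40)
        vals_d = f.at(np.tile([[1.0, 0.0]], (40, 1)), ds)
        assert (np.diff(vals_d) <= 1e-12).all()

    def test_multiplier_at_least_one(self):
        f = cxl_field(CXLProtocol.make("custom_standard", cone_center=(1.0, -0.5)))
        rng = np.random.default_rng(3)
        xy = rng.uniform(-5, 5, (300, 2))
        assert (f.at(xy, rng.uniform(0, 600, 300)) >= 1.0 - 1e-12).all()

    def test_no_treatment_identity(self):
        f = cxl_field(CXLProtocol(name="standard", k_cxl=1.0))
        xy = np.random.default_rng(4).uniform(-4, 4, (100, 2))
        np.testing.assert_allclose(f.at(xy, np.zeros(100)), 1.0)

    def test_continuity_at_test_resolution(self):
        # adjacent-sample jumps stay below 5% of the field's dynamic range
        # (0.1 mm laterally, 10 µm in depth)
        f = cxl_field(CXLProtocol.make("custom_elza", cone_center=(0.8, -0.6)))
        span = 1.33 * 16.3 - 1.0
        xs = np.arange(-4.4, 4.4, 0.1)
        for depth in (0.0, 150.0, 350.0):
            vals = f.at(np.column_stack([xs, np.zeros_like(xs)]),
                        np.full(len(xs), depth))
            assert np.abs(np.diff(vals)).max() < 0.05 * span
        ds = np.arange(0.0, 450.0, 10.0)
        vals = f.at(np.tile([[0.8, -0.6]], (len(ds), 1)), ds)
        assert np.abs(np.diff(vals)).max() < 0.05 * span

    def test_gaussian_sigma_closed_form(self):
        sigma = radial_sigma(4.5)
        assert math.exp(-((0.9 * 4.5) ** 2) / (2 * sigma**2)) == pytest.approx(0.10)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            CXLProtocol(name="bogus")
        with pytest.raises(ValueError):
            CXLProtocol(name="standard", k_cxl=0.5)
        with pytest.raises(ValueError):
            CXLProtocol.make("custom_elza")  # cone center required
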