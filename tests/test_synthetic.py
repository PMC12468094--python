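import numpy as np
import pytest

from cxlsim.metrics import fit_biconic, min_pachymetry, tangential_curvature
from cxlsim.synthetic import (
    CorneaSpec,
    GridParseError,
    analytic_curvature,
    generate_cornea,
    read_grid,
    write_grid,
)


class TestSpecValidation:
    @pytest.mark.parametrize("kw,field", [
        (dict(r_steep=7.9, r_flat=7.7), "r_steep"),
        (dict(grid_diameter=8.0), "grid_diameter"),
        (dict(cone_thinning=600.0), "cone_thinning"),
        (dict(cone_amplitude=-0.01), "cone_amplitude"),
        (dict(noise_sd=-1.0), "noise_sd"),
        (dict(axis_flat=180.0), "axis_flat"),
    ])
    def test_invariant_violation_names_field(self, kw, field):
        with pytest.raises(ValueError, match=field):
            CorneaSpec(**kw)


class TestGenerate:
    def test_biconic_roundtrip_recovery(self):
        spec = CorneaSpec(r_flat=7.7, r_steep=7.3, cone_amplitude=0.0, noise_sd=0.0)
        fit = fit_biconic(generate_cornea(spec).anterior_points())
        assert abs(fit.r_flat - 7.7) < 1e-3
        assert abs(fit.r_steep - 7.3) < 1e-3

    def test_seeded_determinism(self):
        spec = CorneaSpec(noise_sd=5.0, seed=42)
        g1 = generate_cornea(spec)
        g2 = generate_cornea(spec)
        np.testing.assert_array_equal(g1.anterior, g2.anterior)
        np.testing.assert_array_equal(g1.posterior, g2.posterior)

    def test_kmax_increases_with_cone_amplitude(self):
        # oracle: dense analytic curvature of the generating surface
        x = np.linspace(-3, 3, 301)
        xx, yy = np.meshgrid(x, x)
        kmaxes = []
        for amp in (0.0, 0.02):
            spec = CorneaSpec(cone_amplitude=amp, noise_sd=0.0)
            kmaxes.append(np.nanmax(analytic_curvature(xx, yy, spec)))
        assert kmaxes[1] > kmaxes[0]

    def test_estimator_kmax_monotone_in_amplitude(self):
        vals = []
        for amp in (0.0, 0.01, 0.02):
            g = generate_cornea(CorneaSpec(cone_amplitude=amp, noise_sd=0.0))
            cm = tangential_curvature(g.anterior_points())
            vals.append(np.nanmax(cm.k_tg))
        assert vals[0] < vals[1] < vals[2]

    def test_min_pachymetry_decreasing_in_thinning(self):
        mins = []
        for thin in (0.0, 40.0, 85.0):
            g = generate_cornea(CorneaSpec(cone_thinning=thin, noise_sd=0.0))
            mins.append(min_pachymetry(g)[0])
        assert mins[0] > mins[1] > mins[2]
        assert abs(mins[1] - (545.0 - 40.0)) < 0.5

    def test_pachymetry_positive_and_mask_radial(self, kc_grid):
        kc_grid.validate()
        m = kc_grid.mask
        r = np.hypot(kc_grid.xx, kc_grid.yy)
        assert (m == (r <= kc_grid.diameter / 2 + 1e-9)).all()

    def test_curvature_matches_analytic_oracle(self, kc_spec, kc_grid):
        pts = kc_grid.anterior_points()
        cm = tangential_curvature(pts)
        oracle = analytic_curvature(pts[:, 0], pts[:, 1], kc_spec)
        interior = np.hypot(pts[:, 0], pts[:, 1]) < 4.5
        err = np.abs(cm.k_tg[interior] - oracle[interior])
        assert np.nanmax(err) < 0.1


class TestFileDialect:
    def test_roundtrip_identity(self, tmp_path, kc_grid):
        path = tmp_path / "c.csv"
        write_grid(kc_grid, path)
        back = read_grid(path)
        m = kc_grid.mask
        assert (back.mask == m).all()
        np.testing.assert_allclose(back.anterior[m], np.round(kc_grid.anterior[m], 6))
        np.testing.assert_allclose(back.posterior[m], np.round(kc_grid.posterior[m], 6))
        assert back.spacing == kc_grid.spacing
        assert back.diameter == kc_grid.diameter

    def test_missing_header_is_parse_error(self, tmp_path, kc_grid):
        path = tmp_path / "c.csv"
        write_grid(kc_grid, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(ln for ln in lines if "spacing" not in ln) + "\n")
        with pytest.raises(GridParseError, match="spacing_mm"):
            read_grid(path)

    def test_garbled_header_reports_line(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("# spacing_mm=0.1\n# bad header junk !!\n")
        with pytest.raises(GridParseError, match="line 2"):
            read_grid(path)

    def test_non_rectangular_grid_rejected(self, tmp_path, kc_grid):
        path = tmp_path / "c.csv"
        write_grid(kc_grid, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one data row
        with pytest.raises(GridParseError, match="rectangular"):
            read_grid(path)

    def test_unit_mismatch_rejected(self, tmp_path, kc_grid):
        path = tmp_path / "c.csv"
        write_grid(kc_grid, path)
        path.write_text(path.read_text().replace("units=mm", "units=um"))
        with pytest.raises(GridParseError, match="unit"):
            read_grid(path)

    def test_roundtrip_random_specs(self, tmp_path):
        rng = np.random.default_rng(7)
        for i in range(100):
            spec = CorneaSpec(
                r_flat=float(rng.uniform(7.5, 8.2)),
                r_steep=float(rng.uniform(6.9, 7.5)),
                axis_flat=float(rng.uniform(0, 179.9)),
                cone_center=(float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1))),
                cone_amplitude=float(rng.uniform(0, 0.03)),
                cone_sigma=float(rng.uniform(0.6, 1.4)),
                cone_thinning=float(rng.uniform(0, 100)),
                grid_spacing=0.35,
                grid_diameter=9.1,
                noise_sd=float(rng.uniform(0, 8)),
                seed=i,
            )
            g = generate_cornea(spec)
            path = tmp_path / f"r{i}.csv"
            write_grid(g, path)
            back = read_grid(path)
            m = g.mask
            assert (back.mask == m).all()
            np.testing.assert_allclose(back.anterior[m], np.round(g.anterior[m], 6))
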