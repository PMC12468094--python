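"""Synthetic keratoconic corneal topographies with known ground truth.

Surfaces are stored as sag maps: right-handed frame with the origin at the
anterior apex and z increasing posteriorly (x, y, z in mm).  The anterior
surface is a rotated biconic with an optional localized cone (a Gaussian
protrusion toward the anterior, i.e. subtracted from the sag), the posterior
surface follows at a laterally varying thickness.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CorneaSpec",
    "TopographyGrid",
    "generate_cornea",
    "write_grid",
    "read_grid",
    "biconic_sag",
    "anterior_sag",
    "analytic_curvature",
    "GridParseError",
]


class GridParseError(ValueError):
    """Raised when a topography file does not conform to the CSV dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class CorneaSpec:
    """Parameters of a synthetic (keratoconic) cornea.

    Radii/sag in mm, thicknesses in µm, angles in degrees.
    """

    r_flat: float = 7.7
    r_steep: float = 7.3
    axis_flat: float = 0.0
    q_flat: float = -0.2
    q_steep: float = -0.2
    cone_center: tuple[float, float] = (0.8, -0.6)
    cone_amplitude: float = 0.018
    cone_sigma: float = 1.0
    central_thickness: float = 545.0
    cone_thinning: float = 85.0
    grid_spacing: float = 0.1
    grid_diameter: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.r_steep <= self.r_flat:
            raise ValueError("r_steep must be <= r_flat")
        if self.r_steep <= 0:
            raise ValueError("r_steep must be positive")
        if not 0.0 <= self.axis_flat < 180.0:
            raise ValueError("axis_flat must lie in [0, 180)")
        if self.grid_diameter < 9.0:
            raise ValueError("grid_diameter must be >= 9 mm to cover the treatment zone")
        if self.cone_thinning >= self.central_thickness:
            raise ValueError("cone_thinning must be < central_thickness")
        if self.cone_amplitude < 0:
            raise ValueError("cone_amplitude must be >= 0")
        if self.cone_sigma <= 0:
            raise ValueError("cone_sigma must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_(self, **kw) -> "CorneaSpec":
        return replace(self, **kw)


@dataclass
class TopographyGrid:
    """Regular lateral grid of anterior/posterior elevation (sag, mm).

    ``anterior``/``posterior`` are indexed ``[iy, ix]``; invalid points
    (outside ``diameter``) are NaN.  Pachymetry (µm) is derived along z.
    """

    x: np.ndarray
    y: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    spacing: float
    diameter: float

    @property
    def xx(self) -> np.ndarray:
        return np.meshgrid(self.x, self.y)[0]

    @property
    def yy(self) -> np.ndarray:
        return np.meshgrid(self.x, self.y)[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask (True where the grid carries data)."""
        return np.isfinite(self.anterior) & np.isfinite(self.posterior)

    @property
    def pachymetry(self) -> np.ndarray:
        """Corneal thickness along z, µm."""
        return (self.posterior - self.anterior) * 1000.0

    def anterior_points(self) -> np.ndarray:
        """Valid anterior surface points as an (n, 3) array."""
        m = self.mask
        return np.column_stack([self.xx[m], self.yy[m], self.anterior[m]])

    def posterior_points(self) -> np.ndarray:
        m = self.mask
        return np.column_stack([self.xx[m], self.yy[m], self.posterior[m]])

    def validate(self) -> None:
        m = self.mask
        if not m.any():
            raise ValueError("grid has no valid points")
        pach = self.pachymetry[m]
        if not (pach > 0).all():
            raise ValueError("pachymetry must be positive at all valid points")


def _rotate_xy(x, y, angle_deg):
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return c * x + s * y, -s * x + c * y


def biconic_sag(x, y, rx, ry, qx, qy):
    """Sag of a biconic surface with principal meridians along x and y.

    z = (x^2/rx + y^2/ry) / (1 + sqrt(1 - (1+qx) x^2/rx^2 - (1+qy) y^2/ry^2))
    """
    p = x * x / rx + y * y / ry
    s = (1.0 + qx) * x * x / rx**2 + (1.0 + qy) * y * y / ry**2
    root = np.sqrt(np.clip(1.0 - s, 0.0, None))
    with np.errstate(invalid="ignore"):
        z = p / (1.0 + root)
    return np.where(s < 1.0, z, np.nan)


def _biconic_derivs(x, y, rx, ry, qx, qy):
    """Sag and its first/second derivatives (closed form)."""
    ax, ay = 1.0 / rx, 1.0 / ry
    bx, by = (1.0 + qx) / rx**2, (1.0 + qy) / ry**2
    p = ax * x * x + ay * y * y
    s = bx * x * x + by * y * y
    w = np.sqrt(1.0 - s)
    d = 1.0 + w
    px, py = 2.0 * ax * x, 2.0 * ay * y
    pxx, pyy = 2.0 * ax, 2.0 * ay
    sx, sy = 2.0 * bx * x, 2.0 * by * y
    sxx, syy = 2.0 * bx, 2.0 * by
    wx = -sx / (2.0 * w)
    wy = -sy / (2.0 * w)
    wxx = -sxx / (2.0 * w) - sx * sx / (4.0 * w**3)
    wyy = -syy / (2.0 * w) - sy * sy / (4.0 * w**3)
    wxy = -sx * sy / (4.0 * w**3)
    z = p / d
    zx = px / d - p * wx / d**2
    zy = py / d - p * wy / d**2
    zxx = pxx / d - (2.0 * px * wx + p * wxx) / d**2 + 2.0 * p * wx * wx / d**3
    zyy = pyy / d - (2.0 * py * wy + p * wyy) / d**2 + 2.0 * p * wy * wy / d**3
    zxy = -(px * wy + py * wx + p * wxy) / d**2 + 2.0 * p * wx * wy / d**3
    return z, zx, zy, zxx, zxy, zyy


def _bump(x, y, spec: CorneaSpec):
    cx, cy = spec.cone_center
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    return np.exp(-r2 / (2.0 * spec.cone_sigma**2))


def anterior_sag(x, y, spec: CorneaSpec):
    """Noiseless anterior sag of the generating surface (mm).

    The cone protrudes anteriorly: the Gaussian bump of height
    ``cone_amplitude`` is subtracted from the biconic sag, which locally
    steepens the surface at the cone center (maximal tangential curvature at
    the planted location).
    """
    xr, yr = _rotate_xy(np.asarray(x, float), np.asarray(y, float), spec.axis_flat)
    base = biconic_sag(xr, yr, spec.r_flat, spec.r_steep, spec.q_flat, spec.q_steep)
    return base - spec.cone_amplitude * _bump(x, y, spec)


def thickness_um(x, y, spec: CorneaSpec):
    """Thickness map (µm): central thickness minus cone thinning with the bump profile."""
    return spec.central_thickness - spec.cone_thinning * _bump(np.asarray(x, float), np.asarray(y, float), spec)


def analytic_curvature(x, y, spec: CorneaSpec):
    """Mean curvature of the noiseless anterior surface, in diopters.

    Closed-form first/second derivatives of the generating sag (rotated
    biconic minus Gaussian cone) are combined with the graph-surface mean
    curvature formula.  This is the independent oracle against which the
    local-sphere-fit estimator is verified: for a smooth surface, the radius
    of the small-neighborhood best-fit sphere tends to the mean-curvature
    radius.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a = math.radians(spec.axis_flat)
    c, s = math.cos(a), math.sin(a)
    xr, yr = c * x + s * y, -s * x + c * y
    z, zx_r, zy_r, zxx_r, zxy_r, zyy_r = _biconic_derivs(
        xr, yr, spec.r_flat, spec.r_steep, spec.q_flat, spec.q_steep
    )
    # rotate gradient and Hessian back to the lab frame (x' = R x)
    fx = c * zx_r - s * zy_r
    fy = s * zx_r + c * zy_r
    fxx = c * c * zxx_r - 2 * c * s * zxy_r + s * s * zyy_r
    fyy = s * s * zxx_r + 2 * c * s * zxy_r + c * c * zyy_r
    fxy = c * s * (zxx_r - zyy_r) + (c * c - s * s) * zxy_r
    # Gaussian cone contribution (subtracted from the sag)
    cx, cy = spec.cone_center
    sig2 = spec.cone_sigma**2
    dx, dy = x - cx, y - cy
    g = spec.cone_amplitude * np.exp(-(dx * dx + dy * dy) / (2.0 * sig2))
    fx -= -dx / sig2 * g
    fy -= -dy / sig2 * g
    fxx -= (dx * dx / sig2 - 1.0) / sig2 * g
    fyy -= (dy * dy / sig2 - 1.0) / sig2 * g
    fxy -= dx * dy / sig2**2 * g
    num = (1.0 + fy * fy) * fxx - 2.0 * fx * fy * fxy + (1.0 + fx * fx) * fyy
    den = 2.0 * (1.0 + fx * fx + fy * fy) ** 1.5
    h = num / den  # 1/mm, positive for a surface convex toward -z
    return 337.5 * h


def generate_cornea(spec: CorneaSpec) -> TopographyGrid:
    """Generate a reproducible synthetic keratoconic topography.

    Deterministic for a fixed spec (elevation noise is drawn from a generator
    seeded with ``spec.seed``).  Noise is applied to the elevations only;
    pachymetry is recomputed from the noisy surfaces.
    """
    half = spec.grid_diameter / 2.0
    n = int(round(spec.grid_diameter / spec.grid_spacing))
    if n % 2 == 1:
        n += 1  # odd point count -> apex on a node
    axis = np.linspace(-half, half, n + 1)
    xx, yy = np.meshgrid(axis, axis)
    ant = anterior_sag(xx, yy, spec)
    post = ant + thickness_um(xx, yy, spec) / 1000.0
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ant = ant + rng.normal(0.0, spec.noise_sd / 1000.0, ant.shape)
        post = post + rng.normal(0.0, spec.noise_sd / 1000.0, post.shape)
    rr = np.hypot(xx, yy)
    invalid = rr > half + 1e-12
    ant = np.where(invalid, np.nan, ant)
    post = np.where(invalid, np.nan, post)
    grid = TopographyGrid(
        x=axis, y=axis, anterior=ant, posterior=post,
        spacing=spec.grid_spacing, diameter=spec.grid_diameter,
    )
    grid.validate()
    return grid


# ---------------------------------------------------------------------------
# CSV dialect: '# key=value' headers, then x_mm,y_mm,z_ant_mm,z_post_mm rows.

_HEADER_RE = re.compile(r"^#\s*(\w+)\s*=\s*(\S+)\s*$")
_COLUMNS = "x_mm,y_mm,z_ant_mm,z_post_mm"


def write_grid(grid: TopographyGrid, path) -> None:
    """Write a topography to the plain-text dialect (6-decimal values, NaN sentinels)."""
    grid.validate()
    buf = io.StringIO()
    buf.write(f"# spacing_mm={grid.spacing:.6g}\n")
    buf.write(f"# diameter_mm={grid.diameter:.6g}\n")
    buf.write("# units=mm\n")
    buf.write(_COLUMNS + "\n")
    xx, yy = grid.xx, grid.yy
    for xi, yi, ai, pi in zip(xx.ravel(), yy.ravel(), grid.anterior.ravel(), grid.posterior.ravel()):
        a = "NaN" if not np.isfinite(ai) else f"{ai:.6f}"
        p = "NaN" if not np.isfinite(pi) else f"{pi:.6f}"
        buf.write(f"{xi:.6f},{yi:.6f},{a},{p}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_grid(path) -> TopographyGrid:
    """Read a topography written by :func:`write_grid`.

    Raises :class:`GridParseError` (with a line number) on missing header
    keys, unit mismatch, or a non-rectangular grid.
    """
    headers: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _HEADER_RE.match(line)
            if not m:
                raise GridParseError(f"garbled header {line!r}", line=i)
            headers[m.group(1)] = m.group(2)
            continue
        if line.replace(" ", "") == _COLUMNS:
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise GridParseError(f"expected 4 comma-separated values, got {len(parts)}", line=i)
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise GridParseError(str(exc), line=i) from None
    for key in ("spacing_mm", "diameter_mm", "units"):
        if key not in headers:
            raise GridParseError(f"missing required header key {key!r}", line=len(lines))
    if headers["units"] != "mm":
        raise GridParseError(f"unit mismatch: expected mm, got {headers['units']!r}")
    spacing = float(headers["spacing_mm"])
    diameter = float(headers["diameter_mm"])
    data = np.asarray(rows, float)
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    if len(xs) * len(ys) != len(data):
        raise GridParseError("non-rectangular grid: point count does not factor into x/y axes")
    order = np.lexsort((data[:, 0], data[:, 1]))
    data = data[order]
    ant = data[:, 2].reshape(len(ys), len(xs))
    post = data[:, 3].reshape(len(ys), len(xs))
    return TopographyGrid(x=xs, y=ys, anterior=ant, posterior=post, spacing=spacing, diameter=diameter)
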