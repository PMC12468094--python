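"""Anterior-surface keratometric metrics.

Tangential curvature is estimated per node from the radius of the local
least-squares sphere (converted to diopters with the keratometric index
1.3375); global shape indices come from a rotated-biconic least-squares fit
(converted with the physical index 1.376).  The two constants intentionally
differ, matching topographer conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from cxlsim.synthetic import TopographyGrid, biconic_sag

__all__ = [
    "CurvatureMap",
    "BiconicFit",
    "ConeRegion",
    "tangential_curvature",
    "kmax_metrics",
    "fit_biconic",
    "min_pachymetry",
    "detect_cone",
    "ConeDetectionError",
    "BiconicFitError",
    "KERATOMETRIC_INDEX",
    "PHYSICAL_INDEX",
]

KERATOMETRIC_INDEX = 1.3375  # tangential curvature maps
PHYSICAL_INDEX = 1.376  # biconic-derived K values


class ConeDetectionError(RuntimeError):
    """No node strictly exceeds the percentile threshold (KC-free cornea)."""


class BiconicFitError(RuntimeError):
    def __init__(self, message, best_residual=None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class CurvatureMap:
    """Per-node tangential curvature of a surface point cloud."""

    points: np.ndarray  # (n, 3) mm
    k_tg: np.ndarray  # (n,) diopters, NaN where invalid
    radius: np.ndarray  # (n,) local sphere radius, mm
    valid: np.ndarray  # (n,) bool

    def lateral_radius(self) -> np.ndarray:
        return np.hypot(self.points[:, 0], self.points[:, 1])


@dataclass
class BiconicFit:
    """Rotated biconic fit of an anterior surface and derived indices."""

    r_steep: float
    r_flat: float
    axis: float  # orientation of the flat meridian, degrees in [0, 180)
    q_steep: float
    q_flat: float
    center: tuple[float, float]
    z_offset: float
    rms_residual: float  # µm

    @property
    def k_steep(self) -> float:
        return (PHYSICAL_INDEX - 1.0) / (1e-3 * self.r_steep)

    @property
    def k_flat(self) -> float:
        return (PHYSICAL_INDEX - 1.0) / (1e-3 * self.r_flat)

    @property
    def sphere(self) -> float:
        return self.k_flat

    @property
    def cylinder(self) -> float:
        return self.k_steep - self.k_flat

    @property
    def spherical_equivalent(self) -> float:
        return self.sphere + self.cylinder / 2.0

    def to_dict(self) -> dict:
        return {
            "r_steep_mm": self.r_steep,
            "r_flat_mm": self.r_flat,
            "axis_deg": self.axis,
            "q_steep": self.q_steep,
            "q_flat": self.q_flat,
            "sphere_d": self.sphere,
            "cylinder_d": self.cylinder,
            "spherical_equivalent_d": self.spherical_equivalent,
            "rms_residual_um": self.rms_residual,
        }


@dataclass
class ConeRegion:
    """Nodes of the central 8 mm whose tangential curvature exceeds the
    67.5th percentile, with a per-node normalized distance to the region edge."""

    member_idx: np.ndarray  # indices into the source CurvatureMap
    member_points: np.ndarray  # (m, 3)
    center: tuple[float, float]  # location of max K_tg among members
    boundary_distance: np.ndarray  # (m,) normalized in [0, 1]
    edge_angles: np.ndarray  # ray directions used for the edge table
    edge_radii: np.ndarray  # distance center -> first non-member, per ray
    threshold: float  # curvature threshold, D

    def normalized_distance(self, xy: np.ndarray) -> np.ndarray:
        """Normalized distance from the cone center for arbitrary lateral points.

        0 at the center, 1 at (and beyond) the region edge along the point's ray.
        """
        xy = np.atleast_2d(np.asarray(xy, float))
        dx = xy[:, 0] - self.center[0]
        dy = xy[:, 1] - self.center[1]
        r = np.hypot(dx, dy)
        theta = np.mod(np.arctan2(dy, dx), 2.0 * math.pi)
        edge = np.interp(
            theta,
            np.concatenate([self.edge_angles, [2.0 * math.pi]]),
            np.concatenate([self.edge_radii, [self.edge_radii[0]]]),
        )
        return np.clip(r / np.maximum(edge, 1e-9), 0.0, 1.0)


# ---------------------------------------------------------------------------


def _local_sphere_radii(points: np.ndarray, groups: list[np.ndarray]):
    """Batched local-sphere radii via osculating quadrics in the tangent frame.

    Per node: a plane fit of the neighborhood gives the local normal; the
    neighborhood is rotated into the tangent frame and a quadric
    w = c0 + c1 u + c2 v + c3 u^2 + c4 uv + c5 v^2 is fit by least squares.
    The local best-fitting sphere has curvature c3 + c5 (the mean curvature
    of the quadric), so R = 1/(c3 + c5).  Fitting in the tangent frame
    removes the slope-foreshortening bias that a raw algebraic sphere fit
    picks up away from the apex.  Returns NaN on degenerate neighborhoods.
    """
    radii = np.full(len(groups), np.nan)
    by_size: dict[int, list[int]] = {}
    for i, g in enumerate(groups):
        by_size.setdefault(len(g), []).append(i)
    for size, idxs in by_size.items():
        if size < 6:
            continue
        idxs = np.array(idxs)
        pts = points[np.array([groups[i] for i in idxs])]  # (b, size, 3)
        d = pts - points[idxs][:, None, :]
        dc = pts - pts.mean(axis=1, keepdims=True)
        cov = np.einsum("bni,bnj->bij", dc, dc)
        _, evecs = np.linalg.eigh(cov)
        ez = evecs[:, :, 0]  # smallest-variance direction = plane normal
        ez *= np.where(ez[:, 2:3] >= 0, 1.0, -1.0)  # z increases posteriorly
        ex = np.zeros_like(ez)
        use_y = np.abs(ez[:, 0]) > 0.9
        ex[~use_y, 0] = 1.0
        ex[use_y, 1] = 1.0
        ex = ex - ez * np.einsum("bi,bi->b", ex, ez)[:, None]
        ex /= np.linalg.norm(ex, axis=1)[:, None]
        ey = np.cross(ez, ex)
        u = np.einsum("bni,bi->bn", d, ex)
        v = np.einsum("bni,bi->bn", d, ey)
        w = np.einsum("bni,bi->bn", d, ez)
        a = np.stack([np.ones_like(u), u, v, u * u, u * v, v * v], axis=2)
        ata = np.einsum("bni,bnj->bij", a, a)
        atb = np.einsum("bni,bn->bi", a, w)
        try:
            sol = np.linalg.solve(ata, atb[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.full((len(idxs), 6), np.nan)
            for k in range(len(idxs)):
                try:
                    sol[k] = np.linalg.lstsq(a[k], w[k], rcond=None)[0]
                except np.linalg.LinAlgError:
                    pass
        h = sol[:, 3] + sol[:, 5]  # mean curvature, 1/mm
        with np.errstate(divide="ignore", invalid="ignore"):
            radii[idxs] = np.where(h > 0, 1.0 / h, np.nan)
    return radii


def tangential_curvature(
    surface_points: np.ndarray,
    neighborhood_radius: float = 0.12,
    min_points: int = 6,
    fallback_neighbors: int = 8,
) -> CurvatureMap:
    """Per-node tangential curvature from the local best-fitting sphere.

    The neighborhood is all points within ``neighborhood_radius`` lateral
    distance; if fewer than ``min_points`` fall inside it grows to the
    ``fallback_neighbors`` nearest nodes (plus the node itself), keeping the
    estimator defined on coarse FEM surfaces.  K_tg = 337.5 / R[mm].
    """
    pts = np.asarray(surface_points, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("surface_points must be (n, 3)")
    n = len(pts)
    tree = cKDTree(pts[:, :2])
    groups = tree.query_ball_point(pts[:, :2], neighborhood_radius)
    k_fb = min(fallback_neighbors + 1, n)
    need_fb = [i for i, g in enumerate(groups) if len(g) < min_points]
    if need_fb:
        _, nbrs = tree.query(pts[need_fb, :2], k=k_fb)
        nbrs = np.atleast_2d(nbrs)
        for row, i in enumerate(need_fb):
            groups[i] = nbrs[row]
    groups = [np.asarray(g, int) for g in groups]
    radii = _local_sphere_radii(pts, groups)
    valid = np.isfinite(radii) & (radii > 0)
    k_tg = np.where(valid, 1000.0 * (KERATOMETRIC_INDEX - 1.0) / np.where(valid, radii, 1.0), np.nan)
    return CurvatureMap(points=pts, k_tg=k_tg, radius=radii, valid=valid)


def kmax_metrics(cmap: CurvatureMap, zone_diameter: float = 3.0, zone_center=None):
    """Kmax-t (max K_tg), its location, and the mean K_tg within the
    ``zone_diameter`` disc centered at the maximum (KmaxMean3).

    ``zone_center`` overrides the zone anchor (used to track the same
    corneal region across pre/post states); Kmax-t itself is always the
    map maximum.
    """
    if not cmap.valid.any():
        raise ValueError("curvature map has no valid node")
    k = np.where(cmap.valid, cmap.k_tg, -np.inf)
    imax = int(np.argmax(k))
    kmax_t = float(cmap.k_tg[imax])
    loc = cmap.points[imax]
    cx, cy = (loc[0], loc[1]) if zone_center is None else zone_center[:2]
    d = np.hypot(cmap.points[:, 0] - cx, cmap.points[:, 1] - cy)
    in_zone = cmap.valid & (d <= zone_diameter / 2.0)
    kmaxmean3 = float(cmap.k_tg[in_zone].mean())
    return kmax_t, loc.copy(), kmaxmean3


def _biconic_residuals(params, x, y, z):
    rx, ry, angle, qx, qy, x0, y0, z0 = params
    c, s = math.cos(angle), math.sin(angle)
    xr = c * (x - x0) + s * (y - y0)
    yr = -s * (x - x0) + c * (y - y0)
    pred = biconic_sag(xr, yr, rx, ry, qx, qy) + z0
    res = pred - z
    return np.where(np.isfinite(res), res, 1.0)


def _paraboloid_init(x, y, z):
    a = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(a, z, rcond=None)
    m = np.array([[2.0 * coef[0], coef[1]], [coef[1], 2.0 * coef[2]]])
    evals, evecs = np.linalg.eigh(m)
    evals = np.clip(evals, 1e-4, None)
    # smaller curvature -> flatter meridian; use it as the x' direction
    v = evecs[:, 0]
    angle = math.atan2(v[1], v[0]) % math.pi
    return [1.0 / evals[0], 1.0 / evals[1], angle, 0.0, 0.0, 0.0, 0.0, float(np.min(z))]


def fit_biconic(
    surface_points: np.ndarray,
    fit_diameter: float = 8.0,
    max_restarts: int = 5,
    rms_threshold_um: float = 50.0,
    seed: int = 0,
) -> BiconicFit:
    """Nonlinear least-squares rotated-biconic fit over ``fit_diameter``.

    Initialized from a paraboloid least-squares fit, with seeded random
    restarts on non-convergence.  R_steep < R_flat is enforced by
    construction (radii sorted, axis rotated accordingly).
    """
    pts = np.asarray(surface_points, float)
    r = np.hypot(pts[:, 0], pts[:, 1])
    sel = np.isfinite(pts).all(axis=1) & (r <= fit_diameter / 2.0)
    if sel.sum() < 12:
        raise BiconicFitError("not enough points inside the fit diameter")
    x, y, z = pts[sel, 0], pts[sel, 1], pts[sel, 2]
    init = _paraboloid_init(x, y, z)
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max_restarts + 1):
        p0 = list(init)
        if trial > 0:
            p0[0] *= 1.0 + 0.1 * rng.standard_normal()
            p0[1] *= 1.0 + 0.1 * rng.standard_normal()
            p0[2] = (p0[2] + rng.uniform(0, math.pi)) % math.pi
        try:
            sol = least_squares(
                _biconic_residuals, p0, args=(x, y, z), method="lm",
                xtol=1e-12, ftol=1e-12, max_nfev=4000,
            )
        except Exception:
            continue
        rms = float(np.sqrt(np.mean(sol.fun**2))) * 1000.0
        if best is None or rms < best[1]:
            best = (sol.x, rms)
        if rms < rms_threshold_um:
            break
    if best is None:
        raise BiconicFitError("biconic fit failed to converge")
    params, rms = best
    rx, ry, angle, qx, qy, x0, y0, z0 = params
    angle = angle % math.pi
    if rx >= ry:  # x' meridian is the flat one
        r_flat, r_steep, q_flat, q_steep, axis = rx, ry, qx, qy, angle
    else:
        r_flat, r_steep, q_flat, q_steep = ry, rx, qy, qx
        axis = (angle + math.pi / 2.0) % math.pi
    fit = BiconicFit(
        r_steep=float(r_steep), r_flat=float(r_flat), axis=math.degrees(axis) % 180.0,
        q_steep=float(q_steep), q_flat=float(q_flat),
        center=(float(x0), float(y0)), z_offset=float(z0), rms_residual=rms,
    )
    if rms > rms_threshold_um:
        raise BiconicFitError(
            f"biconic fit residual {rms:.1f} µm exceeds threshold", best_residual=rms
        )
    return fit


def min_pachymetry(grid: TopographyGrid):
    """Minimum pachymetry (µm) and its location; ties broken by smallest
    lateral radius, then lexicographically by (x, y)."""
    pach = grid.pachymetry
    m = grid.mask
    if not m.any():
        raise ValueError("all-masked grid")
    vmin = np.nanmin(np.where(m, pach, np.nan))
    iy, ix = np.where(m & (pach <= vmin + 1e-12))
    xs, ys = grid.x[ix], grid.y[iy]
    order = np.lexsort((ys, xs, np.hypot(xs, ys)))
    j = order[0]
    return float(vmin), (float(xs[j]), float(ys[j]))


def detect_cone(
    cmap: CurvatureMap,
    region_diameter: float = 8.0,
    percentile: float = 67.5,
    n_rays: int = 72,
) -> ConeRegion:
    """Detect the keratoconus cone in the central ``region_diameter``.

    Threshold is the linear-interpolation percentile of valid K_tg inside the
    region; members strictly exceed it.  The per-member boundary distance is
    the distance from the cone center normalized by the distance to the first
    non-member along the member's ray (tabulated over ``n_rays`` directions).
    """
    lat = cmap.lateral_radius()
    central = cmap.valid & (lat <= region_diameter / 2.0)
    if central.sum() < 20:
        raise ValueError("fewer than 20 valid nodes in the central region")
    vals = cmap.k_tg[central]
    thr = float(np.percentile(vals, percentile))
    member = central & (cmap.k_tg > thr)
    if not member.any():
        raise ConeDetectionError(
            "no node strictly exceeds the percentile threshold; treat cornea as KC-free"
        )
    midx = np.where(member)[0]
    mpts = cmap.points[midx]
    ic = midx[int(np.argmax(cmap.k_tg[midx]))]
    center = (float(cmap.points[ic, 0]), float(cmap.points[ic, 1]))

    # march along rays from the center to the first non-member sample
    tree = cKDTree(cmap.points[central][:, :2])
    central_member = member[central]
    angles = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
    rmax = region_diameter / 2.0
    # step at half the typical node spacing
    d_nn, _ = tree.query(cmap.points[central][:, :2], k=2)
    step = max(float(np.median(d_nn[:, 1])) / 2.0, 1e-3)
    ts = np.arange(step, rmax + step, step)
    px = center[0] + np.outer(np.cos(angles), ts)
    py = center[1] + np.outer(np.sin(angles), ts)
    _, nearest = tree.query(np.column_stack([px.ravel(), py.ravel()]))
    is_member = central_member[nearest].reshape(len(angles), len(ts))
    edge = np.full(len(angles), rmax)
    for i in range(len(angles)):
        out = np.where(~is_member[i])[0]
        if len(out):
            edge[i] = ts[out[0]]

    region = ConeRegion(
        member_idx=midx, member_points=mpts, center=center,
        boundary_distance=np.empty(len(midx)), edge_angles=angles, edge_radii=edge,
        threshold=thr,
    )
    region.boundary_distance = region.normalized_distance(mpts[:, :2])
    return region
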