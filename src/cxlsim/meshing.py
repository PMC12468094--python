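"""Labeled quadratic (10-node) tetrahedral meshes of the corneal dome.

A graded disc triangulation is extruded through the thickness into prism
layers; each prism is split into three tetrahedra with the lowest-global-index
diagonal rule, which guarantees a conforming decomposition, then midside
nodes are added.  Midside ordering follows the Gmsh TET10 convention:
edges (0,1), (1,2), (0,2), (0,3), (2,3), (1,3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.spatial import Delaunay, cKDTree

from cxlsim.synthetic import TopographyGrid

__all__ = ["CornealMesh", "build_mesh", "build_spherical_shell", "MeshingError",
           "write_msh", "read_msh", "TET10_EDGES"]

TET10_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (2, 3), (1, 3)]


class MeshingError(RuntimeError):
    pass


@dataclass
class CornealMesh:
    """Second-order tetrahedral mesh with surface labels and depth fields."""

    nodes: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (m, 10) int
    anterior: np.ndarray  # node indices, normalized depth 0
    posterior: np.ndarray  # node indices, normalized depth 1
    limbus: np.ndarray  # node indices on the rim lateral surface
    depth: np.ndarray  # (n,) normalized depth in [0, 1]
    thickness: np.ndarray  # (n,) local column thickness, mm
    layers: int
    edge_parents: np.ndarray  # (n_mid, 2) vertex parents of midside nodes
    n_vertices: int  # midside nodes occupy indices >= n_vertices
    vertex_column: np.ndarray  # (n_vertices,) lateral column id
    limbus_dirs: np.ndarray = field(default=None)  # (n,3) slide direction at limbus nodes
    limbus_tangents: np.ndarray = field(default=None)  # (n,3) ring tangent at limbus nodes

    @property
    def lateral_radius(self) -> np.ndarray:
        return np.hypot(self.nodes[:, 0], self.nodes[:, 1])

    @property
    def posterior_faces(self) -> np.ndarray:
        return boundary_faces(self, self.posterior)

    @property
    def anterior_faces(self) -> np.ndarray:
        return boundary_faces(self, self.anterior)

    def with_nodes(self, nodes: np.ndarray) -> "CornealMesh":
        """Copy with updated reference coordinates; derived fields recomputed."""
        m = CornealMesh(
            nodes=np.asarray(nodes, float).copy(), tets=self.tets,
            anterior=self.anterior, posterior=self.posterior, limbus=self.limbus,
            depth=self.depth, thickness=self.thickness.copy(), layers=self.layers,
            edge_parents=self.edge_parents, n_vertices=self.n_vertices,
            vertex_column=self.vertex_column, limbus_dirs=self.limbus_dirs,
            limbus_tangents=self.limbus_tangents,
        )
        m.recompute_thickness()
        return m

    def recompute_thickness(self) -> None:
        """Recompute per-node column thickness from current coordinates."""
        ncols = self.vertex_column.max() + 1
        top = np.zeros((ncols, 3))
        bot = np.zeros((ncols, 3))
        for i in range(self.n_vertices):
            col = self.vertex_column[i]
            if self.depth[i] == 0.0:
                top[col] = self.nodes[i]
            elif self.depth[i] == 1.0:
                bot[col] = self.nodes[i]
        tcol = np.linalg.norm(top - bot, axis=1)
        t = np.empty(len(self.nodes))
        t[: self.n_vertices] = tcol[self.vertex_column]
        t[self.n_vertices:] = 0.5 * (
            t[self.edge_parents[:, 0]] + t[self.edge_parents[:, 1]]
        )
        self.thickness = t

    def depth_um(self) -> np.ndarray:
        """Physical distance from the anterior surface along the node column, µm."""
        return self.depth * self.thickness * 1000.0


# ---------------------------------------------------------------------------
# disc triangulation


def _disc_points(radius: float, edge_central: float, edge_peripheral: float,
                 central_radius: float = 3.0):
    """Ring layout of 2D points: target edge ``edge_central`` inside
    ``central_radius``, blending linearly to ``edge_peripheral`` at the rim."""

    def target(r):
        if r <= central_radius:
            return edge_central
        f = (r - central_radius) / max(radius - central_radius, 1e-9)
        return edge_central + f * (edge_peripheral - edge_central)

    radii = [0.0]
    while True:
        r = radii[-1] + target(radii[-1] + 1e-9)
        if r >= radius - 0.25 * target(radius):
            break
        radii.append(r)
    radii.append(radius)
    pts = [(0.0, 0.0)]
    rim_start = None
    for r in radii[1:]:
        n = max(6, int(round(2.0 * math.pi * r / target(r))))
        if r == radii[-1]:
            rim_start = len(pts)
        ang = np.arange(n) * 2.0 * math.pi / n
        # stagger alternate rings for better-shaped triangles
        ang = ang + (len(pts) % 2) * math.pi / n
        for a in ang:
            pts.append((r * math.cos(a), r * math.sin(a)))
    pts = np.asarray(pts)
    rim = np.arange(rim_start, len(pts))
    return pts, rim


def _split_prism(prism):
    """Split prism (a,b,c | d,e,f) into 3 positively-decomposable tets using
    the lowest-global-index diagonal rule (Dompierre et al. scheme)."""
    a, b, c, d, e, f = prism
    verts = [a, b, c, d, e, f]
    # rotate so the smallest vertex sits at bottom position 0 (or its column)
    rotations = [
        (0, 1, 2, 3, 4, 5),
        (1, 2, 0, 4, 5, 3),
        (2, 0, 1, 5, 3, 4),
        (3, 5, 4, 0, 2, 1),
        (4, 3, 5, 1, 0, 2),
        (5, 4, 3, 2, 1, 0),
    ]
    imin = int(np.argmin(verts))
    rot = rotations[imin]
    a, b, c, d, e, f = (verts[i] for i in rot)
    # quad faces touching vertex a get diagonals a-e and a-f;
    # third face (b,c,f,e): diagonal through its smallest vertex
    if min(b, f) < min(c, e):
        tets = [(a, b, c, f), (a, b, f, e), (a, e, f, d)]
    else:
        tets = [(a, b, c, e), (a, c, f, e), (a, e, f, d)]
    return tets


def _orient_positive(nodes, tets):
    t = np.asarray(tets)
    v0 = nodes[t[:, 1]] - nodes[t[:, 0]]
    v1 = nodes[t[:, 2]] - nodes[t[:, 0]]
    v2 = nodes[t[:, 3]] - nodes[t[:, 0]]
    det = np.einsum("ij,ij->i", np.cross(v0, v1), v2)
    flip = det < 0
    t[flip, 2], t[flip, 3] = t[flip, 3].copy(), t[flip, 2].copy()
    return t


def _add_midside(nodes, tets4):
    """Promote TET4 connectivity to TET10; returns nodes, tets10, edge_parents."""
    edge_map: dict[tuple[int, int], int] = {}
    parents = []
    new_nodes = [nodes]
    next_id = len(nodes)
    tets10 = np.empty((len(tets4), 10), int)
    tets10[:, :4] = tets4
    mids = np.empty((len(tets4), 6), int)
    for k, (ia, ib) in enumerate(TET10_EDGES):
        va, vb = tets4[:, ia], tets4[:, ib]
        lo, hi = np.minimum(va, vb), np.maximum(va, vb)
        for row in range(len(tets4)):
            key = (lo[row], hi[row])
            idx = edge_map.get(key)
            if idx is None:
                idx = next_id
                edge_map[key] = idx
                parents.append(key)
                next_id += 1
            mids[row, k] = idx
    tets10[:, 4:] = mids
    parents = np.asarray(parents, int)
    mid_coords = 0.5 * (nodes[parents[:, 0]] + nodes[parents[:, 1]])
    all_nodes = np.vstack([nodes, mid_coords])
    return all_nodes, tets10, parents


def _fill_nan_grid(z: np.ndarray) -> np.ndarray:
    """Replace NaNs by nearest-valid values (affects only the masked corners)."""
    if not np.isnan(z).any():
        return z
    valid = np.isfinite(z)
    iy, ix = np.indices(z.shape)
    tree = cKDTree(np.column_stack([iy[valid], ix[valid]]))
    _, nearest = tree.query(np.column_stack([iy[~valid], ix[~valid]]))
    out = z.copy()
    out[~valid] = z[valid][nearest]
    return out


def build_mesh(
    grid: TopographyGrid,
    layers: int = 7,
    edge_central: float = 0.35,
    edge_peripheral: float = 0.6,
) -> CornealMesh:
    """Extrude the corneal volume between the two surfaces into ``layers``
    element layers of quadratic tetrahedra; deterministic for fixed inputs."""
    if layers < 2:
        raise MeshingError("layers must be >= 2")
    grid.validate()
    radius = grid.diameter / 2.0
    pts2d, rim = _disc_points(radius, edge_central, edge_peripheral)
    tri = Delaunay(pts2d)
    triangles = tri.simplices

    ant_spline = RectBivariateSpline(grid.y, grid.x, _fill_nan_grid(grid.anterior))
    post_spline = RectBivariateSpline(grid.y, grid.x, _fill_nan_grid(grid.posterior))
    za = ant_spline.ev(pts2d[:, 1], pts2d[:, 0])
    zp = post_spline.ev(pts2d[:, 1], pts2d[:, 0])
    if np.any(zp <= za):
        raise MeshingError("non-positive thickness encountered during extrusion")

    ncol = len(pts2d)
    fracs = np.arange(layers + 1) / layers
    nodes = np.empty((ncol * (layers + 1), 3))
    depth = np.empty(ncol * (layers + 1))
    column = np.empty(ncol * (layers + 1), int)
    for l, f in enumerate(fracs):
        sl = slice(l * ncol, (l + 1) * ncol)
        nodes[sl, 0] = pts2d[:, 0]
        nodes[sl, 1] = pts2d[:, 1]
        nodes[sl, 2] = za + f * (zp - za)
        depth[sl] = f
        column[sl] = np.arange(ncol)

    tets4 = []
    for l in range(layers):
        off_b, off_t = l * ncol, (l + 1) * ncol
        for (i, j, k) in triangles:
            tets4.extend(_split_prism((off_b + i, off_b + j, off_b + k,
                                       off_t + i, off_t + j, off_t + k)))
    tets4 = _orient_positive(nodes, np.asarray(tets4, int))
    n_vertices = len(nodes)
    all_nodes, tets10, parents = _add_midside(nodes, tets4)

    depth_full = np.concatenate([depth, 0.5 * (depth[parents[:, 0]] + depth[parents[:, 1]])])

    # curve the elements: midside nodes are placed on the interpolated
    # surface at their lateral position (a straight chord midpoint sits tens
    # of µm off a 7.7 mm dome over a mm-scale edge, faceting the geometry)
    mid = slice(n_vertices, len(all_nodes))
    mx, my, mf = all_nodes[mid, 0], all_nodes[mid, 1], depth_full[mid]
    za_m = ant_spline.ev(my, mx)
    zp_m = post_spline.ev(my, mx)
    all_nodes[mid, 2] = za_m + mf * (zp_m - za_m)
    anterior = np.where(depth_full == 0.0)[0]
    posterior = np.where(depth_full == 1.0)[0]
    rim_vertex = np.zeros(n_vertices, bool)
    rim_vertex[:n_vertices] = np.isin(column, rim)
    rim_full = np.concatenate([rim_vertex, rim_vertex[parents[:, 0]] & rim_vertex[parents[:, 1]]])
    limbus = np.where(rim_full)[0]

    # curved rim: push limbal midside nodes onto the true circle so the
    # quadratic boundary follows the disc (otherwise the faceted rim
    # under-covers the meshed volume by ~0.5%)
    for i in limbus:
        if i < n_vertices:
            continue
        x, y = all_nodes[i, 0], all_nodes[i, 1]
        rho = math.hypot(x, y)
        if rho < radius - 1e-12:
            xn, yn = x * radius / rho, y * radius / rho
            f = depth_full[i]
            zn = (ant_spline.ev(yn, xn) + f * (post_spline.ev(yn, xn) - ant_spline.ev(yn, xn)))
            all_nodes[i] = (xn, yn, float(zn))

    mesh = CornealMesh(
        nodes=all_nodes, tets=tets10, anterior=anterior, posterior=posterior,
        limbus=limbus, depth=depth_full, thickness=np.zeros(len(all_nodes)),
        layers=layers, edge_parents=parents, n_vertices=n_vertices,
        vertex_column=column,
    )
    mesh.recompute_thickness()

    # sliding direction at the limbus: the outward normals of the (circular)
    # limbal ring are the horizontal radial directions, so the anchoring
    # surface they sweep is the limbal plane -- rim nodes slide radially,
    # axial and circumferential motion is blocked
    dirs = np.zeros((len(all_nodes), 3))
    tangents = np.zeros((len(all_nodes), 3))
    for i in limbus:
        x, y = all_nodes[i, 0], all_nodes[i, 1]
        rho = math.hypot(x, y)
        ux, uy = x / rho, y / rho
        dirs[i] = np.array([ux, uy, 0.0])
        tangents[i] = np.array([-uy, ux, 0.0])
    mesh.limbus_dirs = dirs
    mesh.limbus_tangents = tangents
    _check_jacobians(mesh)
    return mesh


def _check_jacobians(mesh: CornealMesh) -> None:
    t = mesh.tets
    v0 = mesh.nodes[t[:, 1]] - mesh.nodes[t[:, 0]]
    v1 = mesh.nodes[t[:, 2]] - mesh.nodes[t[:, 0]]
    v2 = mesh.nodes[t[:, 3]] - mesh.nodes[t[:, 0]]
    det = np.einsum("ij,ij->i", np.cross(v0, v1), v2)
    bad = np.where(det <= 0)[0]
    if len(bad):
        raise MeshingError(f"inverted elements after extrusion: {bad.tolist()[:20]}")


def tet_volumes(mesh: CornealMesh) -> np.ndarray:
    """Element volumes of the isoparametric (curved) quadratic geometry."""
    from cxlsim.solver import _DN_QP, _QW  # deferred: solver imports meshing

    X = mesh.nodes[mesh.tets]
    J = np.einsum("eai,qak->eqik", X, _DN_QP)
    return np.einsum("eq,q->e", np.linalg.det(J), _QW)


_FACE_OF_TET = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
_FACE_EDGE_MID = {  # midside node slot for each vertex pair, per TET10_EDGES
    frozenset(e): 4 + i for i, e in enumerate(TET10_EDGES)
}


def boundary_faces(mesh: CornealMesh, label_nodes: np.ndarray) -> np.ndarray:
    """Outward-oriented 6-node boundary triangles whose corners all carry the label."""
    label = np.zeros(len(mesh.nodes), bool)
    label[label_nodes] = True
    seen: dict[tuple, tuple] = {}
    for e, tet in enumerate(mesh.tets):
        for fi, (a, b, c) in enumerate(_FACE_OF_TET):
            tri = (tet[a], tet[b], tet[c])
            key = tuple(sorted(tri))
            if key in seen:
                del seen[key]
            else:
                seen[key] = (e, fi)
    faces = []
    for key, (e, fi) in seen.items():
        tet = mesh.tets[e]
        a, b, c = _FACE_OF_TET[fi]
        tri = (tet[a], tet[b], tet[c])
        if not (label[tri[0]] and label[tri[1]] and label[tri[2]]):
            continue
        mids = []
        for pair in ((a, b), (b, c), (a, c)):
            mids.append(tet[_FACE_EDGE_MID[frozenset(pair)]])
        faces.append(list(tri) + mids)
    return np.asarray(sorted(faces), int).reshape(-1, 6)


# ---------------------------------------------------------------------------
# closed spherical shell (solver verification geometry)


def _icosphere(subdiv: int):
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            v = verts[i] + verts[j]
            verts.append(v / np.linalg.norm(v))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdiv):
        new_faces = []
        for (i, j, k) in faces:
            a, b, c = midpoint(i, j), midpoint(j, k), midpoint(k, i)
            new_faces += [(i, a, c), (j, b, a), (k, c, b), (a, b, c)]
        faces = new_faces
    return np.asarray(verts), np.asarray(faces, int)


def build_spherical_shell(radius: float = 7.7, thickness: float = 0.55,
                          subdiv: int = 2, layers: int = 2) -> CornealMesh:
    """Closed thin spherical shell of quadratic tets (analytic-oracle geometry).

    ``radius`` is the mid-surface radius; the 'posterior' label is the inner
    (pressurized) surface, 'anterior' the outer one.  The limbus label is
    empty; rigid-body modes must be removed by the solver.
    """
    verts, faces = _icosphere(subdiv)
    r_in, r_out = radius - thickness / 2.0, radius + thickness / 2.0
    ncol = len(verts)
    fracs = np.arange(layers + 1) / layers
    nodes = np.empty((ncol * (layers + 1), 3))
    depth = np.empty(ncol * (layers + 1))
    column = np.empty(ncol * (layers + 1), int)
    for l, f in enumerate(fracs):
        sl = slice(l * ncol, (l + 1) * ncol)
        nodes[sl] = verts * (r_out - f * (r_out - r_in))
        depth[sl] = f
        column[sl] = np.arange(ncol)
    tets4 = []
    for l in range(layers):
        off_b, off_t = l * ncol, (l + 1) * ncol
        for (i, j, k) in faces:
            tets4.extend(_split_prism((off_b + i, off_b + j, off_b + k,
                                       off_t + i, off_t + j, off_t + k)))
    tets4 = _orient_positive(nodes, np.asarray(tets4, int))
    n_vertices = len(nodes)
    all_nodes, tets10, parents = _add_midside(nodes, tets4)
    # project midside nodes radially so the quadratic geometry follows the sphere
    mid_r = np.linalg.norm(all_nodes[n_vertices:], axis=1)
    target_r = 0.5 * (np.linalg.norm(all_nodes[parents[:, 0]], axis=1)
                      + np.linalg.norm(all_nodes[parents[:, 1]], axis=1))
    all_nodes[n_vertices:] *= (target_r / mid_r)[:, None]
    depth_full = np.concatenate([depth, 0.5 * (depth[parents[:, 0]] + depth[parents[:, 1]])])
    mesh = CornealMesh(
        nodes=all_nodes, tets=tets10,
        anterior=np.where(depth_full == 0.0)[0],
        posterior=np.where(depth_full == 1.0)[0],
        limbus=np.empty(0, int), depth=depth_full,
        thickness=np.full(len(all_nodes), thickness), layers=layers,
        edge_parents=parents, n_vertices=n_vertices, vertex_column=column,
    )
    _check_jacobians(mesh)
    return mesh


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 ASCII I/O with named physical groups

_PHYS = {"anterior": 1, "posterior": 2, "limbus": 3, "volume": 4}


def write_msh(mesh: CornealMesh, path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII with named surface groups."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", "4",
              '2 1 "anterior"', '2 2 "posterior"', '3 4 "volume"', '2 3 "limbus"',
              "$EndPhysicalNames"]
    lines += ["$Nodes", str(len(mesh.nodes))]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
    lines.append("$EndNodes")
    elems = []
    eid = 1
    for name in ("anterior", "posterior"):
        for face in boundary_faces(mesh, getattr(mesh, name)):
            conn = " ".join(str(v + 1) for v in face)
            elems.append(f"{eid} 9 2 {_PHYS[name]} {_PHYS[name]} {conn}")
            eid += 1
    for tet in mesh.tets:
        conn = " ".join(str(v + 1) for v in tet)
        elems.append(f"{eid} 11 2 {_PHYS['volume']} {_PHYS['volume']} {conn}")
        eid += 1
    lines += ["$Elements", str(len(elems))] + elems + ["$EndElements"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path):
    """Read nodes, TET10 connectivity and labeled TRI6 faces from MSH 2.2 ASCII."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    def section(name):
        i = lines.index(f"${name}")
        j = lines.index(f"$End{name}")
        return lines[i + 1: j]
    node_lines = section("Nodes")
    nodes = np.array([[float(v) for v in ln.split()[1:4]] for ln in node_lines[1:]])
    tets, faces = [], {}
    for ln in section("Elements")[1:]:
        parts = [int(v) for v in ln.split()]
        etype, ntags = parts[1], parts[2]
        conn = [v - 1 for v in parts[3 + ntags:]]
        if etype == 11:
            tets.append(conn)
        elif etype == 9:
            faces.setdefault(parts[3], []).append(conn)
    named = {name: np.asarray(faces.get(tag, []), int) for name, tag in _PHYS.items() if tag != 4}
    return nodes, np.asarray(tets, int), named
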