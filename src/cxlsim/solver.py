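"""Quasi-static nonlinear FEM: follower-pressure inflation of the corneal
dome with a sliding limbal boundary, and stress-free geometry recovery.

Total-Lagrangian formulation on 10-node tetrahedra (4-point quadrature).
The material tangent and the follower-load stiffness are built by central
finite differences of the analytic stress / face force, which keeps Newton
quadratic to the tolerance used here while the analytic stress itself is
verified against the energy by independent tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, gmres, splu

from cxlsim.constitutive import MaterialField, MaterialParams, pk1_stress, pk1_tangent_fd
from cxlsim.meshing import CornealMesh, TET10_EDGES, boundary_faces

__all__ = ["SolveConfig", "SolveResult", "PrestressResult", "FEModel",
           "inflate", "find_stress_free", "tangential_modulus_at_iop",
           "SolverError", "MMHG_TO_KPA", "fit_sphere_radius"]

MMHG_TO_KPA = 0.133322


class SolverError(RuntimeError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass(frozen=True)
class SolveConfig:
    iop_mmhg: float = 15.0
    steps: int = 5
    tol: float = 1e-8  # relative residual
    max_newton: int = 12
    max_halvings: int = 10
    sliding: str = "slide"  # 'slide' (radially within the limbal plane) or 'pinned'

    def __post_init__(self):
        if self.iop_mmhg < 0:
            raise ValueError("IOP must be >= 0")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def pressure_kpa(self) -> float:
        return self.iop_mmhg * MMHG_TO_KPA


@dataclass
class SolveResult:
    u: np.ndarray  # (n, 3) displacement, mm
    deformed: np.ndarray  # (n, 3)
    apex_displacement: float  # mm, magnitude at the anterior apex
    history: list
    max_volume_change: float
    model: "FEModel"


@dataclass
class PrestressResult:
    mesh: CornealMesh  # stress-free reference
    solve: SolveResult  # inflation of the stress-free mesh to target IOP
    residual_um: float
    iterations: int
    trace: list


# ---------------------------------------------------------------------------
# TET10 shape functions (Gmsh midside ordering)

_QP = np.array([
    [0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
    [0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
    [0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
    [0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
])
_QW = np.full(4, 1.0 / 24.0)

_DLAM = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


def _tet10_shape(xi):
    lam = np.array([1.0 - xi[0] - xi[1] - xi[2], xi[0], xi[1], xi[2]])
    N = np.empty(10)
    dN = np.empty((10, 3))
    for v in range(4):
        N[v] = lam[v] * (2.0 * lam[v] - 1.0)
        dN[v] = (4.0 * lam[v] - 1.0) * _DLAM[v]
    for m, (a, b) in enumerate(TET10_EDGES):
        N[4 + m] = 4.0 * lam[a] * lam[b]
        dN[4 + m] = 4.0 * (lam[a] * _DLAM[b] + lam[b] * _DLAM[a])
    return N, dN


_N_QP = np.stack([_tet10_shape(xi)[0] for xi in _QP])  # (4, 10)
_DN_QP = np.stack([_tet10_shape(xi)[1] for xi in _QP])  # (4, 10, 3)

# 6-node triangle (face) shape functions, 3-point rule
_FQP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_FQW = np.full(3, 1.0 / 6.0)


def _tri6_shape(xi):
    l0, l1, l2 = 1.0 - xi[0] - xi[1], xi[0], xi[1]
    lam = np.array([l0, l1, l2])
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    N = np.empty(6)
    dN = np.empty((6, 2))
    for v in range(3):
        N[v] = lam[v] * (2.0 * lam[v] - 1.0)
        dN[v] = (4.0 * lam[v] - 1.0) * dlam[v]
    for m, (a, b) in enumerate(((0, 1), (1, 2), (0, 2))):
        N[3 + m] = 4.0 * lam[a] * lam[b]
        dN[3 + m] = 4.0 * (lam[a] * dlam[b] + lam[b] * dlam[a])
    return N, dN


_FN_QP = np.stack([_tri6_shape(xi)[0] for xi in _FQP])  # (3, 6)
_FDN_QP = np.stack([_tri6_shape(xi)[1] for xi in _FQP])  # (3, 6, 2)


# ---------------------------------------------------------------------------


class FEModel:
    """Precomputed element data, boundary faces and constraint basis for one mesh."""

    def __init__(self, mesh: CornealMesh, sliding: str = "slide"):
        self.mesh = mesh
        conn = mesh.tets
        self.conn = conn
        X = mesh.nodes[conn]  # (nel, 10, 3)
        Jref = np.einsum("eai,qak->eqik", X, _DN_QP)  # dx/dxi
        detJ = np.linalg.det(Jref)
        if np.any(detJ <= 0):
            raise SolverError("non-positive Jacobian in reference mesh")
        Jinv = np.linalg.inv(Jref)
        self.dNdX = np.einsum("qak,eqki->eqai", _DN_QP, Jinv)  # (nel, 4, 10, 3)
        self.wdetJ = detJ * _QW[None, :]
        nel, nq = self.wdetJ.shape
        self.nel, self.nq = nel, nq

        # quadrature-point fields
        self.qp_dhat = np.einsum("qa,ea->eq", _N_QP, mesh.depth[conn]).reshape(-1)
        self.qp_xy = np.einsum("qa,eai->eqi", _N_QP, X[..., :2]).reshape(-1, 2)
        self.qp_depth_um = np.einsum("qa,ea->eq", _N_QP, mesh.depth_um()[conn]).reshape(-1)
        self.qp_dhat = np.clip(self.qp_dhat, 0.0, 1.0)

        # fiber frame per quadrature point: surface normal from the depth gradient
        n = np.einsum("eqai,ea->eqi", self.dNdX, mesh.depth[conn]).reshape(-1, 3)
        n /= np.linalg.norm(n, axis=1)[:, None]
        ex = np.zeros_like(n)
        use_ey = np.abs(n[:, 0]) > 0.9
        ex[~use_ey, 0] = 1.0
        ex[use_ey, 1] = 1.0
        a1 = ex - n * np.einsum("ij,ij->i", ex, n)[:, None]
        a1 /= np.linalg.norm(a1, axis=1)[:, None]
        a2 = np.cross(n, a1)
        self.fiber_a1, self.fiber_a2 = a1, a2

        # assembly index maps
        ndof = 3 * len(mesh.nodes)
        self.ndof = ndof
        edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(nel, 30)
        self.rows = np.repeat(edof, 30, axis=1).ravel()
        self.cols = np.tile(edof, (1, 30)).ravel()
        self.edof = edof

        # pressurized (posterior) faces
        self.faces = boundary_faces(mesh, mesh.posterior)
        self.fdof = (3 * self.faces[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 18)
        self.frows = np.repeat(self.fdof, 18, axis=1).ravel()
        self.fcols = np.tile(self.fdof, (1, 18)).ravel()

        self.T = self._constraint_basis(sliding)
        self.sliding = sliding

    # -- constraints -------------------------------------------------------

    def _constraint_basis(self, sliding: str) -> sp.csr_matrix:
        mesh = self.mesh
        n = len(mesh.nodes)
        limbus = set(mesh.limbus.tolist())
        cols = []
        rows = []
        vals = []
        ncol = 0
        for i in range(n):
            if i in limbus:
                if sliding == "pinned":
                    continue
                s = mesh.limbus_dirs[i]
                rows += [3 * i, 3 * i + 1, 3 * i + 2]
                cols += [ncol] * 3
                vals += list(s)
                ncol += 1
            else:
                for k in range(3):
                    rows.append(3 * i + k)
                    cols.append(ncol)
                    vals.append(1.0)
                    ncol += 1
        if len(limbus) == 0:
            # closed shell: remove the 6 rigid modes with a 3-2-1 pin
            T = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, ncol)).tocsc()
            fixed = self._rigid_pin_dofs()
            keep = np.setdiff1d(np.arange(ncol), fixed)
            return T[:, keep].tocsr()
        return sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, ncol)).tocsr()

    def _rigid_pin_dofs(self):
        x = self.mesh.nodes
        a = int(np.argmax(x[:, 0]))
        b = int(np.argmax(x[:, 1]))
        c = int(np.argmax(x[:, 2]))
        return np.array([3 * a, 3 * a + 1, 3 * a + 2, 3 * b + 0, 3 * b + 2, 3 * c + 1])

    # -- material ----------------------------------------------------------

    def material_field(self, params: MaterialParams, weakening=None, cxl=None) -> MaterialField:
        """Evaluate effective parameters at every quadrature point.

        ``weakening``/``cxl`` are :class:`~cxlsim.fields.ScalarField` or None.
        """
        m_kc = weakening.at(self.qp_xy, self.qp_depth_um) if weakening is not None else None
        m_cxl = cxl.at(self.qp_xy, self.qp_depth_um) if cxl is not None else None
        return MaterialField.build(params, self.qp_dhat, self.fiber_a1, self.fiber_a2,
                                   m_kc=m_kc, m_cxl=m_cxl)

    # -- assembly ----------------------------------------------------------

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        F = np.einsum("eai,eqaj->eqij", u[self.conn], self.dNdX)
        F += np.eye(3)
        return F.reshape(-1, 3, 3)

    def internal_force(self, u: np.ndarray, field: MaterialField):
        F = self.deformation_gradients(u)
        P = pk1_stress(F, field).reshape(self.nel, self.nq, 3, 3)
        fe = np.einsum("eq,eqij,eqaj->eai", self.wdetJ, P, self.dNdX, optimize=True)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edof.reshape(self.nel, 10, 3).ravel(), fe.ravel())
        return f, F

    def stiffness(self, u: np.ndarray, field: MaterialField) -> sp.csr_matrix:
        F = self.deformation_gradients(u)
        A = pk1_tangent_fd(F, field).reshape(self.nel, self.nq, 3, 3, 3, 3)
        tmp = np.einsum("eq,eqaj,eqijkl->eqaikl", self.wdetJ, self.dNdX, A, optimize=True)
        Ke = np.einsum("eqaikl,eqbl->eaibk", tmp, self.dNdX, optimize=True).reshape(self.nel, 30, 30)
        K = sp.coo_matrix((Ke.ravel(), (self.rows, self.cols)),
                          shape=(self.ndof, self.ndof))
        return K.tocsr()

    def _face_forces(self, xf: np.ndarray, p_kpa: float) -> np.ndarray:
        """Nodal follower-pressure forces per face; traction -p on the outward normal.

        Units: kPa * mm^2 = mN.
        """
        t1 = np.einsum("qad,fai->qfdi", _FDN_QP, xf)[:, :, 0, :]
        t2 = np.einsum("qad,fai->qfdi", _FDN_QP, xf)[:, :, 1, :]
        nvec = np.cross(t1, t2)  # (3, nf, 3) area-weighted normal at face qps
        fe = -p_kpa * np.einsum("q,qa,qfi->fai", _FQW, _FN_QP, nvec)
        return fe

    def external_force(self, u: np.ndarray, p_kpa: float):
        xf = (self.mesh.nodes + u)[self.faces]  # (nf, 6, 3)
        fe = self._face_forces(xf, p_kpa)
        f = np.zeros(self.ndof)
        np.add.at(f, self.fdof.ravel(), fe.ravel())
        return f

    def load_stiffness(self, u: np.ndarray, p_kpa: float, h: float = 1e-6) -> sp.csr_matrix:
        """d f_ext / d u by central differences over the 18 face dofs."""
        xf = (self.mesh.nodes + u)[self.faces]
        nf = len(self.faces)
        Kp = np.empty((nf, 18, 18))
        for d in range(18):
            a, i = divmod(d, 3)
            dx = np.zeros_like(xf)
            dx[:, a, i] = h
            fp = self._face_forces(xf + dx, p_kpa).reshape(nf, 18)
            fm = self._face_forces(xf - dx, p_kpa).reshape(nf, 18)
            Kp[:, :, d] = (fp - fm) / (2.0 * h)
        return sp.coo_matrix((Kp.ravel(), (self.frows, self.fcols)),
                             shape=(self.ndof, self.ndof)).tocsr()

    def element_volume_change(self, u: np.ndarray) -> float:
        F = self.deformation_gradients(u).reshape(self.nel, self.nq, 3, 3)
        J = np.linalg.det(F)
        mean_dv = np.einsum("eq,eq->e", self.wdetJ, J - 1.0) / self.wdetJ.sum(axis=1)
        return float(np.max(np.abs(mean_dv)))

    def apex_node(self) -> int:
        ant = self.mesh.anterior
        lat = self.mesh.lateral_radius[ant]
        return int(ant[np.argmin(lat + 1e-9 * self.mesh.nodes[ant, 2])])


# ---------------------------------------------------------------------------


class KrylovSolver:
    """Sparse solver that reuses one LU factorization as a GMRES preconditioner.

    A full factorization of the tangent is expensive relative to assembly, but
    consecutive Newton (and pre-stress) tangents are close, so the frozen LU
    preconditions GMRES to convergence in a handful of iterations.  The
    factorization is refreshed when GMRES stalls.
    """

    def __init__(self, max_gmres: int = 20, rtol: float = 1e-7, slow_threshold: int = 10):
        self.lu = None
        self.max_gmres = max_gmres
        self.rtol = rtol
        self.slow_threshold = slow_threshold

    def refactorize(self, K: sp.csc_matrix):
        self.lu = splu(K.tocsc(), permc_spec="COLAMD",
                       options=dict(SymmetricMode=True))

    def solve(self, K: sp.spmatrix, b: np.ndarray) -> np.ndarray:
        if self.lu is None or self.lu.shape[0] != K.shape[0]:
            self.refactorize(K)
            return self.lu.solve(b)
        M = LinearOperator(K.shape, self.lu.solve)
        count = [0]
        x, info = gmres(K, b, M=M, rtol=self.rtol, atol=0.0,
                        restart=self.max_gmres, maxiter=1,
                        callback=lambda *_: count.__setitem__(0, count[0] + 1),
                        callback_type="pr_norm")
        if info != 0 or not np.isfinite(x).all():
            self.refactorize(K)
            return self.lu.solve(b)
        if count[0] > self.slow_threshold:
            # preconditioner has gone stale; refresh for the next solves
            self.refactorize(K)
        return x


def _newton(model: FEModel, field: MaterialField, u, p_kpa, tol, max_newton, history,
            linsolver: KrylovSolver | None = None):
    T = model.T
    fext_ref = model.external_force(np.zeros_like(u), abs(p_kpa) + MMHG_TO_KPA)
    ref = max(float(np.linalg.norm(T.T @ fext_ref)), 1e-12)

    def residual(uu):
        fint, _ = model.internal_force(uu, field)
        fext = model.external_force(uu, p_kpa)
        r = T.T @ (fint - fext)
        return r, float(np.linalg.norm(r))

    try:
        r, rn = residual(u)
    except FloatingPointError:
        return u, False
    for it in range(max_newton + 1):
        history.append((p_kpa, it, rn / ref))
        if not np.isfinite(rn):
            return u, False
        if rn <= tol * ref:
            return u, True
        if it == max_newton:
            return u, False
        K = model.stiffness(u, field) - model.load_stiffness(u, p_kpa)
        Kred = (T.T @ K @ T).tocsc()
        try:
            if linsolver is None:
                dq = splu(Kred, permc_spec="COLAMD").solve(-r)
            else:
                dq = linsolver.solve(Kred, -r)
        except Exception:
            return u, False
        if not np.isfinite(dq).all():
            return u, False
        du = (T @ dq).reshape(-1, 3)
        # guarded full step: Newton is allowed transient residual growth (the
        # volumetric penalty makes the landscape non-monotone) but backtracks
        # on element inversion or blow-up
        alpha = 1.0
        accepted = False
        for _ in range(6):
            try:
                r_try, rn_try = residual(u + alpha * du)
            except FloatingPointError:
                alpha *= 0.5
                continue
            if np.isfinite(rn_try) and rn_try <= 20.0 * rn:
                u = u + alpha * du
                r, rn = r_try, rn_try
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            return u, False
    return u, False


def inflate(mesh: CornealMesh, material, config: SolveConfig = SolveConfig(),
            u0: np.ndarray | None = None, model: FEModel | None = None,
            linsolver: KrylovSolver | None = None) -> SolveResult:
    """Inflate the posterior surface to the configured IOP.

    ``material`` may be a :class:`MaterialParams` (uniform apart from the
    depth scale), a prebuilt :class:`MaterialField`, or a callable
    ``model -> MaterialField``.
    """
    if model is None:
        model = FEModel(mesh, sliding=config.sliding)
    if isinstance(material, MaterialParams):
        field = model.material_field(material)
    elif callable(material):
        field = material(model)
    else:
        field = material

    p_total = config.pressure_kpa
    u = np.zeros_like(mesh.nodes) if u0 is None else u0.copy()
    if linsolver is None:
        linsolver = KrylovSolver()
    history: list = []
    warm_done = False
    if p_total == 0.0:
        u[:] = 0.0
        warm_done = True
    elif u0 is not None:
        # warm start: go straight for the target pressure from the guess
        # (worth a deeper Newton budget than one ramp level - the fallback
        # is a full cold ramp)
        u_trial, ok = _newton(model, field, u0, p_total, config.tol,
                              max(20, config.max_newton), history, linsolver)
        if ok:
            u = u_trial
            warm_done = True
        else:
            u = np.zeros_like(mesh.nodes)
    if not warm_done:
        p_done = 0.0
        dp = p_total / config.steps
        halvings = 0
        u_last, p_last = None, None  # previous converged state for extrapolation
        while p_done < p_total - 1e-12:
            p_try = min(p_done + dp, p_total)
            u_start = u
            if u_last is not None and p_try > p_done > p_last:
                # linear extrapolation of the load path as the initial guess
                frac = (p_try - p_done) / (p_done - p_last)
                u_start = u + frac * (u - u_last)
            u_trial, ok = _newton(model, field, u_start, p_try, config.tol,
                                  config.max_newton, history, linsolver)
            if ok:
                u_last, p_last = u, p_done
                u = u_trial
                p_done = p_try
                dp = min(dp * 1.5, p_total - p_done + 1e-30)
                halvings = 0  # budget is per load level, not cumulative
            else:
                dp /= 2.0
                halvings += 1
                if halvings > config.max_halvings:
                    raise SolverError(
                        f"no convergence after {halvings} step halvings at p={p_try:.4g} kPa",
                        history=history)

    apex = model.apex_node()
    return SolveResult(
        u=u, deformed=mesh.nodes + u,
        apex_displacement=float(np.linalg.norm(u[apex])),
        history=history,
        max_volume_change=model.element_volume_change(u),
        model=model,
    )


def find_stress_free(mesh: CornealMesh, material, config: SolveConfig = SolveConfig(),
                     tol_um: float = 1.0, max_iter: int = 20,
                     relax: float = 1.0, linsolver: KrylovSolver | None = None,
                     initial_reference_nodes: np.ndarray | None = None) -> PrestressResult:
    """Backward-displacement fixed point for the stress-free reference.

    Iterates X <- X_target - omega * U(X) until the re-inflated anterior
    surface matches the target geometry within ``tol_um``; ``omega`` starts
    at ``relax`` and is adapted by Aitken Delta-squared acceleration (soft
    corneas make the plain map oscillate).  ``material`` should be a
    callable ``model -> MaterialField`` (re-evaluated on each updated
    reference) or a :class:`MaterialParams`.
    """
    x_target = mesh.nodes.copy()
    ant = mesh.anterior
    cur = mesh
    if initial_reference_nodes is not None:
        cur = mesh.with_nodes(initial_reference_nodes)  # continuation hint
    trace = []
    u_prev = None
    err_prev = None
    prev_nodes = None
    bad_updates = 0
    omega = relax
    if linsolver is None:
        linsolver = KrylovSolver()

    # At limbus nodes only the blocked direction carries shape information:
    # in-surface slide is a free coordinate of the boundary condition, and
    # feeding it back into the update makes the rim ring drift indefinitely.
    limbus = mesh.limbus
    if len(limbus) and config.sliding == "slide":
        m = np.cross(mesh.limbus_dirs[limbus], mesh.limbus_tangents[limbus])
        m /= np.linalg.norm(m, axis=1)[:, None]
    else:
        m = None

    def shape_error(raw_err):
        err = raw_err.copy()
        if m is not None:
            err[limbus] = m * np.einsum("ij,ij->i", raw_err[limbus], m)[:, None]
        return err

    # loose equilibrium tolerance while the geometry is still far off; the
    # final accepted iterate is always solved at the configured tolerance
    loose = SolveConfig(iop_mmhg=config.iop_mmhg, steps=config.steps,
                        tol=max(config.tol, 1e-5), max_newton=config.max_newton,
                        max_halvings=config.max_halvings, sliding=config.sliding)
    tight_mode = loose.tol == config.tol
    for it in range(1, max_iter + 1):
        try:
            res = inflate(cur, material, config if tight_mode else loose,
                          u0=u_prev, linsolver=linsolver)
        except SolverError:
            # trial reference inverted or intractable: back off half-way
            bad_updates += 1
            if prev_nodes is None or bad_updates > 4:
                raise
            cur = mesh.with_nodes(0.5 * (cur.nodes + prev_nodes))
            u_prev = None
            continue
        u_prev = res.u
        err = shape_error(cur.nodes + res.u - x_target)
        resid_um = float(np.max(np.linalg.norm(err[ant], axis=1))) * 1000.0
        trace.append(resid_um)
        if resid_um <= 5.0 * tol_um:
            tight_mode = True
        if resid_um <= tol_um:
            if res.history and res.history[-1][2] > config.tol:
                res = inflate(cur, material, config, u0=u_prev, linsolver=linsolver)
                u_prev = res.u
                err = shape_error(cur.nodes + res.u - x_target)
                resid_um = float(np.max(np.linalg.norm(err[ant], axis=1))) * 1000.0
                trace[-1] = resid_um
                if resid_um > tol_um:
                    err_prev = err
                    cur = cur.with_nodes(cur.nodes - omega * err)
                    continue
            return PrestressResult(mesh=cur, solve=res, residual_um=resid_um,
                                   iterations=it, trace=trace)
        if err_prev is not None:
            d = (err - err_prev).ravel()
            denom = float(d @ d)
            if denom > 0:
                omega = -omega * float(err_prev.ravel() @ d) / denom
            omega = float(np.clip(omega, 0.1, 1.0))
        err_prev = err
        prev_nodes = cur.nodes
        cur = cur.with_nodes(cur.nodes - omega * err)
    raise SolverError(
        f"pre-stress fixed point did not reach {tol_um} µm in {max_iter} iterations "
        f"(trace: {['%.2f' % t for t in trace]})")


# ---------------------------------------------------------------------------


def fit_sphere_radius(points: np.ndarray) -> float:
    """Algebraic least-squares sphere radius of a point cloud (mm)."""
    pts = np.asarray(points, float)
    b = (pts**2).sum(axis=1)
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return float(math.sqrt(max((sol[:3] ** 2).sum() + sol[3], 0.0)))


def tangential_modulus_at_iop(mesh: CornealMesh, material, iop_mmhg: float = 15.0,
                              d_iop: float = 0.5,
                              config: SolveConfig = SolveConfig(sliding="pinned")) -> float:
    """Overall tangential modulus along the apical rise curve at ``iop_mmhg`` (kPa).

    Estimator (documented contract): two inflations at iop +/- d_iop give
    apical displacements u+/-; membrane stress sigma = p R / (2 t) with R the
    best-fit sphere radius of the deformed anterior surface (central 4 mm)
    and t the deformed central thickness; strain epsilon = u / R.  The
    modulus is the central-difference slope d sigma / d epsilon.

    Defaults to a pinned limbus: the curve emulates an ex vivo inflation
    test with the cornea clamped at the rim, the setting in which the CXL
    stiffening factor was calibrated.  Pass a config with sliding='slide'
    for the in vivo boundary condition.
    """
    lo = SolveConfig(iop_mmhg=iop_mmhg - d_iop, steps=config.steps, tol=config.tol,
                     max_newton=config.max_newton, sliding=config.sliding)
    hi = SolveConfig(iop_mmhg=iop_mmhg + d_iop, steps=1, tol=config.tol,
                     max_newton=config.max_newton, sliding=config.sliding)
    model = FEModel(mesh, sliding=config.sliding)
    linsolver = KrylovSolver()
    res_lo = inflate(mesh, material, lo, model=model, linsolver=linsolver)
    res_hi = inflate(mesh, material, hi, u0=res_lo.u, model=model, linsolver=linsolver)

    apex = model.apex_node()
    col = mesh.vertex_column[apex] if apex < mesh.n_vertices else None
    post_candidates = mesh.posterior[mesh.posterior < mesh.n_vertices]
    if col is not None:
        same_col = post_candidates[mesh.vertex_column[post_candidates] == col]
        post_apex = int(same_col[0]) if len(same_col) else int(post_candidates[
            np.argmin(mesh.lateral_radius[post_candidates])])
    else:
        post_apex = int(post_candidates[np.argmin(mesh.lateral_radius[post_candidates])])

    def state(res, p_mmhg):
        ant_pts = res.deformed[mesh.anterior]
        sel = np.hypot(ant_pts[:, 0], ant_pts[:, 1]) <= 2.0
        R = fit_sphere_radius(ant_pts[sel])
        t = float(np.linalg.norm(res.deformed[apex] - res.deformed[post_apex]))
        sigma = (p_mmhg * MMHG_TO_KPA) * R / (2.0 * t)
        return sigma, res.apex_displacement, R

    s_lo, u_lo, r_lo = state(res_lo, iop_mmhg - d_iop)
    s_hi, u_hi, r_hi = state(res_hi, iop_mmhg + d_iop)
    r_mid = 0.5 * (r_lo + r_hi)
    d_eps = (u_hi - u_lo) / r_mid
    if d_eps <= 0:
        raise SolverError("non-increasing apical rise over the probe window")
    return (s_hi - s_lo) / d_eps
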