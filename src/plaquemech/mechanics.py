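"""Thin-slice hyperelastic finite elements: wrap -> stretch -> pressurize.

The 0.5 mm 3-D thin slice is realised as 2-D generalized plane strain with a
uniform prescribed axial stretch lambda_z: shear-free axial kinematics make
the in-plane state of the slab identical to this far cheaper model.  The
solver is displacement-only with bilinear quadrilaterals; the volumetric
penalty is integrated at the element centroid while the deviatoric energy
uses 2x2 Gauss points (selective reduced integration, which avoids volumetric
locking with the nearly incompressible materials).

The three-step procedure starting from the zero-stress state is
    (a) wrap the opened sector closed (prescribed displacement of the two
        cut faces, then node-to-node tying and release -> residual stress),
    (b) stretch axially to the in vivo length,
    (c) pressurize the lumen (follower load) to recover the in vivo state.
No-residual-stress models start at (b) from the closed no-load mesh.

Element derivatives are computed by the complex-step method on the strain
energy (exact); the tangent stiffness by finite differencing of the exact
internal force.  Newton iterations use backtracking line search and
adaptive load-step halving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .geometry import Mesh, REGION_ID, REGION_NAMES
from .materials import MaterialParams, _EXP_CAP

_G = 1.0 / np.sqrt(3.0)
_QP_DEV = np.array([(-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G)])
_QP_VOL = np.array([(0.0, 0.0)])


def _shape_gradients(xi, eta):
    """dN/d(xi,eta) for the 4-node quad, (4, 2)."""
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


@dataclass
class LoadProtocol:
    """Loading programme for one model variant."""

    lambda_z: float = 1.0
    pressure_mmhg: float = 0.0
    pressure_steps: int = 4
    closure_steps: int = 4
    lambda_z_steps: int = 1

    def __post_init__(self) -> None:
        if self.lambda_z <= 0:
            raise ValueError("lambda_z must be positive")
        if self.pressure_mmhg < 0:
            raise ValueError("pressure must be non-negative")
        if min(self.pressure_steps, self.closure_steps, self.lambda_z_steps) < 1:
            raise ValueError("step counts must be >= 1")

    @property
    def pressure_kpa(self) -> float:
        from .materials import MMHG_TO_KPA
        return self.pressure_mmhg * MMHG_TO_KPA


@dataclass
class SolverConfig:
    newton_tolerance: float = 1e-8  # relative residual
    max_newton_iterations: int = 60
    line_search: bool = True
    max_step_halvings: int = 10
    fd_step: float = 1e-6  # tangent finite-difference step, mm
    # hourglass control (Flanagan-Belytschko): fraction of the volumetric
    # penalty assigned to the spurious modes that centroid-only integration
    # leaves unconstrained; essential for soft inclusions (lipid) embedded in
    # stiff wall, negligible for the wall layers themselves
    hourglass_alpha: float = 3e-3

    def __post_init__(self) -> None:
        if self.newton_tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SolvedState:
    """Converged equilibrium of one slice model at one load state."""

    mesh: Mesh
    displacements: np.ndarray  # (N, 2) mm
    lambda_z: float
    pressure_kpa: float
    cauchy: np.ndarray  # (E, 3, 3) kPa, quadrature-averaged
    green: np.ndarray  # (E, 3, 3) Green-Lagrange strain
    max_principal_stress: np.ndarray  # (E,) kPa
    max_principal_strain: np.ndarray  # (E,)
    J_min: float  # element dilatation range (volumetric quadrature points,
    J_max: float  # i.e. the quantity the penalty constrains)
    residual_norm: float
    reference: str  # "opened" | "closed"
    J_dev_min: float = 1.0  # pointwise J range at the 2x2 deviatoric points
    J_dev_max: float = 1.0  # (includes parasitic in-element modes; diagnostic)

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacements

    def lumen_centroid(self) -> np.ndarray:
        ids = np.unique(self.mesh.lumen_edges)
        return self.deformed_nodes[ids].mean(axis=0)

    def sigma_theta_theta(self) -> np.ndarray:
        """Circumferential Cauchy stress per element (deformed polar basis)."""
        cen = self.deformed_nodes[self.mesh.elems].mean(axis=1) - self.lumen_centroid()
        ang = np.arctan2(cen[:, 1], cen[:, 0])
        e = np.stack([-np.sin(ang), np.cos(ang)], axis=1)
        s2 = self.cauchy[:, :2, :2]
        return np.einsum("ei,eij,ej->e", e, s2, e)

    def lumen_circumference(self) -> float:
        x = self.deformed_nodes
        e = self.mesh.lumen_edges
        return float(np.sum(np.linalg.norm(x[e[:, 1]] - x[e[:, 0]], axis=1)))


def principal_fields(state: SolvedState):
    """Largest eigenvalue of Cauchy stress and Green-Lagrange strain per element."""
    return (np.linalg.eigvalsh(state.cauchy)[:, -1],
            np.linalg.eigvalsh(state.green)[:, -1])


class _Overflow(Exception):
    pass


class ThinSliceFE:
    """Generalized-plane-strain finite-element model of one slice."""

    def __init__(self, mesh: Mesh, materials: dict, config: SolverConfig | None = None):
        self.mesh = mesh
        self.config = config or SolverConfig()
        self.X = mesh.nodes.copy()
        self.elems = mesh.elems
        E = mesh.n_elems

        # per-element material parameter arrays
        names = mesh.region_names()
        def arr(attr):
            return np.array([getattr(materials[n], attr) for n in names])
        self.c1, self.c2 = arr("c1"), arr("c2")
        self.D1, self.D2 = arr("D1"), arr("D2")
        self.K1, self.K2 = arr("K1"), arr("K2")
        self.kappa = arr("kappa")
        self.K2safe = np.where(self.K2 > 0, self.K2, 1.0)
        phis = np.array([
            0.0 if materials[n].fiber_angle_deg is None else materials[n].fiber_angle_deg
            for n in names])
        self.has_fiber = np.array(
            [materials[n].K1 != 0.0 and materials[n].fiber_angle_deg is not None
             for n in names])
        # reference circumferential direction at element centroids
        origin = np.zeros(2) if not mesh.periodic else mesh.centroid
        cen = self.X[self.elems].mean(axis=1) - origin
        ang = np.arctan2(cen[:, 1], cen[:, 0])
        phi = np.deg2rad(phis)
        self.fiber2 = np.cos(phi)[:, None] * np.stack(
            [-np.sin(ang), np.cos(ang)], axis=1)  # in-plane part
        self.fiberz = np.sin(phi)

        # quadrature tables
        def tables(qps):
            dN = np.empty((E, len(qps), 4, 2))
            w = np.empty((E, len(qps)))
            Xe = self.X[self.elems]  # (E,4,2)
            for q, (xi, eta) in enumerate(qps):
                dNxi = _shape_gradients(xi, eta)  # (4,2): dN_a/dxi_k
                A = np.einsum("eaj,ak->ejk", Xe, dNxi)  # (E,2,2): dX_j/dxi_k
                det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
                inv = np.empty_like(A)  # A^-1: dxi_k/dX_j
                inv[:, 0, 0], inv[:, 1, 1] = A[:, 1, 1], A[:, 0, 0]
                inv[:, 0, 1], inv[:, 1, 0] = -A[:, 0, 1], -A[:, 1, 0]
                inv /= det[:, None, None]
                dN[:, q] = np.einsum("ak,ekj->eaj", dNxi, inv)
                w[:, q] = det
            return dN, w
        self.dN_dev, self.w_dev = tables(_QP_DEV)
        self.dN_vol, self.w_vol = tables(_QP_VOL)
        self.w_vol *= 4.0  # centroid rule carries the full parent-element weight

        # Flanagan-Belytschko hourglass base vectors (orthogonal to all
        # linear fields): gamma = h - (h.X) b_x - (h.Y) b_y
        h = np.array([1.0, -1.0, 1.0, -1.0])
        Xe = self.X[self.elems]
        bx = self.dN_vol[:, 0, :, 0]  # mean gradient vectors (E,4)
        by = self.dN_vol[:, 0, :, 1]
        hX = Xe[:, :, 0] @ h
        hY = Xe[:, :, 1] @ h
        self.hg_gamma = h[None, :] - hX[:, None] * bx - hY[:, None] * by
        self.hg_k = self.config.hourglass_alpha * self.kappa  # kPa, per element

        # dof bookkeeping
        N = mesh.n_nodes
        self.n_nodes = N
        self.fixed = np.zeros((N, 2), dtype=bool)
        self.uval = np.zeros((N, 2))
        self.master = np.arange(N)  # tie map: slave -> master
        self.tie_offset = np.zeros((N, 2))  # u_slave = u_master + offset
        self._dofmap = None

        self.u = np.zeros((N, 2))
        self.lambda_z = 1.0
        self.pressure_kpa = 0.0
        self.residual_norm = np.inf
        # optional stabilizing spring toward a predictor displacement field
        # (used by the closure continuation; zero stiffness = inactive)
        self.spring_k = 0.0
        self.spring_target = np.zeros((N, 2))

        # element scatter indices for assembly
        dofs = np.stack([2 * self.elems, 2 * self.elems + 1], axis=-1).reshape(E, 8)
        self._rows = np.repeat(dofs, 8, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 8)).ravel()
        self._edofs = dofs

    # ------------------------------------------------------------- constraints
    def clear_constraints(self) -> None:
        self.fixed[:] = False

    def prescribe(self, nodes, values) -> None:
        """Fully prescribe the displacement of the given nodes."""
        self.fixed[nodes] = True
        self.uval[nodes] = values
        self._dofmap = None

    def fix_dof(self, node: int, dim: int, value: float) -> None:
        self.fixed[node, dim] = True
        self.uval[node, dim] = value
        self._dofmap = None

    def tie(self, slaves, masters) -> None:
        """Tie slave nodes to masters so their positions coincide permanently:
        u_slave = u_master + (X_master - X_slave)."""
        slaves = np.asarray(slaves)
        masters = np.asarray(masters)
        self.master[slaves] = masters
        self.tie_offset[slaves] = self.X[masters] - self.X[slaves]
        self._dofmap = None

    def _build_dofmap(self):
        """Map (node, dim) -> reduced dof index (-1 for prescribed)."""
        N = self.n_nodes
        dofmap = -np.ones((N, 2), dtype=np.int64)
        idx = 0
        is_master = self.master == np.arange(N)
        for n in range(N):
            if not is_master[n]:
                continue
            for d in range(2):
                if not self.fixed[n, d]:
                    dofmap[n, d] = idx
                    idx += 1
        # slaves inherit the master's dofs
        dofmap[~is_master] = dofmap[self.master[~is_master]]
        self._dofmap = dofmap
        self._n_red = idx
        return dofmap

    @property
    def dofmap(self):
        if self._dofmap is None:
            self._build_dofmap()
        return self._dofmap

    def _full_u(self, u):
        """Resolve prescriptions and ties into a full (N,2) displacement."""
        out = u.copy()
        is_master = self.master == np.arange(self.n_nodes)
        fm = self.fixed & is_master[:, None]
        out[fm] = self.uval[fm]
        slaves = np.nonzero(~is_master)[0]
        out[slaves] = out[self.master[slaves]] + self.tie_offset[slaves]
        return out

    # ------------------------------------------------------------- energetics
    def _energy_dev(self, F11, F12, F21, F22, lam_z, active=None):
        """Deviatoric energy density per (batch, element, qp).

        ``active`` optionally freezes the fiber-recruitment switch to a
        base-state mask; the tangent assembly uses this so that real-step
        perturbations cannot flip the recruitment branch (the complex-step
        residual is branch-frozen by construction), keeping the tangent
        consistent at states sitting exactly on the I4 = 1 kink.
        """
        detF2 = F11 * F22 - F12 * F21
        J = detF2 * lam_z
        if np.any(J.real <= 0):
            raise _Overflow("negative Jacobian")
        C11 = F11 * F11 + F21 * F21
        C22 = F12 * F12 + F22 * F22
        C12 = F11 * F12 + F21 * F22
        lz2 = lam_z * lam_z
        I1 = C11 + C22 + lz2
        trC2 = C11 * C11 + C22 * C22 + 2.0 * C12 * C12 + lz2 * lz2
        I2 = 0.5 * (I1 * I1 - trC2)
        Jm23 = J ** (-2.0 / 3.0)
        I1b = Jm23 * I1
        I2b = Jm23 * Jm23 * I2
        c1 = self.c1[:, None]
        c2 = self.c2[:, None]
        D1 = self.D1[:, None]
        D2 = self.D2[:, None]
        arg = D2 * (I1b - 3.0)
        if np.any(arg.real > _EXP_CAP):
            raise _Overflow("matrix exponential overflow")
        W = c1 * (I1b - 3.0) + c2 * (I2b - 3.0) + D1 * (np.exp(arg) - 1.0)
        if np.any(self.has_fiber):
            ax = self.fiber2[:, 0][:, None]
            ay = self.fiber2[:, 1][:, None]
            az = self.fiberz[:, None]
            I4 = (ax * (C11 * ax + C12 * ay) + ay * (C12 * ax + C22 * ay)
                  + az * az * lz2)
            I4b = Jm23 * I4
            e4 = I4b - 1.0
            arg4 = self.K2safe[:, None] * e4 * e4
            if np.any(arg4.real > _EXP_CAP):
                raise _Overflow("fiber exponential overflow")
            if active is None:
                act = (I4b.real > 1.0) & self.has_fiber[:, None]
            else:
                act = active & self.has_fiber[:, None]
            Wf = (self.K1[:, None] / self.K2safe[:, None]) * (np.exp(arg4) - 1.0)
            W = W + np.where(act, Wf, 0.0)
        return W

    def _energy_vol(self, F11, F12, F21, F22, lam_z):
        J = (F11 * F22 - F12 * F21) * lam_z
        return 0.5 * self.kappa[:, None] * (J - 1.0) ** 2

    def _piola(self, u_e, lam_z, dN, energy, **energy_kw):
        """In-plane first Piola stress per (B, E, nq, 2, 2) via complex step."""
        # F2d = I + u_a (x) dN_a
        G = np.einsum("...eai,eqaj->...eqij", u_e, dN)
        F = np.empty((4,) + G.shape, dtype=complex)
        F[...] = G
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        h = 1e-20
        for k, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            F[k, ..., i, j] += 1j * h
        W = energy(F[..., 0, 0], F[..., 0, 1], F[..., 1, 0], F[..., 1, 1],
                   lam_z, **energy_kw)
        return np.moveaxis(W.imag / h, 0, -1).reshape(G.shape)

    def fiber_activation(self, u_full, lam_z):
        """Base-state fiber recruitment mask (E, nq) at the dev points."""
        G = np.einsum("eai,eqaj->eqij", u_full[self.elems], self.dN_dev)
        F11 = G[..., 0, 0] + 1.0
        F22 = G[..., 1, 1] + 1.0
        F12, F21 = G[..., 0, 1], G[..., 1, 0]
        J = (F11 * F22 - F12 * F21) * lam_z
        C11 = F11 * F11 + F21 * F21
        C22 = F12 * F12 + F22 * F22
        C12 = F11 * F12 + F21 * F22
        ax = self.fiber2[:, 0][:, None]
        ay = self.fiber2[:, 1][:, None]
        az = self.fiberz[:, None]
        I4 = ax * (C11 * ax + C12 * ay) + ay * (C12 * ax + C22 * ay) \
            + az * az * lam_z**2
        return J ** (-2.0 / 3.0) * I4 > 1.0

    def element_internal_forces(self, u_e, lam_z, active=None):
        """Element nodal forces (B, E, 4, 2) from element displacements."""
        P = self._piola(u_e, lam_z, self.dN_dev, self._energy_dev, active=active)
        f = np.einsum("...eqij,eqaj,eq->...eai", P, self.dN_dev, self.w_dev)
        Pv = self._piola(u_e, lam_z, self.dN_vol, self._energy_vol)
        f = f + np.einsum("...eqij,eqaj,eq->...eai", Pv, self.dN_vol, self.w_vol)
        if self.config.hourglass_alpha > 0.0:
            q = np.einsum("...eai,ea->...ei", u_e, self.hg_gamma)  # hourglass amp
            f = f + (self.hg_k[:, None] * q)[..., None, :] * \
                self.hg_gamma[..., :, None]
        return f

    # ------------------------------------------------------------- assembly
    def _internal(self, u_full, lam_z):
        u_e = u_full[self.elems]  # (E,4,2)
        fe = self.element_internal_forces(u_e[None], lam_z)[0]  # (E,4,2)
        f = np.zeros((self.n_nodes, 2))
        np.add.at(f, self.elems, fe)
        scale = float(np.sqrt(np.sum(fe**2)))
        return f, scale

    def _pressure_forces(self, u_full, pressure):
        """Follower pressure load on the lumen edges (deformed geometry)."""
        f = np.zeros((self.n_nodes, 2))
        if pressure == 0.0:
            return f
        x = self.X + u_full
        e = self.mesh.lumen_edges
        t = x[e[:, 1]] - x[e[:, 0]]  # CCW tangent
        # deformed wetted area per unit reference thickness carries lambda_z
        fe = 0.5 * pressure * self.lambda_z * np.stack([t[:, 1], -t[:, 0]], axis=1)
        np.add.at(f, e[:, 0], fe)
        np.add.at(f, e[:, 1], fe)
        return f

    def _reduce(self, f):
        """Assemble nodal forces into the reduced dof vector."""
        dofmap = self.dofmap
        r = np.zeros(self._n_red)
        m = dofmap >= 0
        np.add.at(r, dofmap[m], f[m])
        return r

    def residual(self, u_red):
        """Reduced residual f_int - f_ext and a reference force scale."""
        u_full = self._expand(u_red)
        fint, scale = self._internal(u_full, self.lambda_z)
        fext = self._pressure_forces(u_full, self.pressure_kpa)
        f = fint - fext
        if self.spring_k > 0.0:
            f = f + self.spring_k * (u_full - self.spring_target)
        R = self._reduce(f)
        ref = max(scale, float(np.linalg.norm(fext)), 1e-6)
        return R, ref

    def _expand(self, u_red):
        dofmap = self.dofmap
        u = np.zeros((self.n_nodes, 2))
        m = dofmap >= 0
        u[m] = u_red[dofmap[m]]
        return self._full_u(u)

    def _collapse(self, u_full):
        """Extract the reduced vector consistent with a full displacement."""
        dofmap = self.dofmap
        u_red = np.zeros(self._n_red)
        is_master = self.master == np.arange(self.n_nodes)
        m = (dofmap >= 0) & is_master[:, None]
        u_red[dofmap[m]] = u_full[m]
        return u_red

    def tangent(self, u_red):
        """Reduced tangent stiffness by forward differences of element forces."""
        h = self.config.fd_step
        u_full = self._expand(u_red)
        u_e = u_full[self.elems]  # (E,4,2)
        B = np.broadcast_to(u_e, (9,) + u_e.shape).copy()
        for k in range(8):
            a, i = divmod(k, 2)
            B[k, :, a, i] += h
        # freeze the fiber-recruitment branch at the base state so the
        # perturbed evaluations stay consistent with the residual's gradient
        active = self.fiber_activation(u_full, self.lambda_z)
        fe = self.element_internal_forces(B, self.lambda_z, active=active)
        Ke = np.empty((self.mesh.n_elems, 8, 8))
        for k in range(8):
            Ke[:, :, k] = (fe[k] - fe[8]).reshape(-1, 8) / h
        K = sparse.coo_matrix(
            (Ke.ravel(), (self._rows, self._cols)),
            shape=(2 * self.n_nodes, 2 * self.n_nodes)).tocsr()

        if self.pressure_kpa != 0.0:
            K = K + self._pressure_tangent(u_full)
        if self.spring_k > 0.0:
            K = K + self.spring_k * sparse.identity(2 * self.n_nodes, format="csr")
        # reduce: map full dofs to reduced
        dofmap_flat = self.dofmap.ravel()
        keep = dofmap_flat >= 0
        T = sparse.coo_matrix(
            (np.ones(keep.sum()), (np.nonzero(keep)[0], dofmap_flat[keep])),
            shape=(2 * self.n_nodes, self._n_red)).tocsr()
        return (T.T @ K @ T).tocsr()

    def _pressure_tangent(self, u_full):
        """-d f_ext/du for the follower pressure load (analytic, edge-local)."""
        p = self.pressure_kpa * self.lambda_z
        e = self.mesh.lumen_edges
        ne = e.shape[0]
        # f_n1 = f_n2 = p/2 * (y2-y1, x1-x2); derivative w.r.t. (x1,y1,x2,y2)
        dfe = np.zeros((4, 4))
        dfe[0, 3], dfe[0, 1] = 0.5 * p, -0.5 * p   # dfx/dy2, dfx/dy1
        dfe[1, 0], dfe[1, 2] = 0.5 * p, -0.5 * p   # dfy/dx1, dfy/dx2
        dfe[2, :] = dfe[0, :]
        dfe[3, :] = dfe[1, :]
        # residual = fint - fext, so tangent contribution is -dfe
        dofs = np.empty((ne, 4), dtype=np.int64)
        dofs[:, 0] = 2 * e[:, 0]
        dofs[:, 1] = 2 * e[:, 0] + 1
        dofs[:, 2] = 2 * e[:, 1]
        dofs[:, 3] = 2 * e[:, 1] + 1
        rows = np.repeat(dofs, 4, axis=1).ravel()
        cols = np.tile(dofs, (1, 4)).ravel()
        vals = np.tile(-dfe.ravel(), ne)
        return sparse.coo_matrix(
            (vals, (rows, cols)),
            shape=(2 * self.n_nodes, 2 * self.n_nodes)).tocsr()

    # ------------------------------------------------------------- Newton
    def solve_equilibrium(self) -> None:
        """Modified Newton iteration at the current constraint/load state.

        The tangent is refactorized only when convergence slows (residual
        reduction factor above 0.3), which roughly halves assembly cost on
        the smooth load steps of the three-step procedure.
        """
        cfg = self.config
        u_red = self._collapse(self.u)
        R, ref = self.residual(u_red)
        norm0 = np.linalg.norm(R)
        lu = None
        fresh = False
        prev_norm = np.inf
        for it in range(cfg.max_newton_iterations):
            # absolute floor: forces below 1e-9 kPa*mm are numerically zero
            # (covers load-free states, e.g. pure axial stretch of a uniform
            # ring, whose in-plane element forces vanish identically)
            if norm0 <= max(cfg.newton_tolerance * ref, 1e-9):
                break
            if lu is None or norm0 > 0.3 * prev_norm:
                lu = sparse.linalg.splu(self.tangent(u_red).tocsc())
                fresh = True
            prev_norm = norm0
            du = lu.solve(-R)
            step = 1.0
            ok = False
            for _ in range(12 if cfg.line_search else 1):
                try:
                    R_new, ref_new = self.residual(u_red + step * du)
                    norm_new = np.linalg.norm(R_new)
                except _Overflow:
                    norm_new = np.inf
                if (norm_new < norm0 and np.isfinite(norm_new)) or not cfg.line_search:
                    ok = np.isfinite(norm_new)
                    break
                step *= 0.5
            if not ok:
                if not fresh:
                    lu = None  # stale tangent: refactorize and retry
                    continue
                # Levenberg-style damping: the tangent can be inconsistent at
                # the fiber-recruitment kink (I4 = 1); shift the diagonal and
                # retry until a descent direction appears
                K = self.tangent(u_red)
                mu = 1e-3 * float(np.median(np.abs(K.diagonal())))
                while mu < 1e5 * float(np.median(np.abs(K.diagonal()))) and not ok:
                    Kd = (K + mu * sparse.identity(K.shape[0], format="csr"))
                    du = sparse.linalg.splu(Kd.tocsc()).solve(-R)
                    try:
                        R_new, ref_new = self.residual(u_red + du)
                        norm_new = np.linalg.norm(R_new)
                        ok = norm_new < norm0 and np.isfinite(norm_new)
                    except _Overflow:
                        ok = False
                    mu *= 10.0
                if not ok:
                    raise RuntimeError(
                        f"Newton line search stalled at iteration {it} "
                        f"(residual {norm0:.3e}, ref {ref:.3e})")
                step = 1.0
                lu = None  # force refactorization after a damped step
            fresh = False
            u_red = u_red + step * du
            R, ref, norm0 = R_new, ref_new, norm_new
        else:
            raise RuntimeError(
                f"Newton did not converge in {cfg.max_newton_iterations} "
                f"iterations (relative residual {norm0 / ref:.3e})")
        self.u = self._expand(u_red)
        self.residual_norm = norm0 / ref

    # ------------------------------------------------------------- outputs
    def evaluate_state(self, reference: str) -> SolvedState:
        u_e = self.u[self.elems]
        G = np.einsum("eai,eqaj->eqij", u_e, self.dN_dev)  # (E,nq,2,2)
        F2 = G.copy()
        F2[..., 0, 0] += 1.0
        F2[..., 1, 1] += 1.0
        lam_z = self.lambda_z
        J = (F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]) * lam_z
        # constrained dilatation: J at the volumetric (centroid) points
        Gv = np.einsum("eai,eqaj->eqij", u_e, self.dN_vol)
        Fv = Gv.copy()
        Fv[..., 0, 0] += 1.0
        Fv[..., 1, 1] += 1.0
        Jv = (Fv[..., 0, 0] * Fv[..., 1, 1] - Fv[..., 0, 1] * Fv[..., 1, 0]) * lam_z
        # per-qp Cauchy stress from the complex-step Piola stress
        P = self._piola(u_e[None], lam_z, self.dN_dev, self._energy_dev)[0]
        Pv = self._piola(u_e[None], lam_z, self.dN_vol, self._energy_vol)[0]
        # volumetric part evaluated at centroid; broadcast to the dev points
        P = P + Pv  # (E,nq,2,2) + (E,1,2,2)
        sig2 = np.einsum("eqij,eqkj->eqik", P, F2) / J[..., None, None]
        # axial stress from dW/dlambda_z (uniform thickness-direction stretch)
        h = 1e-20
        Wz = (self._energy_dev(F2[..., 0, 0].astype(complex),
                               F2[..., 0, 1].astype(complex),
                               F2[..., 1, 0].astype(complex),
                               F2[..., 1, 1].astype(complex), lam_z + 1j * h)
              + self._energy_vol(F2[..., 0, 0].astype(complex),
                                 F2[..., 0, 1].astype(complex),
                                 F2[..., 1, 0].astype(complex),
                                 F2[..., 1, 1].astype(complex), lam_z + 1j * h))
        sig_zz = lam_z * (Wz.imag / h) / J

        cauchy = np.zeros((self.mesh.n_elems, 3, 3))
        cauchy[:, :2, :2] = 0.5 * (sig2 + np.swapaxes(sig2, -1, -2)).mean(axis=1)
        cauchy[:, 2, 2] = sig_zz.mean(axis=1)

        C2 = np.einsum("eqji,eqjk->eqik", F2, F2)
        green = np.zeros((self.mesh.n_elems, 3, 3))
        green[:, :2, :2] = 0.5 * (C2.mean(axis=1) - np.eye(2))
        green[:, 2, 2] = 0.5 * (lam_z**2 - 1.0)

        state = SolvedState(
            mesh=self.mesh,
            displacements=self.u.copy(),
            lambda_z=lam_z,
            pressure_kpa=self.pressure_kpa,
            cauchy=cauchy,
            green=green,
            max_principal_stress=np.linalg.eigvalsh(cauchy)[:, -1],
            max_principal_strain=np.linalg.eigvalsh(green)[:, -1],
            J_min=float(Jv.min()),
            J_max=float(Jv.max()),
            residual_norm=float(self.residual_norm),
            reference=reference,
            J_dev_min=float(J.min()),
            J_dev_max=float(J.max()),
        )
        return state

    def reaction_summary(self):
        """Net reaction force and moment about the slice centre (equilibrium check)."""
        fint, _ = self._internal(self._full_u(self.u), self.lambda_z)
        fext = self._pressure_forces(self._full_u(self.u), self.pressure_kpa)
        r = fint - fext
        x = self.X + self.u
        c = x.mean(axis=0)
        net_force = r.sum(axis=0)
        rel = x - c
        net_moment = float(np.sum(rel[:, 0] * r[:, 1] - rel[:, 1] * r[:, 0]))
        return net_force, net_moment


# ----------------------------------------------------------------- procedures
def _fix_rigid_modes(model: ThinSliceFE) -> None:
    """Pin translations and rotation of a free closed ring (3 constraints)."""
    mesh = model.mesh
    a = int(mesh.lumen_edges[0, 0])
    model.fix_dof(a, 0, model.u[a, 0])
    model.fix_dof(a, 1, model.u[a, 1])
    x = model.X + model.u
    lumen_nodes = np.unique(mesh.lumen_edges)
    b = int(lumen_nodes[np.argmax(np.linalg.norm(x[lumen_nodes] - x[a], axis=1))])
    lever = x[b] - x[a]
    dim = 1 if abs(lever[0]) >= abs(lever[1]) else 0  # perpendicular component
    model.fix_dof(b, dim, model.u[b, dim])


def _partial_close_positions(mesh: Mesh, t: float) -> np.ndarray:
    """Analytic wrap predictor: the opening map at intermediate sector angle.

    t = 0 returns the opened reference positions, t = 1 the closed ring.
    """
    sector = mesh.sector_angle + t * (2 * np.pi - mesh.sector_angle)
    rel = mesh.closed_nodes - mesh.centroid
    r = np.hypot(rel[:, 0], rel[:, 1])
    th = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    # the seam column was built at theta = 2*pi exactly
    seam = np.zeros(mesh.n_nodes, dtype=bool)
    seam[mesh.cut_face_b] = True
    th[seam] = 2 * np.pi
    r_m = mesh.midwall_radius_closed
    k = 2 * np.pi / sector
    R = np.sqrt((k * r_m) ** 2 + k * (r**2 - r_m**2))
    Th = th / k
    return np.stack([R * np.cos(Th), R * np.sin(Th)], axis=1)


def _incremental_wrap(model: ThinSliceFE, mesh: Mesh, closure_steps: int) -> None:
    """Drive the cut faces to coincidence by incremental prescribed
    displacements along the analytic partial-closing map, equilibrating the
    interior at each increment (adaptive step halving)."""
    faces = np.concatenate([mesh.cut_face_a, mesh.cut_face_b])
    t, dt = 0.0, 1.0 / closure_steps
    u_corr = np.zeros_like(model.u)
    halvings = 0
    while t < 1.0 - 1e-12:
        t_try = min(t + dt, 1.0)
        pos = _partial_close_positions(mesh, t_try)
        u_prev = model.u.copy()
        model.u = (pos - model.X) + u_corr
        model.clear_constraints()
        model.prescribe(faces, pos[faces] - model.X[faces])
        try:
            model.solve_equilibrium()
        except (RuntimeError, _Overflow):
            halvings += 1
            if halvings > model.config.max_step_halvings:
                raise RuntimeError(
                    f"sector closure failed at wrap fraction {t_try:.3f}")
            dt *= 0.5
            model.u = u_prev
            continue
        t = t_try
        u_corr = model.u - (pos - model.X)
    model.clear_constraints()


def _release_with_continuation(model: ThinSliceFE) -> None:
    """Equilibrate the tied ring, stabilizing with a decaying spring.

    A spring of stiffness k pulls every node toward the current predictor;
    k is reduced tenfold per solve (raised again on failure) until a plain
    k = 0 solve converges, so the final state is the true equilibrium.
    """
    try:
        model.solve_equilibrium()
        return
    except (RuntimeError, _Overflow):
        pass
    model.spring_target = model.u.copy()
    k_scale = float(np.median(_tangent_diag_scale(model)))
    k = 0.1 * k_scale
    k_floor = 1e-6 * k_scale
    u_best = model.u.copy()
    attempts = 0
    while attempts < 40:
        attempts += 1
        model.spring_k = max(k, 0.0)
        try:
            model.solve_equilibrium()
        except (RuntimeError, _Overflow):
            model.u = u_best.copy()
            k = k * 5.0 if k > 0 else k_floor * 5.0
            if k > 10.0 * k_scale:
                model.spring_k = 0.0
                raise RuntimeError("sector release failed: spring continuation "
                                   "could not stabilize the wrap")
            continue
        u_best = model.u.copy()
        model.spring_target = model.u.copy()  # re-anchor to the converged state
        if model.spring_k == 0.0:
            return
        k = 0.0 if k <= k_floor else k / 10.0
    model.spring_k = 0.0
    raise RuntimeError("sector release failed: continuation budget exhausted")


def _tangent_diag_scale(model: ThinSliceFE):
    """Positive diagonal entries of the current tangent (spring sizing)."""
    K = model.tangent(model._collapse(model.u))
    d = np.abs(K.diagonal())
    return d[d > 0]


def close_sector(mesh: Mesh, materials: dict, config: SolverConfig | None = None,
                 closure_steps: int = 4) -> ThinSliceFE:
    """Wrap an opened zero-stress sector closed: the residual-stress state.

    The cut faces are brought to coincidence along the analytic closing map,
    tied node-to-node and released with zero external traction; because the
    material is hyperelastic the released equilibrium is path-independent,
    so the wrap is applied kinematically in one shot and relaxed (with a
    decaying-spring continuation when the soft-inclusion states make the
    one-shot relaxation diverge), falling back to the incremental
    prescribed-displacement wrap.  Returns the model holding the
    self-equilibrated no-load state.
    """
    if mesh.cut_face_a is None:
        raise ValueError("mesh has no cut faces; build it from an opened sector")
    config = config or SolverConfig()
    model = ThinSliceFE(mesh, materials, config)
    pos = _partial_close_positions(mesh, 1.0)
    model.u = pos - model.X
    model.tie(mesh.cut_face_b, mesh.cut_face_a)
    _fix_rigid_modes(model)
    try:  # one-shot kinematic wrap + relaxation (path independence)
        model.solve_equilibrium()
        return model
    except (RuntimeError, _Overflow):
        pass
    # fallback 1: incremental wrap with interior equilibration, then release
    try:
        model = ThinSliceFE(mesh, materials, config)
        _incremental_wrap(model, mesh, closure_steps)
        model.tie(mesh.cut_face_b, mesh.cut_face_a)
        _fix_rigid_modes(model)
        model.solve_equilibrium()
        return model
    except (RuntimeError, _Overflow):
        pass
    # fallback 2: decaying-spring continuation from the kinematic wrap
    model = ThinSliceFE(mesh, materials, config)
    model.u = pos - model.X
    model.tie(mesh.cut_face_b, mesh.cut_face_a)
    _fix_rigid_modes(model)
    _release_with_continuation(model)
    return model


def run_three_step(mesh: Mesh, materials: dict, protocol: LoadProtocol,
                   config: SolverConfig | None = None) -> SolvedState:
    """Execute wrap -> axial stretch -> pressurize and return the final state.

    ``mesh`` is an opened sector (residual-stress variants; reference =
    zero-stress state) or a closed ring (no-residual variants; reference =
    no-load state, steps (b)-(c) only).
    """
    config = config or SolverConfig()
    reference = "opened" if mesh.cut_face_a is not None else "closed"
    if reference == "opened":
        model = close_sector(mesh, materials, config, protocol.closure_steps)
    else:
        model = ThinSliceFE(mesh, materials, config)
        _fix_rigid_modes(model)

    # (b) axial stretch (adaptive ramp).  Each increment is warm-started with
    # the incompressible homogeneous contraction x -> c + (x - c)/sqrt(ratio),
    # which leaps over the weakly non-convex neighbourhood of the reference
    # state (the printed c1 < 0 makes the tangent indefinite there) straight
    # into the stable working regime.
    lz_now, dlz = 1.0, (protocol.lambda_z - 1.0) / protocol.lambda_z_steps
    halvings = 0
    u_save = model.u.copy()
    while abs(lz_now - protocol.lambda_z) > 1e-14 and dlz != 0.0:
        lz_try = lz_now + dlz
        if (protocol.lambda_z - lz_try) * np.sign(dlz) < 0:
            lz_try = protocol.lambda_z
        x = model.X + model.u
        c = x[np.unique(mesh.lumen_edges)].mean(axis=0)
        model.u = (c + (x - c) / np.sqrt(lz_try / lz_now)) - model.X
        # rigid-mode pins are pure gauge: move them with the warm start so
        # the predictor stays kinematically compatible
        model.uval[model.fixed] = model.u[model.fixed]
        model.lambda_z = lz_try
        try:
            # plain Newton first; the spring continuation handles the weakly
            # indefinite tangent near the reference on fine meshes
            _release_with_continuation(model)
            lz_now = lz_try
            u_save = model.u.copy()
        except (RuntimeError, _Overflow):
            halvings += 1
            if halvings > config.max_step_halvings:
                raise RuntimeError(
                    f"axial stretch ramp failed at lambda_z = {lz_try:.4f}")
            dlz *= 0.5
            model.u = u_save.copy()
    model.lambda_z = protocol.lambda_z

    # (c) pressure ramp (follower load), adaptive halving on divergence
    target = protocol.pressure_kpa
    p = 0.0
    dp = target / protocol.pressure_steps if target > 0 else 0.0
    halvings = 0
    u_save = model.u.copy()
    while p < target - 1e-12:
        p_try = min(p + dp, target)
        model.pressure_kpa = p_try
        try:
            model.solve_equilibrium()
            p = p_try
            u_save = model.u.copy()
        except (RuntimeError, _Overflow):
            halvings += 1
            if halvings > config.max_step_halvings:
                raise RuntimeError(
                    f"pressure ramp failed; last converged pressure {p:.3f} kPa")
            dp *= 0.5
            model.u = u_save.copy()
    model.pressure_kpa = target
    return model.evaluate_state(reference)
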