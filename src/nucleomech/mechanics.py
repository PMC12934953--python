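"""Quasi-static incompressible Mooney-Rivlin mechanics of the NE shell.

The shell is discretized with Taylor-Hood elements (quadratic displacements,
linear pressure) on curved tetrahedra. The mixed weak form is the perturbed
Lagrangian

    int grad(v) : P dV + int q (phi0 (J - 1) + p) dV - external work = 0,

with strain energy W = Escale (E1 (I1 - 3) + E2 (I2 - 3)) - p (J - 1), so the
Lagrange-multiplier pressure satisfies p = -phi0 (J - 1) weakly and phi0 sets
the (large) effective bulk modulus. External loads are follower loads on the
deformed surface: osmotic pressure dP on the inner sphere, the actin-cap
stress profile on the outer sphere (directed along -z), and the steric
nanopillar repulsion weighted by the smooth pillar indicator. Substrate-floor
contact is an active-set Dirichlet condition on z-displacement, and the apex
roof patch can be pinned to the stretch-weighted average of the previous
z-displacement over the surrounding annulus (a stabilization of the flat
apex region under cap load).

Volume integrals use analytic consistent tangents; the (cheap) surface-load
tangents are assembled by per-face central differences, which leaves Newton
convergence intact at the tolerances used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import TRI_EDGES, p1_tet_shape, p2_tet_shape, p2_tri_shape, tet_quadrature, tri_quadrature
from .geometry import (
    NanopillarArraySpec,
    ReferenceMesh,
    pillar_indicator_smooth,
    tangent_frame,
)

__all__ = [
    "MaterialParams",
    "LoadState",
    "KinematicsBundle",
    "MechanicalSolution",
    "MechanicsProblem",
    "NewtonError",
    "cap_stress_schedule",
    "cap_stress_profile",
    "contact_repulsion",
    "update_pressure",
    "mooney_rivlin_piola",
    "mooney_rivlin_tangent",
]

DZ_BILAYER = 0.05  # double bilayer + perinuclear space thickness (um)


class NewtonError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive and contact constants (Pa and um)."""

    E1: float = 5000.0
    E2: float = 1000.0
    phi0: float = 1.0e8
    phi_inner: float = 100.0
    Pmax: float = 820.0
    sigma_contact0: float = 1000.0
    dsteric: float = 0.2
    Z0: float = 2.05
    E1_nuc: float = 5000.0
    phi_nuc: float = 1.0e5

    def __post_init__(self):
        for name in ("E1", "E2", "phi0", "phi_inner", "E1_nuc", "phi_nuc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LoadState:
    """Instantaneous load amplitudes."""

    sigma_cap: float = 0.0
    dP: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        if self.sigma_cap < 0:
            raise ValueError("sigma_cap must be nonnegative")


@dataclass
class KinematicsBundle:
    """Deformation measures at shell quadrature points and on the outer surface."""

    F: np.ndarray  # (ne, nq, 3, 3)
    J: np.ndarray  # (ne, nq)
    I1: np.ndarray
    I2: np.ndarray
    Finv: np.ndarray
    # outer surface (per face quadrature point)
    alpha_outer: np.ndarray | None = None  # (nf, nqs)
    n_outer: np.ndarray | None = None  # (nf, nqs, 3)


@dataclass
class MechanicalSolution:
    """Converged mixed solution plus scalar measures of the deformed state."""

    U: np.ndarray  # (n_nodes, 3) shell P2 displacements
    P: np.ndarray  # (n_pverts,) pressure multipliers
    load: LoadState
    vol_nuc: float
    area_outer: float
    area_inner: float
    shell_vol_dev: float  # |int J dV - V_ref| / V_ref
    active_floor: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    u_nuc: np.ndarray | None = None  # (n_vertices, 3) nucleoplasm extension
    newton_iters: int = 0


def cap_stress_schedule(t: float, sigma_max: float, t0_cap: float) -> float:
    """Saturating cap-assembly schedule sigma_max (1 - exp(-t/t0))."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return float(sigma_max * (1.0 - np.exp(-t / t0_cap)))


def cap_stress_profile(Z, sigma_cap: float, Z0: float, znuc: float, R0: float):
    """Cap stress magnitude at material height Z: peaks at the apex Z=znuc+2 R0."""
    Z = np.asarray(Z, dtype=float)
    return sigma_cap * np.exp((Z - (znuc + 2.0 * R0)) / Z0)


def contact_repulsion(z_def, sigma_contact0: float, dsteric: float):
    """Steric repulsion magnitude at deformed height z above the pillar-top plane."""
    z_def = np.asarray(z_def, dtype=float)
    return sigma_contact0 * np.exp(-(z_def - dsteric) / dsteric)


def update_pressure(dP_prev: float, vol_nuc: float, vol_nuc_prev: float, phi_inner: float) -> float:
    """Osmotic-pressure feedback: penalize nucleoplasm volume change."""
    if vol_nuc <= 0:
        raise ValueError("vol_nuc must be positive")
    return float(dP_prev - phi_inner * (vol_nuc - vol_nuc_prev) / vol_nuc)


# ---------------------------------------------------------------------------
# constitutive pointwise kernels (vectorized over leading axes)

def mooney_rivlin_piola(F, p, E1, E2, escale=1.0):
    """First Piola-Kirchhoff stress of W = Es(E1(I1-3)+E2(I2-3)) - p(J-1).

    F has shape (..., 3, 3); p and escale broadcast over the leading axes.
    Returns (P, J, Finv, I1, I2).
    """
    F = np.asarray(F, dtype=float)
    C = np.einsum("...ji,...jk->...ik", F, F)
    I1 = np.einsum("...ii->...", C)
    I2 = 0.5 * (I1**2 - np.einsum("...ij,...ji->...", C, C))
    J = np.linalg.det(F)
    Finv = np.linalg.inv(F)
    FiT = np.swapaxes(Finv, -1, -2)
    es = np.asarray(escale, dtype=float)[..., None, None] if np.ndim(escale) else escale
    FC = np.einsum("...ij,...jk->...ik", F, C)
    P = es * (2.0 * E1 * F + 2.0 * E2 * (I1[..., None, None] * F - FC))
    P = P - (np.asarray(p)[..., None, None] * J[..., None, None]) * FiT
    return P, J, Finv, I1, I2


def mooney_rivlin_tangent(F, p, J, Finv, I1, E1, E2, escale=1.0):
    """Material tangent A_ijkl = dP_ij/dF_kl for the same energy."""
    d = np.eye(3)
    C = np.einsum("...ji,...jk->...ik", F, F)
    B = np.einsum("...ij,...kj->...ik", F, F)
    FiT = np.swapaxes(Finv, -1, -2)
    es = np.asarray(escale, dtype=float)
    if np.ndim(es):
        es = es[..., None, None, None, None]
    A = 2.0 * E1 * np.einsum("ik,jl->ijkl", d, d) + 2.0 * E2 * (
        2.0 * np.einsum("...ij,...kl->...ijkl", F, F)
        + I1[..., None, None, None, None] * np.einsum("ik,jl->ijkl", d, d)
        - np.einsum("ik,...lj->...ijkl", d, C)
        - np.einsum("...il,...kj->...ijkl", F, F)
        - np.einsum("...ik,jl->...ijkl", B, d)
    )
    A = es * A
    pJ = (np.asarray(p) * J)[..., None, None, None, None]
    A = A - pJ * (
        np.einsum("...ij,...kl->...ijkl", FiT, FiT)
        - np.einsum("...il,...kj->...ijkl", FiT, FiT)
    )
    return A


# ---------------------------------------------------------------------------


class MechanicsProblem:
    """Assembled shell problem bound to one reference mesh.

    Parameters
    ----------
    mesh : ReferenceMesh
    material : MaterialParams
    pillars : NanopillarArraySpec or None
        None disables all substrate terms (free shell).
    contact_mode : {"ez", "normal"}
        Direction of the pillar repulsion: along +z (default, the printed
        weak-form variant) or along the inward deformed normal.
    flat_floor_repulsion : bool
        On a flat substrate apply the steric repulsion with indicator == 1 in
        addition to the floor Dirichlet active set.
    """

    def __init__(
        self,
        mesh: ReferenceMesh,
        material: MaterialParams,
        pillars: NanopillarArraySpec | None = None,
        quad_degree: int = 2,
        contact_mode: str = "ez",
        flat_floor_repulsion: bool = False,
        newton_rtol: float = 1e-9,
        newton_maxit: int = 30,
    ):
        self.mesh = mesh
        self.material = material
        self.pillars = pillars
        self.contact_mode = contact_mode
        self.flat_floor_repulsion = flat_floor_repulsion
        self.newton_rtol = newton_rtol
        self.newton_maxit = newton_maxit
        self._setup(quad_degree)

    # -- setup ------------------------------------------------------------
    def _setup(self, quad_degree: int):
        mesh = self.mesh
        nv = mesh.n_vertices
        st = mesh.shell_tets
        # compact node numbering: vertices of shell tets, then shell edges
        used_v = np.unique(st)
        self.vmap = -np.ones(nv, dtype=np.int64)
        self.vmap[used_v] = np.arange(len(used_v))
        self.used_vertices = used_v
        ne_edges = len(mesh.edges)
        self.n_vnodes = len(used_v)
        self.n_nodes = len(used_v) + ne_edges
        self.n_p = len(used_v)

        conn_v = self.vmap[st]
        conn_e = self.n_vnodes + mesh.tet_edges
        self.conn = np.hstack([conn_v, conn_e])  # (ne, 10)
        self.pconn = conn_v  # (ne, 4)

        # reference coordinates of compact nodes
        self.node_X = np.vstack(
            [mesh.points[used_v], mesh.p2_points[nv:]]
        )  # (n_nodes, 3)

        pts, w = tet_quadrature(quad_degree)
        N2, dN2 = p2_tet_shape(pts)
        N1, _ = p1_tet_shape(pts)
        self.N1 = N1
        Xe = self.node_X[self.conn]  # (ne,10,3)
        Jgeo = np.einsum("qad,nak->nqkd", dN2, Xe)  # dX_k/dxi_d
        detJ = np.linalg.det(Jgeo)
        if detJ.min() <= 0:
            raise RuntimeError("negative reference Jacobian in shell mesh")
        Jinv = np.linalg.inv(Jgeo)
        self.dNdX = np.einsum("qad,nqdk->nqak", dN2, Jinv)  # (ne,nq,10,3)
        self.wdet = detJ * w  # (ne,nq)
        self.V_ref = float(self.wdet.sum())
        self.escale_elem = np.ones(len(st))

        # sparse scatter pattern for the coupled (3u + p) system
        ndof_u = 3 * self.n_nodes
        self.ndof = ndof_u + self.n_p
        edof = np.concatenate(
            [
                (3 * self.conn[:, :, None] + np.arange(3)).reshape(len(st), 30),
                ndof_u + self.pconn,
            ],
            axis=1,
        )  # (ne, 34)
        self.edof = edof
        self.Krow = np.repeat(edof, 34, axis=1).ravel()
        self.Kcol = np.tile(edof, (1, 34)).ravel()

        self._setup_faces(quad_degree)
        self._setup_node_classes()
        self._setup_nucleoplasm()

    def _face_conn(self, vert_ids: np.ndarray) -> np.ndarray:
        """P2 connectivity (compact node ids) of surface triangles."""
        mesh = self.mesh
        edge_lookup = {tuple(e): i for i, e in enumerate(map(tuple, mesh.edges))}
        tris = vert_ids[mesh.surf_tris]  # (nf,3) global vertex ids
        conn = np.empty((len(tris), 6), dtype=np.int64)
        conn[:, :3] = self.vmap[tris]
        for k, (a, b) in enumerate(TRI_EDGES):
            pairs = np.sort(tris[:, [a, b]], axis=1)
            conn[:, 3 + k] = [
                self.n_vnodes + edge_lookup[tuple(p)] for p in pairs
            ]
        return conn

    def _setup_faces(self, quad_degree: int):
        mesh = self.mesh
        self._surf_qn = max(3, quad_degree + 1)
        spts, sw = tri_quadrature(self._surf_qn)
        self._surf_qp = spts
        self.sN, self.sdN = p2_tri_shape(spts)
        self.sw = sw
        self.fconn_outer = self._face_conn(mesh.outer_verts)
        self.fconn_inner = self._face_conn(mesh.inner_verts)
        # reference face geometry and outward orientation signs
        for tag, fconn in (("outer", self.fconn_outer), ("inner", self.fconn_inner)):
            Xf = self.node_X[fconn]  # (nf,6,3)
            pos = np.einsum("qa,fak->fqk", self.sN, Xf)
            t1 = np.einsum("qa,fak->fqk", self.sdN[:, :, 0], Xf)
            t2 = np.einsum("qa,fak->fqk", self.sdN[:, :, 1], Xf)
            cr = np.cross(t1, t2)
            radial = pos - mesh.center
            s = np.sign(np.einsum("fqk,fqk->fq", cr, radial).sum(axis=1))
            if tag == "inner":
                s = -s  # outward of the shell domain points toward the centre
            setattr(self, f"sign_{tag}", s)
            setattr(self, f"Xq_{tag}", pos)
            area = np.einsum("q,fq->", self.sw, np.linalg.norm(cr, axis=2) * 1.0)
            setattr(self, f"area_ref_{tag}", float(abs(area)))
            crs = cr * s[:, None, None]
            setattr(self, f"crref_{tag}", crs)

    def _setup_node_classes(self):
        mesh = self.mesh
        X = self.node_X
        tol = 1e-9
        self.nodes_x0 = np.where(np.abs(X[:, 0]) < tol)[0]
        self.nodes_y0 = np.where(np.abs(X[:, 1]) < tol)[0]
        zc = mesh.center[2]
        self.nodes_equator = np.where(np.abs(X[:, 2] - zc) < 1e-9)[0]
        # outer-surface nodes (for floor contact), and roof sets
        outer_nodes = np.unique(self.fconn_outer)
        self.outer_nodes = outer_nodes
        apex_vid = mesh.outer_verts[mesh.apex_column]
        apex_node = self.vmap[apex_vid]
        touch = np.any(self.fconn_outer[:, :3] == apex_node, axis=1)
        self.roof_faces1 = np.where(touch)[0]
        self.roof_nodes1 = np.unique(self.fconn_outer[touch])
        rho = np.hypot(self.Xq_outer[..., 0], self.Xq_outer[..., 1])
        d_roof = mesh.spec.d_roof
        upper = (rho <= d_roof).all(axis=1) & (
            self.Xq_outer[..., 2].mean(axis=1) > mesh.center[2]
        )
        self.roof_faces2 = np.where(upper & ~touch)[0]
        # contact candidate faces: lower hemisphere
        self.contact_faces = np.where(
            self.Xq_outer[..., 2].mean(axis=1) < mesh.center[2]
        )[0]

    def _setup_nucleoplasm(self):
        mesh = self.mesh
        nt = mesh.nuc_tets
        used = np.unique(nt)
        self.nuc_vmap = -np.ones(mesh.n_vertices, dtype=np.int64)
        self.nuc_vmap[used] = np.arange(len(used))
        self.nuc_used = used
        self.nuc_conn = self.nuc_vmap[nt]
        X = mesh.points[used]
        self.nuc_X = X
        v0 = mesh.points[nt[:, 0]]
        M = np.stack([mesh.points[nt[:, k]] - v0 for k in (1, 2, 3)], axis=-1)
        det = np.linalg.det(M)
        self.nuc_w = det / 6.0
        Minv = np.linalg.inv(M)
        dref = np.array(
            [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        # dN_a/dX_k = dref_ad (M^-1)_dk, constant per tet: (nt,4,3)
        self.nuc_dNdX = np.einsum("ad,ndk->nak", dref, Minv)
        tol = 1e-9
        inner_set = set(mesh.inner_verts.tolist())
        self.nuc_dirichlet = np.array(
            [i for i, g in enumerate(used) if g in inner_set], dtype=np.int64
        )
        self.nuc_x0 = np.where(np.abs(X[:, 0]) < tol)[0]
        self.nuc_y0 = np.where(np.abs(X[:, 1]) < tol)[0]

    # -- kinematics and fields --------------------------------------------
    def deformation(self, U: np.ndarray):
        F = np.eye(3) + np.einsum("nqaj,nai->nqij", self.dNdX, U[self.conn])
        return F

    def compute_kinematics(self, U: np.ndarray) -> KinematicsBundle:
        F = self.deformation(U)
        J = np.linalg.det(F)
        if J.min() <= 0:
            raise NewtonError("inverted element (J <= 0)")
        Finv = np.linalg.inv(F)
        C = np.einsum("nqji,nqjk->nqik", F, F)
        I1 = np.einsum("nqii->nq", C)
        I2 = 0.5 * (I1**2 - np.einsum("nqij,nqji->nq", C, C))
        crd, crr = self._outer_cross(U)
        a_def = np.linalg.norm(crd, axis=2)
        a_ref = np.linalg.norm(crr, axis=2)
        alpha = a_def / a_ref
        n = crd / a_def[..., None]
        return KinematicsBundle(F=F, J=J, I1=I1, I2=I2, Finv=Finv, alpha_outer=alpha, n_outer=n)

    def _outer_cross(self, U, which="outer"):
        fconn = getattr(self, f"fconn_{which}")
        sgn = getattr(self, f"sign_{which}")
        xdef = self.node_X[fconn] + U[fconn]
        t1 = np.einsum("qa,fak->fqk", self.sdN[:, :, 0], xdef)
        t2 = np.einsum("qa,fak->fqk", self.sdN[:, :, 1], xdef)
        cr = np.cross(t1, t2) * sgn[:, None, None]
        return cr, getattr(self, f"crref_{which}")

    def surface_measures(self, U):
        """Deformed outer/inner areas and nucleoplasm volume (quarter domain)."""
        cro, _ = self._outer_cross(U, "outer")
        area_outer = float(np.einsum("q,fq->", self.sw, np.linalg.norm(cro, axis=2)))
        cri, _ = self._outer_cross(U, "inner")
        area_inner = float(np.einsum("q,fq->", self.sw, np.linalg.norm(cri, axis=2)))
        xdef = self.node_X[self.fconn_inner] + U[self.fconn_inner]
        pos = np.einsum("qa,fak->fqk", self.sN, xdef)
        # cri points outward of the shell = toward the centre; nucleoplasm
        # outward normal is the opposite
        vol = -float(np.einsum("q,fqk,fqk->", self.sw, pos, cri)) / 3.0
        return area_outer, area_inner, vol

    def shell_volume_deviation(self, U):
        F = self.deformation(U)
        J = np.linalg.det(F)
        V = float((J * self.wdet).sum())
        return abs(V - self.V_ref) / self.V_ref

    def set_stiffness_scale(self, escale_elem: np.ndarray | float):
        self.escale_elem = np.broadcast_to(
            np.asarray(escale_elem, dtype=float), (len(self.conn),)
        ).copy()

    # -- assembly ----------------------------------------------------------
    def _volume_residual_tangent(self, U, Pv, want_tangent=True):
        mat = self.material
        F = self.deformation(U)
        J = np.linalg.det(F)
        if J.min() <= 0:
            raise NewtonError("inverted element (J <= 0)")
        pq = np.einsum("qa,na->nq", self.N1, Pv[self.pconn])
        es = self.escale_elem[:, None]
        Ppk, J, Finv, I1, I2 = mooney_rivlin_piola(F, pq, mat.E1, mat.E2, es)
        FiT = np.swapaxes(Finv, -1, -2)

        Ru_e = np.einsum("nqij,nqaj,nq->nai", Ppk, self.dNdX, self.wdet)
        rp = mat.phi0 * (J - 1.0) + pq
        Rp_e = np.einsum("nq,qa,nq->na", rp, self.N1, self.wdet)

        R = np.zeros(self.ndof)
        np.add.at(R, 3 * self.conn[:, :, None] + np.arange(3), Ru_e)
        np.add.at(R, 3 * self.n_nodes + self.pconn, Rp_e)
        if not want_tangent:
            return R, None

        A = mooney_rivlin_tangent(F, pq, J, Finv, I1, mat.E1, mat.E2, es)
        JFiT = J[..., None, None] * FiT
        ne = len(self.conn)
        K = np.zeros((ne, 34, 34))
        T = np.einsum("nqijkl,nqbl,nq->nqijbk", A, self.dNdX, self.wdet, optimize=True)
        Kuu = np.einsum("nqaj,nqijbk->naibk", self.dNdX, T, optimize=True)
        K[:, :30, :30] = Kuu.reshape(ne, 30, 30)
        Kup = -np.einsum(
            "nqij,nqaj,qb,nq->naib", JFiT, self.dNdX, self.N1, self.wdet, optimize=True
        )
        K[:, :30, 30:] = Kup.reshape(ne, 30, 4)
        Kpu = self.material.phi0 * np.einsum(
            "qa,nqkl,nqbl,nq->nabk", self.N1, JFiT, self.dNdX, self.wdet, optimize=True
        )
        K[:, 30:, :30] = Kpu.reshape(ne, 4, 30)
        Kpp = np.einsum("qa,qb,nq->nab", self.N1, self.N1, self.wdet)
        K[:, 30:, 30:] = Kpp
        return R, K

    # surface load residual on a face set given deformed face coords
    def _face_load_residual(self, xdef, which, load: LoadState, faces=None):
        """R_ext contributions (nf,6,3) of follower loads on one face family."""
        sN, sdN, sw = self.sN, self.sdN, self.sw
        t1 = np.einsum("qa,fak->fqk", sdN[:, :, 0], xdef)
        t2 = np.einsum("qa,fak->fqk", sdN[:, :, 1], xdef)
        mesh = self.mesh
        if which == "inner":
            cr = np.cross(t1, t2) * self.sign_inner[:, None, None]
            # traction -dP * n_hat on the shell side of the cavity wall
            Rf = -load.dP * np.einsum("q,qa,fqk->fak", sw, sN, cr)
            return Rf
        # outer: cap stress and pillar repulsion
        sgn = self.sign_outer if faces is None else self.sign_outer[faces]
        cr = np.cross(t1, t2) * sgn[:, None, None]
        Rf = np.zeros_like(xdef)
        Zq = (self.Xq_outer if faces is None else self.Xq_outer[faces])[..., 2]
        if load.sigma_cap > 0:
            prof = cap_stress_profile(
                Zq, load.sigma_cap, self.material.Z0, mesh.spec.znuc, mesh.spec.R0
            )
            amag = np.linalg.norm(cr, axis=2)
            Rf[..., 2] += -np.einsum("q,fq,fq,qa->fa", sw, prof, amag, sN)
        if self._contact_active():
            pos = np.einsum("qa,fak->fqk", sN, xdef)
            sig = contact_repulsion(
                pos[..., 2], self.material.sigma_contact0, self.material.dsteric
            )
            if self.pillars is not None and not self.pillars.flat:
                h = pillar_indicator_smooth(
                    pos[..., 0].ravel(), pos[..., 1].ravel(), self.pillars
                ).reshape(sig.shape)
            else:
                h = 1.0  # flat substrate: steric floor everywhere
            w = sig * h
            if self.contact_mode == "normal":
                Rf += -np.einsum("q,fq,fqk,qa->fak", sw, w, cr, sN)
            else:  # +z variant
                amag = np.linalg.norm(cr, axis=2)
                Rf[..., 2] += np.einsum("q,fq,fq,qa->fa", sw, w, amag, sN)
        return Rf

    def _contact_active(self):
        if self.pillars is None:
            return False
        if self.pillars.flat:
            return self.flat_floor_repulsion
        return True

    def _surface_loads(self, U, load: LoadState, want_tangent=True):
        """Assemble external-load residual R_ext and its tangent (COO parts)."""
        R = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        specs = [("inner", self.fconn_inner, None)]
        cf = self.contact_faces if self._contact_active() else None
        if load.sigma_cap > 0 or self._contact_active():
            specs.append(("outer", self.fconn_outer, None))
        for which, fconn, faces in specs:
            if which == "outer" and load.sigma_cap == 0 and self._contact_active():
                fconn = self.fconn_outer[self.contact_faces]
                faces = self.contact_faces
            xdef = self.node_X[fconn] + U[fconn]
            Rf = self._face_load_residual(xdef, which, load, faces)
            np.add.at(R, 3 * fconn[:, :, None] + np.arange(3), Rf)
            if not want_tangent:
                continue
            nf = len(fconn)
            Kf = np.zeros((nf, 18, 18))
            h = 1e-6
            for a in range(6):
                for i in range(3):
                    xp = xdef.copy()
                    xp[:, a, i] += h
                    Rp = self._face_load_residual(xp, which, load, faces)
                    xp[:, a, i] -= 2 * h
                    Rm = self._face_load_residual(xp, which, load, faces)
                    Kf[:, :, 3 * a + i] = (Rp - Rm).reshape(nf, 18) / (2 * h)
            fd = (3 * fconn[:, :, None] + np.arange(3)).reshape(nf, 18)
            rows.append(np.repeat(fd, 18, axis=1).ravel())
            cols.append(np.tile(fd, (1, 18)).ravel())
            vals.append(Kf.ravel())
        if want_tangent and rows:
            Kext = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.ndof, self.ndof),
            ).tocsr()
        else:
            Kext = None
        return R, Kext

    # -- boundary conditions ------------------------------------------------
    def _dirichlet(self, phase, roof_uz, active_floor, floor_targets):
        """(dof indices, target values) for all Dirichlet conditions."""
        dofs = [3 * self.nodes_x0 + 0, 3 * self.nodes_y0 + 1]
        vals = [np.zeros(len(self.nodes_x0)), np.zeros(len(self.nodes_y0))]
        if phase == "inflate":
            dofs.append(3 * self.nodes_equator + 2)
            vals.append(np.zeros(len(self.nodes_equator)))
        if roof_uz is not None:
            dofs.append(3 * self.roof_nodes1 + 2)
            vals.append(np.full(len(self.roof_nodes1), roof_uz))
        if len(active_floor):
            dofs.append(3 * active_floor + 2)
            vals.append(floor_targets)
        dofs = np.concatenate(dofs)
        vals = np.concatenate(vals)
        # deduplicate (roof nodes may also lie on symmetry planes etc.)
        uniq, idx = np.unique(dofs, return_index=True)
        return uniq, vals[idx]

    def roof_average_uz(self, U):
        """Stretch-weighted average of u_z over the roof annulus."""
        if len(self.roof_faces2) == 0:
            return float(U[self.roof_nodes1, 2].mean())
        fconn = self.fconn_outer[self.roof_faces2]
        xdef = self.node_X[fconn] + U[fconn]
        t1 = np.einsum("qa,fak->fqk", self.sdN[:, :, 0], xdef)
        t2 = np.einsum("qa,fak->fqk", self.sdN[:, :, 1], xdef)
        amag = np.linalg.norm(np.cross(t1, t2), axis=2)
        uzq = np.einsum("qa,fa->fq", self.sN, U[fconn][:, :, 2])
        num = np.einsum("q,fq,fq->", self.sw, amag, uzq)
        den = np.einsum("q,fq->", self.sw, amag)
        return float(num / den)

    # -- Newton solve -------------------------------------------------------
    def solve_equilibrium(
        self,
        load: LoadState,
        prev: MechanicalSolution | None = None,
        phase: str = "compress",
        roof_uz: float | None = None,
        max_retries: int = 4,
    ) -> MechanicalSolution:
        """Solve the mixed equilibrium at the given loads.

        ``phase='inflate'`` pins u_z on the equator ring (removes the free
        rigid translation of the unloaded shell); ``phase='compress'`` applies
        the roof condition (if ``roof_uz`` given) and the floor active set.
        Newton divergence triggers load-increment halving from ``prev``.
        """
        U0 = prev.U.copy() if prev is not None else np.zeros((self.n_nodes, 3))
        P0 = prev.P.copy() if prev is not None else np.zeros(self.n_p)
        active = prev.active_floor.copy() if prev is not None else np.zeros(0, np.int64)
        base = prev.load if prev is not None else LoadState()
        targets = [(load, 1.0)]
        attempt = 0
        while targets:
            cur, frac = targets.pop()
            mix = lambda a, b: a + frac * (b - a)
            step_load = LoadState(
                sigma_cap=mix(base.sigma_cap, load.sigma_cap),
                dP=mix(base.dP, load.dP),
                t=load.t,
            )
            try:
                U0, P0, active, iters = self._newton(
                    U0, P0, step_load, phase, roof_uz, active
                )
            except NewtonError:
                attempt += 1
                if attempt > max_retries:
                    raise
                targets.append((load, frac))
                targets.append((load, frac / 2.0))
                continue
            if frac >= 1.0:
                break
            base = replace(step_load)
            targets.append((load, 1.0))
        area_o, area_i, vol = self.surface_measures(U0)
        return MechanicalSolution(
            U=U0,
            P=P0,
            load=load,
            vol_nuc=vol,
            area_outer=area_o,
            area_inner=area_i,
            shell_vol_dev=self.shell_volume_deviation(U0),
            active_floor=active,
            newton_iters=iters,
        )

    def _floor_z(self):
        return -(self.pillars.h_np if self.pillars is not None else 0.0)

    def _newton(self, U, Pv, load, phase, roof_uz, active):
        """Newton iteration with in-loop floor active-set updates.

        Dirichlet targets enter as affine constraints of the linear solve
        (dx on fixed dofs equals the remaining boundary gap), so the
        inversion-backtracking step scaling applies to boundary moves too.
        Penetrating nodes are pinned as they are found; pinned nodes with an
        adhesive reaction are released once the residual is nearly converged.
        """
        floor_on = self.pillars is not None
        zfloor = self._floor_z()

        def floor_targets(act):
            return zfloor - self.node_X[act, 2]

        # seed: if a downward cap load exists on a flat substrate with an
        # empty active set, put the lowest outer node on the floor (removes
        # the rigid-body mode before contact establishes)
        if (
            floor_on
            and self.pillars.flat
            and not self.flat_floor_repulsion
            and len(active) == 0
            and load.sigma_cap > 0
        ):
            zb = self.node_X[self.outer_nodes, 2] + U[self.outer_nodes, 2]
            low = self.outer_nodes[np.argmin(zb)]
            U = U.copy()
            U[:, 2] += zfloor - zb.min()
            active = np.array([low], dtype=np.int64)

        x = np.concatenate([U.ravel(), Pv])
        norm0 = None
        lu = None
        K = None
        lu_free = None
        rn_prev = None
        for it in range(self.newton_maxit):
            U = x[: 3 * self.n_nodes].reshape(-1, 3)
            Pv = x[3 * self.n_nodes :]
            R_int, _ = self._volume_residual_tangent(U, Pv, want_tangent=False)
            R_ext, _ = self._surface_loads(U, load, want_tangent=False)
            R = R_int - R_ext
            if floor_on:
                zdef = self.node_X[self.outer_nodes, 2] + U[self.outer_nodes, 2]
                viol = self.outer_nodes[zdef < zfloor - 1e-6]
                release = np.zeros(0, np.int64)
                if len(active) and norm0 is not None and \
                        np.linalg.norm(R[self._free_mask(active, phase, roof_uz)]) < 1e-2 * norm0:
                    reaction = R[3 * active + 2]
                    release = active[reaction < -1e-8]
                new_active = np.setdiff1d(np.union1d(active, viol), release)
                if (
                    len(new_active) == 0
                    and roof_uz is None
                    and phase == "compress"
                    and self.pillars.flat
                    and not self.flat_floor_repulsion
                ):
                    # keep the lowest node pinned as a vertical gauge: with no
                    # roof pin an unloaded resting shell has a free rigid mode
                    zb = self.node_X[self.outer_nodes, 2] + U[self.outer_nodes, 2]
                    new_active = np.array(
                        [self.outer_nodes[np.argmin(zb)]], dtype=np.int64
                    )
                if not np.array_equal(new_active, np.sort(active)):
                    active = new_active
                    lu = None  # constraint set changed; stale factorization
            fixed, fvals = self._dirichlet(
                phase, roof_uz, active, floor_targets(active)
            )
            free = np.ones(self.ndof, dtype=bool)
            free[fixed] = False
            bc_gap = fvals - x[fixed]
            rn = np.linalg.norm(R[free])
            scale = max(np.linalg.norm(R_ext), 1.0)
            if norm0 is None:
                norm0 = max(rn, scale)
            gap = float(np.abs(bc_gap).max()) if len(bc_gap) else 0.0
            if rn < self.newton_rtol * norm0 + 1e-10 and gap < 1e-9:
                return U, Pv, active, it
            # modified Newton: refactor only when contraction stalls
            if lu is None or (rn_prev is not None and rn > 0.3 * rn_prev):
                _, K_int = self._volume_residual_tangent(U, Pv)
                _, K_ext = self._surface_loads(U, load)
                K = sp.coo_matrix(
                    (K_int.ravel(), (self.Krow, self.Kcol)),
                    shape=(self.ndof, self.ndof),
                ).tocsr()
                if K_ext is not None:
                    K = K - K_ext
                try:
                    lu = spla.splu(K[free][:, free].tocsc())
                except RuntimeError as exc:
                    raise NewtonError(f"linear solve failed: {exc}") from exc
                lu_free = free
            rn_prev = rn
            # cap the boundary correction applied in one iteration
            bc_step = np.clip(bc_gap, -0.05, 0.05)
            rhs = -R[free] - K[free][:, fixed] @ bc_step
            dx = np.zeros(self.ndof)
            dx[free] = lu.solve(rhs)
            dx[fixed] = bc_step
            # full Newton step; backtrack only on element inversion
            # (the residual norm may rise transiently under follower loads)
            step = 1.0
            for _ in range(8):
                xt = x + step * dx
                Ut = xt[: 3 * self.n_nodes].reshape(-1, 3)
                if np.linalg.det(self.deformation(Ut)).min() > 0:
                    break
                step *= 0.5
            else:
                raise NewtonError("cannot avoid element inversion")
            x = xt
            if rn > 1e7 * norm0:
                raise NewtonError("Newton divergence")
        raise NewtonError("Newton did not converge")

    def _free_mask(self, active, phase, roof_uz):
        fixed, _ = self._dirichlet(
            phase, roof_uz, active, np.zeros(len(active))
        )
        free = np.ones(self.ndof, dtype=bool)
        free[fixed] = False
        return free

    # -- pressure feedback loop --------------------------------------------
    def equilibrate_pressure(
        self,
        load: LoadState,
        prev: MechanicalSolution,
        phase: str = "compress",
        roof_uz: float | None = None,
        rtol: float = 0.01,
        max_iter: int = 40,
        refresh_roof: bool = True,
    ) -> MechanicalSolution:
        """Alternate equilibrium solves with the osmotic-pressure update until
        the pressure changes by less than ``rtol`` (1% by default).

        With ``refresh_roof`` the roof pin follows the annulus average of the
        current iterate; otherwise the supplied value is held fixed.
        """
        mat = self.material
        dP = load.dP
        vol_prev = prev.vol_nuc
        sol = prev
        trace = []
        for it in range(max_iter):
            sol = self.solve_equilibrium(
                LoadState(sigma_cap=load.sigma_cap, dP=dP, t=load.t),
                prev=sol,
                phase=phase,
                roof_uz=roof_uz,
            )
            if roof_uz is not None and refresh_roof:
                # refresh the roof pin from the current iterate: the apex
                # tracks the annulus within the fixed-point loop instead of
                # lagging a full time step behind it
                roof_uz = self.roof_average_uz(sol.U)
            dP_new = update_pressure(dP, sol.vol_nuc, vol_prev, mat.phi_inner)
            trace.append((dP, sol.vol_nuc))
            vol_prev = sol.vol_nuc
            if it > 0 and abs(dP_new - dP) < rtol * max(abs(dP), 1.0):
                # keep the (dP, displacement) pair actually solved: carrying
                # the trailing update forward would re-perturb the volume on
                # the soft part of the inflation curve at every call
                return sol
            dP = dP_new
        raise NewtonError(f"pressure loop did not converge; trace={trace[-5:]}")

    # -- nucleoplasm extension ----------------------------------------------
    def extend_displacement_to_nucleoplasm(
        self, U: np.ndarray, guess: np.ndarray | None = None
    ) -> np.ndarray:
        """Compressible neo-Hookean extension of u into the nucleoplasm.

        Returns displacements on all mesh vertices (zeros outside the
        nucleoplasm closure); matches u on the inner surface exactly.
        """
        mesh = self.mesh
        mat = self.material
        nvert = len(self.nuc_used)
        bvals = U[self.vmap[self.nuc_used[self.nuc_dirichlet]]]
        fixed_dofs = [3 * self.nuc_dirichlet + k for k in range(3)]
        fixed_dofs.append(3 * self.nuc_x0 + 0)
        fixed_dofs.append(3 * self.nuc_y0 + 1)
        fixed = np.unique(np.concatenate(fixed_dofs))
        ndof = 3 * nvert
        free = np.ones(ndof, dtype=bool)
        free[fixed] = False
        conn = self.nuc_conn
        dNdX = self.nuc_dNdX
        w = self.nuc_w
        E1n, phin = mat.E1_nuc, mat.phi_nuc
        edof = (3 * conn[:, :, None] + np.arange(3)).reshape(-1, 12)
        rows = np.repeat(edof, 12, axis=1).ravel()
        cols = np.tile(edof, (1, 12)).ravel()
        d = np.eye(3)
        force_scale = max(E1n * abs(float(self.nuc_w.sum())), 1.0)

        # radial initial guess: scale the inner-surface displacement of each
        # column down the layers (vertex id = layer * n_cols + column)
        ncols = len(mesh.unit_dirs)
        u_guess = np.zeros((nvert, 3))
        gids = self.nuc_used
        layered = gids < len(mesh.layer_radii) * ncols
        vcols = gids[layered] % ncols
        vradii = mesh.layer_radii[gids[layered] // ncols]
        inner_u = U[self.vmap[mesh.inner_verts]]  # per column (inner_verts order)
        u_guess[layered] = (vradii / mesh.spec.r_inner)[:, None] * inner_u[vcols]

        def newton(u, bfrac):
            u = u.copy()
            u[self.nuc_dirichlet] = bfrac * bvals
            for _ in range(40):
                F = np.eye(3) + np.einsum("naj,nai->nij", dNdX, u[conn])
                J = np.linalg.det(F)
                if J.min() <= 0:
                    raise NewtonError("inverted nucleoplasm element")
                Finv = np.linalg.inv(F)
                FiT = np.swapaxes(Finv, 1, 2)
                P = 2.0 * E1n * (F - FiT) + (
                    2.0 * phin * (J - 1.0) * J
                )[:, None, None] * FiT
                Re = np.einsum("nij,naj,n->nai", P, dNdX, w)
                R = np.zeros(ndof)
                np.add.at(R, 3 * conn[:, :, None] + np.arange(3), Re)
                if np.linalg.norm(R[free]) < 1e-9 * force_scale:
                    return u
                A = 2.0 * E1n * (
                    np.einsum("ik,jl->ijkl", d, d)[None]
                    + np.einsum("nil,nkj->nijkl", FiT, FiT)
                )
                A = A + 2.0 * phin * (
                    ((2.0 * J - 1.0) * J)[:, None, None, None, None]
                    * np.einsum("nij,nkl->nijkl", FiT, FiT)
                    - ((J - 1.0) * J)[:, None, None, None, None]
                    * np.einsum("nil,nkj->nijkl", FiT, FiT)
                )
                T = np.einsum("nijkl,nbl,n->nijbk", A, dNdX, w, optimize=True)
                Ke = np.einsum(
                    "naj,nijbk->naibk", dNdX, T, optimize=True
                ).reshape(-1, 12, 12)
                K = sp.coo_matrix(
                    (Ke.ravel(), (rows, cols)), shape=(ndof, ndof)
                ).tocsr()
                du = np.zeros(ndof)
                du[free] = spla.splu(K[free][:, free].tocsc()).solve(-R[free])
                # backtrack on element inversion
                step = 1.0
                for _ in range(8):
                    ut = u + step * du.reshape(-1, 3)
                    Ft = np.eye(3) + np.einsum("naj,nai->nij", dNdX, ut[conn])
                    if np.linalg.det(Ft).min() > 0:
                        break
                    step *= 0.5
                else:
                    raise NewtonError("inverted nucleoplasm element")
                u = ut
            raise NewtonError("nucleoplasm extension did not converge")

        if guess is not None:
            u_guess = guess[self.nuc_used]
        try:
            u = newton(u_guess, 1.0)
        except NewtonError:
            # adaptive continuation in the boundary-data fraction
            cur, step = 0.0, 0.5
            u = u_guess * 0.0
            while cur < 1.0:
                trial = min(1.0, cur + step)
                try:
                    u = newton(u, trial)
                    cur = trial
                    step = min(step * 1.6, 1.0 - cur if cur < 1.0 else 1.0)
                except NewtonError:
                    step *= 0.5
                    if step < 1.0 / 256.0:
                        raise
        out = np.zeros((mesh.n_vertices, 3))
        out[self.nuc_used] = u
        # shell vertices keep the shell displacement
        out[self.used_vertices] = U[: self.n_vnodes]
        return out

    # -- tension -------------------------------------------------------------
    def membrane_tension(self, U: np.ndarray, Pv: np.ndarray) -> np.ndarray:
        """NE tension gamma (Pa um) at outer-face quadrature points.

        gamma = (dz_hat / 2)(sigma_g1 + sigma_g2), with the frame tractions of
        the first Piola-Kirchhoff stress divided by the in-plane stretches,
        evaluated at the outer surface of the shell elements.
        """
        mesh = self.mesh
        # outer faces are the top faces of the third tet of each outer prism
        # column; evaluate volumetric fields there via the P2 tet basis
        nface = len(self.fconn_outer)
        F, pq = self._eval_at_outer_faces(U, Pv)
        Ppk, J, Finv, I1, I2 = mooney_rivlin_piola(
            F, pq, self.material.E1, self.material.E2,
            self._escale_face()[:, None],
        )
        FiT = np.swapaxes(Finv, -1, -2)
        Xq = self.Xq_outer
        e_t, e_p = tangent_frame(Xq.reshape(-1, 3), mesh.spec)
        e_t = e_t.reshape(Xq.shape)
        e_p = e_p.reshape(Xq.shape)
        a_t = np.linalg.norm(J[..., None] * np.einsum("fqij,fqj->fqi", FiT, e_p), axis=-1)
        a_p = np.linalg.norm(J[..., None] * np.einsum("fqij,fqj->fqi", FiT, e_t), axis=-1)
        s1 = np.einsum("fqi,fqij,fqj->fq", e_t, Ppk, e_t) / a_t
        s2 = np.einsum("fqi,fqij,fqj->fq", e_p, Ppk, e_p) / a_p
        return 0.5 * DZ_BILAYER * (s1 + s2)

    def _escale_face(self):
        # outer faces follow surface-triangle order; shell elements store the
        # parent triangle, prism layer 0 elements are the first 3*ntris
        ntri = len(self.mesh.surf_tris)
        es = np.ones(ntri)
        pe = self.escale_elem[: 3 * ntri].reshape(ntri, 3)
        return pe.mean(axis=1)

    def _eval_at_outer_faces(self, U, Pv):
        """F and p at outer-face quadrature points via the adjacent tets.

        The outer face of surface column-triangle t is the top face of tet
        3*t + 2 (the third tet of its outermost prism), with local vertices
        (bi, tj, tk, ti) where (i, j, k) are the triangle's columns sorted
        ascending; face barycentric (li, lj, lk) maps to xi = (lj, lk, li).
        """
        ntri = len(self.mesh.surf_tris)
        qp = self._surf_qp
        nq = len(qp)
        lam = np.empty((nq, 3))
        lam[:, 1:] = qp
        lam[:, 0] = 1.0 - qp.sum(axis=1)
        order = np.argsort(self.mesh.surf_tris, axis=1)  # (ntri, 3)
        # lam columns follow surf_tris vertex order (a,b,c); reorder to sorted
        lam_s = lam[:, order]  # (nq, ntri, 3)
        xi = np.stack([lam_s[..., 1], lam_s[..., 2], lam_s[..., 0]], axis=-1)
        xi = np.swapaxes(xi, 0, 1).reshape(-1, 3)  # (ntri*nq, 3)
        N2, dN2 = p2_tet_shape(xi)
        dN2 = dN2.reshape(ntri, nq, 10, 3)
        tet_ids = 3 * np.arange(ntri) + 2
        conn = self.conn[tet_ids]
        Xe = self.node_X[conn]
        Jgeo = np.einsum("fqad,fak->fqkd", dN2, Xe)
        dNdX = np.einsum("fqad,fqdk->fqak", dN2, np.linalg.inv(Jgeo))
        Fout = np.eye(3) + np.einsum("fqaj,fai->fqij", dNdX, U[conn])
        N1 = np.empty((ntri, nq, 4))
        xi3 = xi.reshape(ntri, nq, 3)
        N1[..., 0] = 1.0 - xi3.sum(axis=-1)
        N1[..., 1:] = xi3
        pout = np.einsum("fqa,fa->fq", N1, Pv[self.pconn[tet_ids]])
        return Fout, pout
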