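"""Reaction-transport of NE surface species and nuclear volume species.

Species move with the deforming geometry in a fully Lagrangian frame: fields
live on the reference mesh, and the deformed metric enters through pulled-back
measures. Each step splits advection from diffusion-reaction:

1. a multiplicative dilution correction by the ratio of old to new local
   measure (Jacobian J for volume species, area stretch alpha for surface
   species), which conserves total molecule number exactly at the discrete
   level when the ratios are taken between lumped mass entries;
2. an implicit-Euler diffusion-reaction solve on the frozen deformed domain.

Surface species ([NPC], [NPC]_A) use the deformed outer-surface metric;
NE-bound lamin [L] is tracked on the outer-surface vertices but transported
with the metric of the concentric inner surface (the lamina lies at the inner
face of the NE); volume species ([L]_phos, [Y]_nuc) live on the full deformed
nuclear volume (nucleoplasm + NE) with boundary exchange fluxes on the outer
surface, converted between areal number densities and micromolar
concentrations by N_conv = 602.2 molecules um^-3 uM^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ReferenceMesh

__all__ = [
    "SpeciesState",
    "DeformationMaps",
    "TransportSystem",
    "surface_operators",
    "volume_operators",
    "inner_surface_maps",
    "step_surface_species",
    "step_volume_species",
    "step_lamin",
]

N_CONV = 602.2  # molecules per um^3 per uM


@dataclass
class SpeciesState:
    """Concentration fields on the reference mesh.

    Surface densities (um^-2) on outer-surface vertices; volume
    concentrations (uM) on all mesh vertices.
    """

    lamin: np.ndarray  # [L], um^-2, outer-surface vertices (inner-surface metric)
    npc: np.ndarray  # [NPC], um^-2
    npc_a: np.ndarray  # [NPC]_A, um^-2
    lamin_phos: np.ndarray  # [L]_phos, uM, all vertices
    yap_nuc: np.ndarray  # [Y]_nuc, uM, all vertices

    def copy(self) -> "SpeciesState":
        return SpeciesState(*(v.copy() for v in (
            self.lamin, self.npc, self.npc_a, self.lamin_phos, self.yap_nuc)))

    def clip_negative(self, tol: float = 1e-10) -> int:
        """Clip tiny negative values to zero; abort on large negatives."""
        n = 0
        for name in ("lamin", "npc", "npc_a", "lamin_phos", "yap_nuc"):
            v = getattr(self, name)
            scale = max(float(np.max(np.abs(v))), 1.0)
            if v.min() < -tol * scale * 1e4:
                raise FloatingPointError(
                    f"large negative concentration in {name}: {v.min()}"
                )
            neg = v < 0
            n += int(neg.sum())
            v[neg] = 0.0
        return n


def _tri_operators(coords: np.ndarray, tris: np.ndarray, nvert: int):
    """Lumped mass and stiffness of P1 triangles embedded in 3-D."""
    p0, p1, p2 = (coords[tris[:, k]] for k in range(3))
    e1, e2 = p1 - p0, p2 - p0
    cr = np.cross(e1, e2)
    area2 = np.linalg.norm(cr, axis=1)
    area = 0.5 * area2
    n = cr / area2[:, None]
    # P1 gradients: grad lam_k = (n x opposite_edge) / (2A), in-plane
    g = np.empty((len(tris), 3, 3))
    g[:, 0] = np.cross(n, p2 - p1) / area2[:, None]
    g[:, 1] = np.cross(n, p0 - p2) / area2[:, None]
    g[:, 2] = np.cross(n, p1 - p0) / area2[:, None]
    M = np.zeros(nvert)
    np.add.at(M, tris, (area / 3.0)[:, None])
    Ke = np.einsum("nak,nbk,n->nab", g, g, area)
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(nvert, nvert)).tocsr()
    return M, K


def _tet_operators(coords: np.ndarray, tets: np.ndarray, nvert: int):
    """Lumped mass and stiffness of P1 tetrahedra."""
    v0 = coords[tets[:, 0]]
    Mm = np.stack([coords[tets[:, k]] - v0 for k in (1, 2, 3)], axis=-1)
    det = np.linalg.det(Mm)
    if det.min() <= 0:
        raise FloatingPointError("inverted element in deformed transport mesh")
    vol = det / 6.0
    Minv = np.linalg.inv(Mm)
    dref = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    g = np.einsum("ad,ndk->nak", dref, Minv)  # dN_a/dX_k = dref_ad (M^-1)_dk
    M = np.zeros(nvert)
    np.add.at(M, tets, (vol / 4.0)[:, None])
    Ke = np.einsum("nak,nbk,n->nab", g, g, vol)
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(nvert, nvert)).tocsr()
    return M, K


def surface_operators(coords, tris, nvert):
    """Public wrapper: (lumped mass, stiffness) on a deformed triangulation."""
    return _tri_operators(coords, tris, nvert)


def volume_operators(coords, tets, nvert):
    return _tet_operators(coords, tets, nvert)


def inner_surface_maps(mesh: ReferenceMesh, u_vertices: np.ndarray):
    """Deformed inner-surface vertex positions by the concentric map.

    The inner reference surface is the radial projection of the outer one, so
    outer column i maps to inner vertex ``mesh.inner_verts[i]``; the deformed
    inner position is that vertex plus its displacement. Returns positions in
    outer-column order.
    """
    iv = mesh.inner_verts
    return mesh.points[iv] + u_vertices[iv]


@dataclass
class DeformationMaps:
    """Per-step deformation data consumed by the transport solvers."""

    x_vertices: np.ndarray  # deformed positions of all mesh vertices
    x_outer: np.ndarray  # deformed outer-surface vertex positions (column order)
    x_inner: np.ndarray  # deformed inner-surface vertex positions (column order)
    # assembled operators
    M_outer: np.ndarray = None
    K_outer: sp.csr_matrix = None
    M_inner: np.ndarray = None
    K_inner: sp.csr_matrix = None
    M_vol: np.ndarray = None
    K_vol: sp.csr_matrix = None
    alpha_outer: np.ndarray = None  # per-vertex stretch vs reference
    alpha_inner: np.ndarray = None


class TransportSystem:
    """Surface/volume transport on one reference mesh.

    The outer-surface field vector is indexed by surface column; the volume
    field vector by mesh vertex. ``outer_to_vertex`` maps between them.
    """

    def __init__(self, mesh: ReferenceMesh):
        self.mesh = mesh
        self.tris = mesh.surf_tris
        self.n_surf = len(mesh.unit_dirs)
        self.outer_to_vertex = mesh.outer_verts
        self.n_vert = mesh.n_vertices
        self.tets = mesh.tets
        # reference measures
        ref = self.build_maps(np.zeros((self.n_vert, 3)))
        self.M_outer_ref = ref.M_outer
        self.M_inner_ref = ref.M_inner
        self.M_vol_ref = ref.M_vol

    def build_maps(self, u_vertices: np.ndarray) -> DeformationMaps:
        mesh = self.mesh
        x = mesh.points + u_vertices
        x_outer = x[mesh.outer_verts]
        x_inner = inner_surface_maps(mesh, u_vertices)
        Mo, Ko = _tri_operators(x_outer, self.tris, self.n_surf)
        Mi, Ki = _tri_operators(x_inner, self.tris, self.n_surf)
        Mv, Kv = _tet_operators(x, self.tets, self.n_vert)
        maps = DeformationMaps(
            x_vertices=x, x_outer=x_outer, x_inner=x_inner,
            M_outer=Mo, K_outer=Ko, M_inner=Mi, K_inner=Ki, M_vol=Mv, K_vol=Kv,
        )
        if hasattr(self, "M_outer_ref"):
            maps.alpha_outer = Mo / self.M_outer_ref
            maps.alpha_inner = Mi / self.M_inner_ref
        else:  # reference build during __init__
            maps.alpha_outer = np.ones_like(Mo)
            maps.alpha_inner = np.ones_like(Mi)
        return maps

    # -- dilution ---------------------------------------------------------
    @staticmethod
    def dilute(field: np.ndarray, M_old: np.ndarray, M_new: np.ndarray) -> np.ndarray:
        """Multiplicative dilution by the lumped measure ratio (conservative)."""
        return field * (M_old / M_new)

    def dilute_state(self, state: SpeciesState, old: DeformationMaps, new: DeformationMaps):
        state.lamin = self.dilute(state.lamin, old.M_inner, new.M_inner)
        state.npc = self.dilute(state.npc, old.M_outer, new.M_outer)
        state.npc_a = self.dilute(state.npc_a, old.M_outer, new.M_outer)
        state.lamin_phos = self.dilute(state.lamin_phos, old.M_vol, new.M_vol)
        state.yap_nuc = self.dilute(state.yap_nuc, old.M_vol, new.M_vol)

    # -- implicit steps ---------------------------------------------------
    @staticmethod
    def _implicit_solve(M, K, D, dt, c_old, *, rate_imp=None, source=None):
        """(M/dt + D K + diag(M*rate_imp)) c = M/dt c_old + M*source."""
        n = len(c_old)
        A = sp.diags(M / dt) + D * K
        if rate_imp is not None:
            A = A + sp.diags(M * rate_imp)
        b = M / dt * c_old
        if source is not None:
            b = b + M * source
        return spla.spsolve(A.tocsr(), b)

    def step_surface_pair(self, state: SpeciesState, maps: DeformationMaps,
                          dt: float, D_npc: float, kf_npc: np.ndarray, kr_npc: float):
        """Coupled implicit step of [NPC] / [NPC]_A (activation conserves the sum)."""
        M, K = maps.M_outer, maps.K_outer
        n = self.n_surf
        A11 = sp.diags(M / dt) + D_npc * K + sp.diags(M * kf_npc)
        A22 = sp.diags(M / dt) + D_npc * K + sp.diags(M * kr_npc)
        A12 = sp.diags(-M * kr_npc)
        A21 = sp.diags(-M * kf_npc)
        A = sp.bmat([[A11, A12], [A21, A22]]).tocsr()
        b = np.concatenate([M / dt * state.npc, M / dt * state.npc_a])
        sol = spla.spsolve(A, b)
        state.npc = sol[:n]
        state.npc_a = sol[n:]

    def step_lamin_pair(self, state: SpeciesState, maps: DeformationMaps, dt: float,
                        DL: float, DL_vol: float, krl: float, kfl_eff: np.ndarray,
                        literal_exchange_measure: bool = False):
        """Lamin cycling between the NE surface pool and the nucleoplasmic pool.

        The phospho pool is stepped first (implicit in its own sink), then the
        surface pool with the fresh dephosphorylation source; the exchange
        flux is applied with the inner-surface measure on both sides by
        default so total lamin is conserved to near round-off.
        """
        Ms = maps.M_outer if literal_exchange_measure else maps.M_inner
        ov = self.outer_to_vertex
        # volume step: d(Lphos)/dt = ... + (1/Nconv)(krl L - kfl_eff Lphos) on boundary
        Mv, Kv = maps.M_vol, maps.K_vol
        rate_imp = np.zeros(self.n_vert)
        src = np.zeros(self.n_vert)
        rate_imp[ov] = kfl_eff * Ms / (N_CONV * Mv[ov])
        src[ov] = krl * state.lamin * Ms / (N_CONV * Mv[ov])
        lphos = self._implicit_solve(Mv, Kv, DL_vol, dt, state.lamin_phos,
                                     rate_imp=rate_imp, source=src)
        # surface step with the updated phospho source
        Mi, Ki = maps.M_inner, maps.K_inner
        src_s = kfl_eff * lphos[ov] * Ms / Mi
        lam = self._implicit_solve(Mi, Ki, DL, dt, state.lamin,
                                   rate_imp=krl * Ms / Mi, source=src_s)
        state.lamin_phos = lphos
        state.lamin = lam

    def step_yap(self, state: SpeciesState, maps: DeformationMaps, dt: float,
                 DY: float, kin_tot: np.ndarray, kout: float, y_free: float):
        """Nuclear YAP/TAZ with stretch-gated influx and first-order efflux."""
        Mv, Kv = maps.M_vol, maps.K_vol
        ov = self.outer_to_vertex
        Ms = maps.M_outer
        rate_imp = np.zeros(self.n_vert)
        src = np.zeros(self.n_vert)
        rate_imp[ov] = kout * Ms / (N_CONV * Mv[ov])
        src[ov] = kin_tot * y_free * Ms / (N_CONV * Mv[ov])
        state.yap_nuc = self._implicit_solve(Mv, Kv, DY, dt, state.yap_nuc,
                                             rate_imp=rate_imp, source=src)

    # -- totals ------------------------------------------------------------
    def totals(self, state: SpeciesState, maps: DeformationMaps):
        """Integrated molecule counts (quarter domain)."""
        return {
            "L_total": float(maps.M_inner @ state.lamin),
            "Lphos_total": float(N_CONV * maps.M_vol @ state.lamin_phos),
            "NPC_total": float(maps.M_outer @ state.npc),
            "NPCA_total": float(maps.M_outer @ state.npc_a),
            "Ynuc_total": float(N_CONV * maps.M_vol @ state.yap_nuc),
        }


# -- thin functional wrappers (operation-level API) -------------------------

def step_volume_species(field, dt, maps_old: DeformationMaps, maps_new: DeformationMaps,
                        D: float, rate_imp=None, source=None):
    """Dilute by the volume-measure ratio, then implicit diffusion-reaction."""
    c = field * (maps_old.M_vol / maps_new.M_vol)
    return TransportSystem._implicit_solve(
        maps_new.M_vol, maps_new.K_vol, D, dt, c, rate_imp=rate_imp, source=source
    )


def step_surface_species(field, dt, maps_old: DeformationMaps, maps_new: DeformationMaps,
                         D: float, rate_imp=None, source=None):
    """Dilute by the outer-area ratio, then implicit diffusion-reaction."""
    c = field * (maps_old.M_outer / maps_new.M_outer)
    return TransportSystem._implicit_solve(
        maps_new.M_outer, maps_new.K_outer, D, dt, c, rate_imp=rate_imp, source=source
    )


def step_lamin(field, dt, maps_old: DeformationMaps, maps_new: DeformationMaps,
               D: float, rate_imp=None, source=None):
    """As step_surface_species with the inner-surface measures."""
    c = field * (maps_old.M_inner / maps_new.M_inner)
    return TransportSystem._implicit_solve(
        maps_new.M_inner, maps_new.K_inner, D, dt, c, rate_imp=rate_imp, source=source
    )
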