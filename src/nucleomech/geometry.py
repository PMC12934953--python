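"""Reference geometry of the nuclear envelope and substrate-derived fields.

The undeformed nucleus is a spherical shell (outer radius ``R0``, thickness
``dT``) centred at ``(0, 0, znuc + R0)``, enclosing the nucleoplasm. Because
the nucleus sits centred above a nanopillar, mirror symmetry about the planes
x = 0 and y = 0 lets a single quadrant (X >= 0, Y >= 0) represent the whole
geometry. Substrate coordinates put the nanopillar top plane at z = 0 and the
substrate floor at z = -hNP; a flat substrate is the degenerate case hNP = 0.

The mesh generator triangulates the quarter sphere by recursive octahedron
subdivision (which keeps vertices exactly on the symmetry planes), extrudes
the shell radially into prism layers split into tetrahedra, and fills the
nucleoplasm with graded concentric layers closed by a cone at the centre.
Quadratic mid-edge nodes inside the shell are snapped onto the interpolated
sphere so the shell elements are curved (isoparametric P2 geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fem import TET_EDGES

__all__ = [
    "NanopillarArraySpec",
    "ShellGeometrySpec",
    "ReferenceMesh",
    "build_reference_mesh",
    "reference_normal",
    "tangent_frame",
    "pillar_lattice",
    "pillar_indicator",
    "pillar_indicator_smooth",
    "pm_distance_and_curvature",
    "factin_concentration",
]

D_STERIC_PM = 0.05  # steric radius between nanopillar and plasma membrane (um)


@dataclass(frozen=True)
class NanopillarArraySpec:
    """Square nanopillar array: radius, height, pitch and lattice cutoff (um).

    ``h_np = 0`` denotes a flat substrate. ``n_np = round(r_max / p_np)`` is
    the half-extent of the lattice actually enumerated.
    """

    r_np: float = 0.2
    h_np: float = 1.5
    p_np: float = 5.0
    r_max: float = 7.5

    def __post_init__(self):
        if min(self.r_np, self.h_np, self.p_np, self.r_max) < 0:
            raise ValueError("nanopillar dimensions must be nonnegative")
        if self.h_np > 0 and self.p_np < 2.0 * self.r_np:
            raise ValueError("pillars overlap: require p_np >= 2*r_np")

    @property
    def n_np(self) -> int:
        if self.p_np <= 0:
            return 0
        return int(round(self.r_max / self.p_np))

    @property
    def flat(self) -> bool:
        return self.h_np == 0.0


@dataclass(frozen=True)
class ShellGeometrySpec:
    """Stress-free shell geometry and meshing controls (lengths in um)."""

    R0: float = 4.1
    dT: float = 0.2
    znuc: float = 1.04
    hedge: float = 0.4
    d_roof: float = 1.5

    def __post_init__(self):
        if not (0 < self.dT < self.R0):
            raise ValueError("require 0 < dT < R0")
        if self.hedge <= 0:
            raise ValueError("hedge must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.znuc + self.R0])

    @property
    def r_inner(self) -> float:
        return self.R0 - self.dT


def _octahedron_quarter(levels: int):
    """Triangulate the quarter sphere (x>=0, y>=0) by octahedron subdivision."""
    verts = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0, 0, -1)]
    faces = [(0, 1, 2), (0, 3, 1)]
    verts = [np.array(v, dtype=float) for v in verts]
    for _ in range(levels):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in edge_mid:
                m = verts[a] + verts[b]
                m /= np.linalg.norm(m)
                verts.append(m)
                edge_mid[key] = len(verts) - 1
            return edge_mid[key]

        for (a, b, c) in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        faces = new_faces
    dirs = np.array(verts)
    # snap near-plane coordinates exactly onto the symmetry planes
    dirs[np.abs(dirs) < 1e-12] = 0.0
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    return dirs, np.array(faces, dtype=np.int64)


def _split_prism(bot, top, order):
    """Path tetrahedralization of a prism; ``order`` ranks the three columns.

    Diagonals run from the bottom vertex of the lower-ranked column to the top
    vertex of the higher-ranked column, which is automatically conforming
    between prisms sharing a quad face.
    """
    i, j, k = [bot[m] for m in order], None, None
    bi, bj, bk = (bot[m] for m in order)
    ti, tj, tk = (top[m] for m in order)
    return [(bi, bj, bk, tk), (bi, bj, tk, tj), (bi, tj, tk, ti)]


@dataclass
class ReferenceMesh:
    """Quarter shell + nucleoplasm tetrahedral mesh with tagged surfaces.

    Vertices are stored once (``points``); the shell additionally carries
    quadratic mid-edge nodes (``p2_points`` holds vertices followed by edge
    nodes). Surface triangulations of the outer and inner spheres share the
    same connectivity (column-wise radial extrusion), so outer vertex ``i``
    corresponds radially to inner vertex ``inner_of_outer[i]``.
    """

    spec: ShellGeometrySpec
    points: np.ndarray  # (nv, 3) vertices
    tets: np.ndarray  # (nt, 4)
    region: np.ndarray  # (nt,) 1 = NE shell, 2 = nucleoplasm
    surf_tris: np.ndarray  # (ns, 3) quarter-sphere triangulation (indices into columns)
    outer_verts: np.ndarray  # (nsv,) vertex ids of the outer sphere
    inner_verts: np.ndarray  # (nsv,) vertex ids of the inner sphere (same column order)
    unit_dirs: np.ndarray  # (nsv, 3) radial unit direction per column
    # quadratic layer (shell only)
    edges: np.ndarray = field(default=None)  # (ne,2) global vertex pairs (shell)
    tet_edges: np.ndarray = field(default=None)  # (nt_shell,6) -> edge index
    p2_points: np.ndarray = field(default=None)  # (nv+ne,3)
    shell_tets_idx: np.ndarray = field(default=None)
    nuc_tets_idx: np.ndarray = field(default=None)
    shell_parent_tri: np.ndarray = field(default=None)  # (nt_shell,) surface tri id
    apex_column: int = -1  # surface column index of the top pole
    bottom_column: int = -1  # surface column index of the bottom pole
    layer_radii: np.ndarray = field(default=None)  # radius of each vertex layer
    # vertex id = layer * n_columns + column for layered vertices; the centre
    # vertex is the last one

    @property
    def center(self) -> np.ndarray:
        return self.spec.center

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def shell_tets(self) -> np.ndarray:
        return self.tets[self.shell_tets_idx]

    @property
    def nuc_tets(self) -> np.ndarray:
        return self.tets[self.nuc_tets_idx]

    def outer_tri_vertices(self) -> np.ndarray:
        return self.outer_verts[self.surf_tris]

    def inner_tri_vertices(self) -> np.ndarray:
        return self.inner_verts[self.surf_tris]


def build_reference_mesh(shell: ShellGeometrySpec) -> ReferenceMesh:
    """Build the conforming quarter shell + nucleoplasm tetrahedral mesh."""
    R0, dT = shell.R0, shell.dT
    Rin = shell.r_inner
    # subdivision level from the target edge length (octahedron edge arc pi/2)
    levels = int(np.clip(round(np.log2(R0 * (np.pi / 2) / shell.hedge)), 2, 7))
    dirs, tris = _octahedron_quarter(levels)
    nsv = len(dirs)

    # radial layers: outer -> inner shell, then graded nucleoplasm, then centre
    n_shell_layers = max(1, int(round(dT / shell.hedge)))
    shell_radii = np.linspace(R0, Rin, n_shell_layers + 1)
    nuc_fracs = np.array([0.72, 0.45, 0.20])
    nuc_radii = Rin * nuc_fracs
    radii = np.concatenate([shell_radii, nuc_radii])

    center = shell.center
    layers = []  # vertex id of (layer, column)
    pts = []
    for r in radii:
        base = len(pts)
        pts.extend(center + r * dirs)
        layers.append(np.arange(base, base + nsv))
    center_id = len(pts)
    pts.append(center.copy())
    points = np.array(pts)

    tets = []
    region = []
    parent = []

    def add_prism_layers(l0, l1, reg):
        for t_idx, (a, b, c) in enumerate(tris):
            cols = np.array([a, b, c])
            order = np.argsort(cols)  # rank columns by global column id
            bot = [layers[l1][cols[m]] for m in order]
            top = [layers[l0][cols[m]] for m in order]
            bi, bj, bk = bot
            ti, tj, tk = top
            for tet in [(bi, bj, bk, tk), (bi, bj, tk, tj), (bi, tj, tk, ti)]:
                tets.append(tet)
                region.append(reg)
                parent.append(t_idx)

    nlay = len(radii)
    for l0 in range(nlay - 1):
        reg = 1 if l0 < n_shell_layers else 2
        add_prism_layers(l0, l0 + 1, reg)
    # cone from innermost layer to the centre
    for t_idx, (a, b, c) in enumerate(tris):
        tets.append((layers[-1][a], layers[-1][b], layers[-1][c], center_id))
        region.append(2)
        parent.append(t_idx)

    tets = np.array(tets, dtype=np.int64)
    region = np.array(region, dtype=np.int64)
    parent = np.array(parent, dtype=np.int64)

    # fix inverted tets (positive volume convention)
    v0 = points[tets[:, 0]]
    m = np.stack(
        [points[tets[:, k]] - v0 for k in (1, 2, 3)], axis=-1
    )  # (nt,3,3) columns
    vol6 = np.linalg.det(m)
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    if np.any(np.abs(vol6) < 1e-14):
        raise RuntimeError("degenerate element in generated mesh")

    shell_idx = np.where(region == 1)[0]
    nuc_idx = np.where(region == 2)[0]

    # shell quadratic layer: unique edges of shell tets
    st = tets[shell_idx]
    pairs = np.sort(st[:, TET_EDGES].reshape(-1, 2), axis=1)
    edges, inv = np.unique(pairs, axis=0, return_inverse=True)
    tet_edges = inv.reshape(len(st), 6)

    # mid-edge nodes snapped to the interpolated sphere
    radius_of = np.full(len(points), np.nan)
    dir_of = np.zeros((len(points), 3))
    for li, r in enumerate(radii):
        radius_of[layers[li]] = r
        dir_of[layers[li]] = dirs
    ra, rb = radius_of[edges[:, 0]], radius_of[edges[:, 1]]
    da, db = dir_of[edges[:, 0]], dir_of[edges[:, 1]]
    dm = da + db
    dm /= np.linalg.norm(dm, axis=1)[:, None]
    mid = center + 0.5 * (ra + rb)[:, None] * dm
    p2_points = np.vstack([points, mid])

    mesh = ReferenceMesh(
        spec=shell,
        points=points,
        tets=tets,
        region=region,
        surf_tris=tris,
        outer_verts=layers[0],
        inner_verts=layers[n_shell_layers],
        unit_dirs=dirs,
        edges=edges,
        tet_edges=tet_edges,
        p2_points=p2_points,
        shell_tets_idx=shell_idx,
        nuc_tets_idx=nuc_idx,
        shell_parent_tri=parent[shell_idx],
        apex_column=int(np.argmax(dirs[:, 2])),
        bottom_column=int(np.argmin(dirs[:, 2])),
        layer_radii=radii,
    )
    return mesh


def reference_normal(X: np.ndarray, shell: ShellGeometrySpec) -> np.ndarray:
    """Outward radial unit normal of the reference shell at material point(s) X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    v = X - shell.center
    r = np.linalg.norm(v, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("reference normal undefined at the shell centre")
    n = v / r[:, None]
    return n[0] if n.shape[0] == 1 and np.asarray(X).ndim == 1 else n


def tangent_frame(X: np.ndarray, shell: ShellGeometrySpec):
    """Orthonormal surface frame (e_theta, e_phi) at material point(s) X.

    e_theta is the azimuthal direction [-Y, X, 0]/rho; e_phi = e_theta x N.
    On the polar axis (X = Y = 0) the azimuth is undefined and a fixed frame
    aligned with the x/y axes is substituted (the in-plane stress there is
    isotropic by symmetry, so any orthonormal tangent pair is equivalent).
    """
    single = np.asarray(X).ndim == 1
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = reference_normal(X, shell)
    N = np.atleast_2d(N)
    rho = np.hypot(X[:, 0], X[:, 1])
    e_t = np.zeros_like(X)
    on_axis = rho < 1e-12
    ok = ~on_axis
    e_t[ok, 0] = -X[ok, 1] / rho[ok]
    e_t[ok, 1] = X[ok, 0] / rho[ok]
    e_t[on_axis] = [0.0, 1.0, 0.0]  # fallback frame on the polar axis
    e_p = np.cross(e_t, N)
    nrm = np.linalg.norm(e_p, axis=1)
    e_p /= np.where(nrm > 0, nrm, 1.0)[:, None]
    if single:
        return e_t[0], e_p[0]
    return e_t, e_p


def pillar_lattice(spec: NanopillarArraySpec) -> np.ndarray:
    """(x, y) centres of all pillars within the lattice cutoff; empty if flat."""
    if spec.flat or spec.p_np <= 0:
        return np.zeros((0, 2))
    n = spec.n_np
    g = np.arange(-n, n + 1) * spec.p_np
    xx, yy = np.meshgrid(g, g)
    return np.column_stack([xx.ravel(), yy.ravel()])


def pillar_indicator(x, y, spec: NanopillarArraySpec) -> np.ndarray:
    """Sharp indicator: 1 directly above a nanopillar, else 0."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    centers = pillar_lattice(spec)
    if len(centers) == 0:
        return np.zeros_like(x)
    d2 = (x[:, None] - centers[:, 0]) ** 2 + (y[:, None] - centers[:, 1]) ** 2
    return (d2.min(axis=1) <= spec.r_np**2).astype(float)


def pillar_indicator_smooth(x, y, spec: NanopillarArraySpec) -> np.ndarray:
    """Super-Gaussian approximation of the pillar indicator.

    Sum over lattice sites of exp(-r^4 / (2 (r_np + 0.05)^4)).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    centers = pillar_lattice(spec)
    if len(centers) == 0:
        return np.zeros_like(x)
    w4 = (spec.r_np + D_STERIC_PM) ** 4
    d2 = (x[:, None] - centers[:, 0]) ** 2 + (y[:, None] - centers[:, 1]) ** 2
    return np.exp(-(d2**2) / (2.0 * w4)).sum(axis=1)


def pm_distance_and_curvature(x, y, z, spec: NanopillarArraySpec, dsteric: float):
    """Distances to the plasma membrane over the nearest pillar, and PM curvature.

    Assumes a cylindrical PM wrapped around the nearest nanopillar with a
    0.05 um steric radius; ``dsteric`` is the NE-PM steric gap. z is measured
    from the pillar-top plane. Returns (d_top, d_side, H_side) where the PM
    curvature is 0 over the pillar top and ``1/(2 (r_np + 0.05))`` on the side.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    centers = pillar_lattice(spec)
    if len(centers) == 0:
        raise ValueError("pm_distance_and_curvature requires a pillar array")
    d2 = (x[:, None] - centers[:, 0]) ** 2 + (y[:, None] - centers[:, 1]) ** 2
    r_local = np.sqrt(d2.min(axis=1))
    rim = spec.r_np + D_STERIC_PM
    dr = r_local - spec.r_np
    corner = np.hypot(dr, z + dsteric)
    d_top = np.where(r_local <= rim, z + dsteric, corner)
    d_side = np.where(z > -dsteric, corner, dr)
    # distances are clamped at zero: the piecewise branches can go negative
    # in the (physically excluded) sliver below the pillar top inside its
    # footprint, which would otherwise blow up the F-actin exponential
    h_side = 1.0 / (2.0 * rim)
    return np.maximum(d_top, 0.0), np.maximum(d_side, 0.0), h_side


def factin_concentration(
    x,
    y,
    z,
    spec: NanopillarArraySpec,
    *,
    f0: float,
    f1: float,
    d_f: float,
    h0: float,
    dsteric: float,
) -> np.ndarray:
    """Cytosolic F-actin concentration (uM) at deformed NE point(s).

    Flat substrate: f0 + f1 exp(-(z + dsteric)/d_f). Pillar substrate: the
    maximum of the pillar-top term and the curvature-weighted side term, which
    makes the transition over the pillar shoulder continuous.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if spec.flat:
        return f0 + f1 * np.exp(-(z + dsteric) / d_f)
    d_top, d_side, h_side = pm_distance_and_curvature(x, y, z, spec, dsteric)
    top = np.exp(-d_top / d_f)
    side = np.exp(-d_side / d_f) * np.exp(h_side / h0)
    return f0 + f1 * np.maximum(top, side)
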