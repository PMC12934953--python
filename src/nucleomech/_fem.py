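"""Minimal finite-element kernels: quadrature and Lagrange shape functions.

Quadrature on simplices is built from collapsed-coordinate (Duffy) tensor
products of Gauss-Legendre / Gauss-Jacobi rules, which are exact for complete
polynomials up to degree 2n-1 with n points per direction. Only the pieces
needed by the shell solver are provided: quadratic (P2) and linear (P1)
tetrahedra and triangles.
"""

from __future__ import annotations

import numpy as np
from scipy.special import roots_jacobi, roots_legendre

__all__ = [
    "tet_quadrature",
    "tri_quadrature",
    "p2_tet_shape",
    "p1_tet_shape",
    "p2_tri_shape",
    "TET_EDGES",
    "TRI_EDGES",
]

# local edge numbering for 10-node tets / 6-node triangles (vertex pairs)
TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
TRI_EDGES = [(0, 1), (0, 2), (1, 2)]


def _gauss01(n: int):
    x, w = roots_legendre(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _jacobi01(n: int, alpha: int):
    # weight (1-x)^alpha on [0,1]
    x, w = roots_jacobi(n, alpha, 0.0)
    return 0.5 * (x + 1.0), w / 2.0 ** (alpha + 1)


def tet_quadrature(n: int):
    """Collapsed tensor rule on the reference tetrahedron.

    Returns (points (nq,3), weights (nq,)); weights sum to 1/6.
    Exact for polynomials of total degree <= 2n-1.
    """
    x1, w1 = _jacobi01(n, 2)
    x2, w2 = _jacobi01(n, 1)
    x3, w3 = _gauss01(n)
    pts = []
    wts = []
    for a, wa in zip(x1, w1):
        for b, wb in zip(x2, w2):
            for c, wc in zip(x3, w3):
                xi1 = a
                xi2 = b * (1.0 - a)
                xi3 = c * (1.0 - a) * (1.0 - b)
                pts.append((xi1, xi2, xi3))
                wts.append(wa * wb * wc)
    return np.asarray(pts), np.asarray(wts)


def tri_quadrature(n: int):
    """Collapsed tensor rule on the reference triangle; weights sum to 1/2."""
    x1, w1 = _jacobi01(n, 1)
    x2, w2 = _gauss01(n)
    pts = []
    wts = []
    for a, wa in zip(x1, w1):
        for b, wb in zip(x2, w2):
            pts.append((a, b * (1.0 - a)))
            wts.append(wa * wb)
    return np.asarray(pts), np.asarray(wts)


def p2_tet_shape(pts: np.ndarray):
    """P2 shape functions and reference gradients on the tetrahedron.

    Node order: 4 vertices, then 6 edge midnodes (TET_EDGES order).
    Returns N (nq,10) and dN (nq,10,3).
    """
    xi = np.atleast_2d(pts)
    lam = np.empty((xi.shape[0], 4))
    lam[:, 0] = 1.0 - xi.sum(axis=1)
    lam[:, 1:] = xi
    dlam = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    nq = xi.shape[0]
    N = np.empty((nq, 10))
    dN = np.empty((nq, 10, 3))
    for v in range(4):
        N[:, v] = lam[:, v] * (2.0 * lam[:, v] - 1.0)
        dN[:, v, :] = (4.0 * lam[:, v] - 1.0)[:, None] * dlam[v]
    for k, (a, b) in enumerate(TET_EDGES):
        N[:, 4 + k] = 4.0 * lam[:, a] * lam[:, b]
        dN[:, 4 + k, :] = 4.0 * (
            lam[:, a][:, None] * dlam[b] + lam[:, b][:, None] * dlam[a]
        )
    return N, dN


def p1_tet_shape(pts: np.ndarray):
    xi = np.atleast_2d(pts)
    nq = xi.shape[0]
    N = np.empty((nq, 4))
    N[:, 0] = 1.0 - xi.sum(axis=1)
    N[:, 1:] = xi
    dN = np.broadcast_to(
        np.array(
            [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        ),
        (nq, 4, 3),
    ).copy()
    return N, dN


def p2_tri_shape(pts: np.ndarray):
    """P2 shape functions on the reference triangle (3 vertices + TRI_EDGES)."""
    xi = np.atleast_2d(pts)
    lam = np.empty((xi.shape[0], 3))
    lam[:, 0] = 1.0 - xi.sum(axis=1)
    lam[:, 1:] = xi
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    nq = xi.shape[0]
    N = np.empty((nq, 6))
    dN = np.empty((nq, 6, 2))
    for v in range(3):
        N[:, v] = lam[:, v] * (2.0 * lam[:, v] - 1.0)
        dN[:, v, :] = (4.0 * lam[:, v] - 1.0)[:, None] * dlam[v]
    for k, (a, b) in enumerate(TRI_EDGES):
        N[:, 3 + k] = 4.0 * lam[:, a] * lam[:, b]
        dN[:, 3 + k, :] = 4.0 * (
            lam[:, a][:, None] * dlam[b] + lam[:, b][:, None] * dlam[a]
        )
    return N, dN
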