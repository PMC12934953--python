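"""Test fixtures: analytic oracles, prescribed deformations and coarse presets.

The balloon oracle solves the one-dimensional inflation of an incompressible
Mooney-Rivlin thick sphere by quadrature of the radial equilibrium equation,
independently of the finite-element path, and is used to cross-check the 3-D
solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .geometry import NanopillarArraySpec, ShellGeometrySpec, build_reference_mesh
from .mechanics import MaterialParams

__all__ = [
    "balloon_oracle",
    "balloon_pressure",
    "PrescribedDeformation",
    "make_coarse_fixture",
    "COARSE_PRESETS",
]


def balloon_pressure(r_out: float, shell: ShellGeometrySpec, material: MaterialParams) -> float:
    """Inflation pressure (Pa) required to hold outer radius ``r_out`` (um).

    Incompressibility ties every material radius R to r(R) = (R^3 + a)^(1/3)
    with a = r_out^3 - R0^3; radial equilibrium integrates the stress
    difference 2 (sigma_theta - sigma_r) / r through the wall, where for the
    two-term Mooney-Rivlin solid sigma_theta - sigma_r =
    2 (lam^2 - lam^-4)(E1 + lam^2 E2) with hoop stretch lam = r/R.
    """
    R_out, R_in = shell.R0, shell.r_inner
    a = r_out**3 - R_out**3
    E1, E2 = material.E1, material.E2

    def integrand(R):
        r = (R**3 + a) ** (1.0 / 3.0)
        lam = r / R
        sdiff = 2.0 * (lam**2 - lam**-4) * (E1 + lam**2 * E2)
        drdR = R**2 / r**2
        return 2.0 * sdiff / r * drdR

    val, _ = quad(integrand, R_in, R_out, limit=200)
    return float(val)


def balloon_oracle(dP: float, shell: ShellGeometrySpec, material: MaterialParams):
    """Deformed (outer radius, wall thickness) of the freely inflated shell."""
    if dP == 0:
        return shell.R0, shell.dT
    f = lambda r: balloon_pressure(r, shell, material) - dP
    lo, hi = shell.R0 * (1.0 + 1e-9), shell.R0 * 4.0
    if f(hi) < 0:
        raise ValueError("no inflation solution in bracket (pressure too large)")
    r_out = brentq(f, lo, hi, xtol=1e-10)
    r_in = (shell.r_inner**3 + r_out**3 - shell.R0**3) ** (1.0 / 3.0)
    return float(r_out), float(r_out - r_in)


@dataclass(frozen=True)
class PrescribedDeformation:
    """Closed-form displacement families used to exercise the transport stack.

    kinds: 'dilation' (x = (1 + amp s) X about the shell centre),
    'squash' (uniaxial z-compression about the centre, volume-preserving in
    plane), 'inflation' (radial displacement of magnitude amp s).
    ``s`` is a schedule parameter in [0, 1].
    """

    kind: str = "dilation"
    amplitude: float = 0.2
    center: np.ndarray | None = None

    def displacement(self, X: np.ndarray, s: float) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        c = self.center if self.center is not None else np.zeros(3)
        d = X - c
        a = self.amplitude * s
        if self.kind == "dilation":
            return a * d
        if self.kind == "squash":
            lam_z = 1.0 - a
            lam_xy = lam_z**-0.5
            u = np.empty_like(d)
            u[..., 0] = (lam_xy - 1.0) * d[..., 0]
            u[..., 1] = (lam_xy - 1.0) * d[..., 1]
            u[..., 2] = (lam_z - 1.0) * d[..., 2]
            return u
        if self.kind == "inflation":
            r = np.linalg.norm(d, axis=-1, keepdims=True)
            r = np.where(r > 0, r, 1.0)
            return a * d / r
        raise ValueError(f"unknown deformation kind {self.kind!r}")


COARSE_PRESETS = ("flat_coarse", "pillar200_coarse", "sphere_free")


def make_coarse_fixture(preset: str, hedge: float = 0.45):
    """Coarse (CI-scale) mesh + configuration for one of the named presets."""
    from .driver import SimulationConfig

    if preset not in COARSE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {COARSE_PRESETS}")
    shell = ShellGeometrySpec(hedge=hedge)
    if preset == "flat_coarse":
        pillars = NanopillarArraySpec(r_np=0.0, h_np=0.0, p_np=0.0, r_max=0.0)
    elif preset == "pillar200_coarse":
        pillars = NanopillarArraySpec(r_np=0.2, h_np=1.5, p_np=5.0, r_max=7.5)
    else:
        pillars = None
    cfg = SimulationConfig(
        shell=shell,
        pillars=pillars,
        sigma_max=400.0,
        t0_cap=100.0,
        t_end=300.0,
    )
    mesh = build_reference_mesh(shell)
    return mesh, cfg
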