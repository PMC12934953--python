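"""Shared fixtures: coarse meshes and cached expensive solves.

Session-scoped so that the inflation and compression solves are shared by
the unit and acceptance tests; the mesh resolutions here are CI-scale
(coarser than production runs) to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from nucleomech.driver import SimulationConfig, _Coupler, _inflate
from nucleomech.geometry import (
    NanopillarArraySpec,
    ShellGeometrySpec,
    build_reference_mesh,
)
from nucleomech.mechanics import LoadState, MaterialParams, MechanicsProblem

FLAT = NanopillarArraySpec(0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def coarse_shell_spec():
    return ShellGeometrySpec(hedge=0.7)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_shell_spec):
    return build_reference_mesh(coarse_shell_spec)


@pytest.fixture(scope="session")
def free_problem(coarse_mesh):
    return MechanicsProblem(coarse_mesh, MaterialParams(), pillars=None)


@pytest.fixture(scope="session")
def inflated_free(free_problem):
    """Free-shell inflation to the osmotic set-point (no substrate)."""
    sol = None
    for frac in (0.35, 0.7, 0.9, 1.0):
        sol = free_problem.solve_equilibrium(
            LoadState(dP=820.0 * frac), prev=sol, phase="inflate"
        )
    return sol


@pytest.fixture(scope="session")
def flat_coupler(coarse_mesh, coarse_shell_spec):
    cfg = SimulationConfig(
        shell=coarse_shell_spec,
        pillars=FLAT,
        sigma_max=800.0,
        t0_cap=100.0,
        t_end=300.0,
        contact_mode="ez",
    )
    return _Coupler(cfg, coarse_mesh)


@pytest.fixture(scope="session")
def inflated_flat(flat_coupler):
    """Inflation against the flat substrate (floor contact active)."""
    return _inflate(flat_coupler)
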