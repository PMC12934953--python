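"""Coupled mechanochemical simulation driver.

One simulation runs the following stages:

1. inflate the shell to the osmotic set-point Pmax (equator-pinned gauge,
   substrate contact active), then settle at zero cap stress in the
   compression gauge (apex held at its post-inflation roof average);
2. initialize the reaction-transport system at its well-mixed steady state
   using the settled post-inflation measures;
3. re-solve the mechanics with the lamin-scaled stiffness;
4. record the reference NE stretch alpha_init and the cytosolic YAP pools;
5. loop: advance the cap-stress schedule, re-equilibrate mechanics and
   osmotic pressure (to <1% pressure change; the mechanics stays frozen
   while the cap stress is zero), extend the displacement into the
   nucleoplasm, dilute species by the measure ratios, take an implicit
   reaction-diffusion step, refresh the cytosolic pools and the
   lamin-dependent stiffness, until t exceeds t_end.

Time steps are bounded so the cap-stress increment stays below
min(2 kPa, sigma_max / 10) and within the configured dt bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    NanopillarArraySpec,
    ReferenceMesh,
    ShellGeometrySpec,
    build_reference_mesh,
    factin_concentration,
)
from .mechanics import (
    LoadState,
    MaterialParams,
    MechanicalSolution,
    MechanicsProblem,
    cap_stress_schedule,
)
from .metrics import mean_lower_stretch, metrics_row
from .signaling import (
    KineticParams,
    cytosolic_yap,
    hill_stiffness_factor,
    initial_steady_state,
    yap_import_rate,
)
from .transport import N_CONV, SpeciesState, TransportSystem

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "CoupledState",
    "stiffness_scale",
    "force_per_lamin",
    "run_simulation",
    "run_pitch_sweep",
]


@dataclass
class SimulationConfig:
    """Complete description of one simulation run."""

    shell: ShellGeometrySpec = field(default_factory=ShellGeometrySpec)
    pillars: NanopillarArraySpec | None = field(
        default_factory=lambda: NanopillarArraySpec(0.0, 0.0, 0.0, 0.0)
    )
    material: MaterialParams = field(default_factory=MaterialParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    sigma_max: float = 400.0
    t0_cap: float = 1000.0
    t_end: float = 10000.0
    dt_min: float = 0.5
    dt_max: float = 50.0
    output_every: float = 50.0
    quad_degree: int = 2
    contact_mode: str = "ez"
    flat_floor_repulsion: bool = False
    init_mode: str = "effective"
    l_ref_mode: str = "auto"  # stiffness normalization: model WT density or fixed L_ref
    literal_exchange_measure: bool = False
    alpha_mode: str = "local"  # stretch entering the import rate
    couple_stiffness: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")

    def kinetics_for_substrate(self) -> KineticParams:
        """Kinetics with the baseline F-actin set by the pillar radius."""
        k = self.kinetics
        flat = self.pillars is None or self.pillars.flat
        r = 0.0 if self.pillars is None else self.pillars.r_np
        return replace(k, f0=k.f0_for_pillars(r, flat))


@dataclass
class CoupledState:
    """Mechanics + species + cytosol snapshot at one time."""

    t: float
    mech: MechanicalSolution
    species: SpeciesState
    y_cyto: float
    y_free: float
    escale_elem: np.ndarray
    u_vertices: np.ndarray


@dataclass
class SimulationResult:
    config: SimulationConfig
    mesh: ReferenceMesh
    table: pd.DataFrame  # per-output-time scalar log
    final: CoupledState
    alpha_init: float
    measures0: dict
    l_ref_used: float = float("nan")


class SimulationError(RuntimeError):
    """Raised on a mid-run failure; carries the last consistent state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


def stiffness_scale(lamin, params: KineticParams):
    """Lamin-dependent elastic-modulus multiplier.

    Normalized so that the wild-type reference density gives 1:
    Escale = (1 - phi_L) + phi_L [L]/[L]_ref. A lamin-free NE keeps the
    membrane contribution (1 - phi_L); phi_L = 0 disables the coupling.
    """
    return (1.0 - params.phi_L) + params.phi_L * np.asarray(lamin) / params.L_ref


def force_per_lamin(traction_mag, lamin, floor: float = 1.0):
    """Force per lamin subunit F_L = |sigma_NE| / [L] in pN (Pa um^2 = pN).

    Densities below ``floor`` (um^-2) are clamped to avoid division blow-up.
    """
    lam = np.maximum(np.asarray(lamin, dtype=float), floor)
    return np.asarray(traction_mag, dtype=float) / lam


class _Coupler:
    """Shared machinery between run_simulation stages."""

    def __init__(self, config: SimulationConfig, mesh: ReferenceMesh | None = None):
        self.cfg = config
        self.mesh = mesh if mesh is not None else build_reference_mesh(config.shell)
        self.kin = config.kinetics_for_substrate()
        self.prob = MechanicsProblem(
            self.mesh,
            config.material,
            pillars=config.pillars,
            quad_degree=config.quad_degree,
            contact_mode=config.contact_mode,
            flat_floor_repulsion=config.flat_floor_repulsion,
        )
        self.trans = TransportSystem(self.mesh)

    # displacement of every mesh vertex (shell + nucleoplasm extension);
    # warm-started from the previous step's extension
    def vertex_displacement(self, sol: MechanicalSolution) -> np.ndarray:
        u = self.prob.extend_displacement_to_nucleoplasm(
            sol.U, guess=getattr(self, "_last_unuc", None)
        )
        self._last_unuc = u
        return u

    def f_actin_outer(self, x_outer: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        pillars = cfg.pillars
        if pillars is None:
            # free shell: far from any substrate
            return np.full(len(x_outer), self.kin.f0)
        return factin_concentration(
            x_outer[:, 0], x_outer[:, 1], x_outer[:, 2], pillars,
            f0=self.kin.f0, f1=self.kin.f1, d_f=self.kin.d_f, h0=self.kin.h0,
            dsteric=cfg.material.dsteric,
        )

    def escale_from_lamin(self, lamin: np.ndarray) -> np.ndarray:
        """Per-shell-element stiffness multiplier from the surface lamin field."""
        if not self.cfg.couple_stiffness:
            return np.ones(len(self.prob.conn))
        tri_mean = lamin[self.mesh.surf_tris].mean(axis=1)
        es_tri = stiffness_scale(tri_mean, self.kin)
        return es_tri[self.mesh.shell_parent_tri]


def _inflate(c: _Coupler, settle: bool = True) -> MechanicalSolution:
    """Osmotic inflation, then (on a substrate) settling at zero cap stress.

    Inflation is solved with the equator-pinned gauge; the settle stage
    drops that pin and iterates the pressure loop at sigma_cap = 0 with the
    substrate contact carrying the vertical force, so the species are
    initialized on a genuinely resting state.
    """
    prob = c.prob
    sol = None
    Pmax = c.cfg.material.Pmax
    for frac in (0.35, 0.7, 0.9, 1.0):
        sol = prob.solve_equilibrium(
            LoadState(dP=frac * Pmax), prev=sol, phase="inflate"
        )
    if settle and c.cfg.pillars is not None:
        # switch to the compression gauge: drop the equator pin and hold the
        # apex at a FIXED height (the post-inflation roof average) while the
        # pressure loop settles. A fixed pin avoids the ratchet of the
        # refreshed roof condition at zero load, and keeps a height gauge:
        # the steric repulsion alone decays with height, so an unpinned
        # resting shell on pillars has no preferred vertical position.
        roof0 = prob.roof_average_uz(sol.U)
        c._roof0 = roof0
        for _ in range(10):
            vol_prev = sol.vol_nuc
            sol = prob.equilibrate_pressure(
                LoadState(sigma_cap=0.0, dP=sol.load.dP),
                prev=sol,
                roof_uz=roof0,
                refresh_roof=False,
            )
            if abs(sol.vol_nuc - vol_prev) < 1e-4 * vol_prev:
                break
    return sol


def run_simulation(
    config: SimulationConfig,
    mesh: ReferenceMesh | None = None,
    progress: bool = False,
    resume: SimulationResult | None = None,
) -> SimulationResult:
    """Execute the coupled simulation; returns the scalar log and final state.

    ``resume`` restarts the time loop from the final state of a previous
    result (same mesh and configuration apart from ``t_end``); the returned
    table then covers only the resumed span.
    """
    rng = np.random.default_rng(config.seed)  # reserved for perturbation diagnostics
    c = _Coupler(config, mesh if mesh is not None else (resume.mesh if resume else None))
    prob, trans, kin = c.prob, c.trans, c.kin
    if resume is not None:
        return _run_loop_from(c, config, resume)

    # 1-2: inflation and steady-state initialization
    sol = _inflate(c)
    measures0 = {
        "area_outer": sol.area_outer,
        "area_inner": sol.area_inner,
        "vol_nuc": sol.vol_nuc,
    }
    u_vert = c.vertex_displacement(sol)
    maps = trans.build_maps(u_vert)
    f_out = c.f_actin_outer(maps.x_outer)
    f_mean = float((maps.M_outer @ f_out) / maps.M_outer.sum())
    if config.l_ref_mode == "auto":
        # normalize the lamin-stiffness coupling by this run's own initial
        # steady-state density, so every run starts at Escale = 1 and the
        # coupling acts on lamin redistribution during the run. (The
        # reference inflation curve saturates near 890 Pa, so an absolute
        # normalization leaves a lamin-depleted shell with no equilibrium at
        # the 820 Pa osmotic set-point.)
        ss_fields, _ = initial_steady_state(
            sol.area_inner, sol.area_outer, sol.vol_nuc,
            kin, f_mean, mode=config.init_mode,
        )
        kin = replace(kin, L_ref=float(ss_fields["lamin"]))
        c.kin = kin
    fields, cyt = initial_steady_state(
        sol.area_inner, sol.area_outer, sol.vol_nuc, kin, f_mean,
        mode=config.init_mode,
    )
    ns = trans.n_surf
    nv = trans.n_vert
    species = SpeciesState(
        lamin=np.full(ns, fields["lamin"]),
        npc=np.full(ns, fields["npc"]),
        npc_a=np.full(ns, fields["npc_a"]),
        lamin_phos=np.full(nv, fields["lamin_phos"]),
        yap_nuc=np.full(nv, fields["yap_nuc"]),
    )

    # 3: re-solve with lamin-scaled stiffness (resting gauge: substrate
    # contact, no equator pin; for a free shell keep the inflation gauge)
    escale = c.escale_from_lamin(species.lamin)
    prob.set_stiffness_scale(escale)
    if config.pillars is None:
        sol = prob.solve_equilibrium(sol.load, prev=sol, phase="inflate")
    else:
        sol = prob.solve_equilibrium(
            sol.load, prev=sol, phase="compress",
            roof_uz=getattr(c, "_roof0", None),
        )
    u_vert = c.vertex_displacement(sol)
    maps = trans.build_maps(u_vert)

    # 4: reference stretch and cytosol pools
    alpha_init = sol.area_outer / prob.area_ref_outer
    cyt = cytosolic_yap(
        float(N_CONV * maps.M_vol @ species.yap_nuc), sol.vol_nuc, kin
    )

    rows = []
    t = 0.0
    dP = sol.load.dP
    next_out = 0.0
    state = CoupledState(t, sol, species, cyt.y_cyto, cyt.y_free, escale, u_vert)

    def record(state, maps):
        rows.append(
            metrics_row(c, state, maps, alpha_init)
        )

    record(state, maps)
    next_out = config.output_every

    return _time_loop(c, config, sol, species, cyt, escale, maps, t, dP,
                      rows, next_out, alpha_init, measures0, progress)


def _run_loop_from(c, config, resume: SimulationResult):
    """Restart the coupled loop from a previous result's final state."""
    c.kin = replace(c.kin, L_ref=resume.l_ref_used)
    st = resume.final
    sol = st.mech
    species = st.species.copy()
    escale = st.escale_elem
    c.prob.set_stiffness_scale(escale)
    c._last_unuc = st.u_vertices
    c._roof0 = c.prob.roof_average_uz(st.mech.U)
    maps = c.trans.build_maps(st.u_vertices)
    cyt = cytosolic_yap(
        float(N_CONV * maps.M_vol @ species.yap_nuc), sol.vol_nuc, c.kin
    )
    t = st.t
    next_out = (np.floor(t / config.output_every) + 1) * config.output_every
    return _time_loop(c, config, sol, species, cyt, escale, maps, t,
                      sol.load.dP, [], next_out, resume.alpha_init,
                      resume.measures0, False)


def _time_loop(c, config, sol, species, cyt, escale, maps, t, dP, rows,
               next_out, alpha_init, measures0, progress):
    prob, trans, kin = c.prob, c.trans, c.kin

    def record(state, maps):
        rows.append(metrics_row(c, state, maps, alpha_init))

    state = CoupledState(t, sol, species, cyt.y_cyto, cyt.y_free, escale,
                         maps.x_vertices - c.mesh.points)
    sigma_cap_bound = min(2000.0, config.sigma_max / 10.0) if config.sigma_max > 0 else None
    try:
        t, state, maps = _advance(
            c, config, sol, species, cyt, escale, maps, t, dP, rows,
            next_out, alpha_init, sigma_cap_bound, record, progress, state,
        )
    except Exception as exc:
        raise SimulationError(
            f"simulation failed at t={t:.1f} s: {exc}", state=state
        ) from exc
    table = pd.DataFrame(rows)
    return SimulationResult(
        config=config, mesh=c.mesh, table=table, final=state,
        alpha_init=alpha_init, measures0=measures0, l_ref_used=kin.L_ref,
    )


def _advance(c, config, sol, species, cyt, escale, maps, t, dP, rows,
             next_out, alpha_init, sigma_cap_bound, record, progress, state):
    prob, trans, kin = c.prob, c.trans, c.kin
    while t < config.t_end - 1e-9:
        # time step from the stress-increment rule
        dt = config.dt_max
        if sigma_cap_bound and config.sigma_max > 0:
            s_now = cap_stress_schedule(t, config.sigma_max, config.t0_cap)
            room = 1.0 - (s_now + sigma_cap_bound) / config.sigma_max
            if room > 0:
                t_next = -config.t0_cap * np.log(room)
                dt = min(dt, max(t_next - t, config.dt_min))
        dt = float(np.clip(dt, config.dt_min, config.dt_max))
        dt = min(dt, config.t_end - t)
        t += dt
        # 5-6: mechanics at the new cap stress with pressure equilibration.
        # At zero cap load the quasi-static geometry is already settled, so
        # the mechanics stays frozen and only the kinetics advance.
        s_cap = cap_stress_schedule(t, config.sigma_max, config.t0_cap)
        if s_cap > 0:
            roof = prob.roof_average_uz(sol.U)
            sol = prob.equilibrate_pressure(
                LoadState(sigma_cap=s_cap, dP=dP, t=t), prev=sol, roof_uz=roof
            )
        dP = sol.load.dP
        # 7: updated geometry and cytosolic F-actin
        u_vert = c.vertex_displacement(sol)
        new_maps = trans.build_maps(u_vert)
        f_out = c.f_actin_outer(new_maps.x_outer)
        # 8-9: dilution then implicit reaction-diffusion on the new domain
        trans.dilute_state(species, maps, new_maps)
        maps = new_maps
        kfl_eff = kin.kfl * hill_stiffness_factor(f_out, kin)
        trans.step_lamin_pair(
            species, maps, dt, kin.DL, kin.DL_vol, kin.krl, kfl_eff,
            literal_exchange_measure=config.literal_exchange_measure,
        )
        kf_npc = kin.kf_npc * f_out * species.lamin * kin.mA
        trans.step_surface_pair(species, maps, dt, kin.DNPC, kf_npc, kin.kr_npc)
        alpha_for_import = (
            maps.alpha_outer
            if config.alpha_mode == "local"
            else np.full(trans.n_surf, sol.area_outer / prob.area_ref_outer)
        )
        kin_tot = yap_import_rate(alpha_for_import, alpha_init, species.npc_a, kin)
        trans.step_yap(species, maps, dt, kin.DY, kin_tot, kin.kout, cyt.y_free)
        species.clip_negative()
        # 10: cytosol pools and stiffness coupling
        cyt = cytosolic_yap(
            float(N_CONV * maps.M_vol @ species.yap_nuc), sol.vol_nuc, kin
        )
        escale = c.escale_from_lamin(species.lamin)
        prob.set_stiffness_scale(escale)
        state = CoupledState(t, sol, species, cyt.y_cyto, cyt.y_free, escale, u_vert)
        if t >= next_out - 1e-9 or t >= config.t_end - 1e-9:
            record(state, maps)
            next_out += config.output_every
        if progress:
            print(f"t={t:8.1f} s sigma_cap={s_cap:6.1f} Pa dP={dP:7.1f} Pa "
                  f"vol={sol.vol_nuc:7.2f} um^3", flush=True)

    return t, state, maps


def run_pitch_sweep(
    config: SimulationConfig,
    pitches,
    sigma_maxes,
    mesh: ReferenceMesh | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run one simulation per (pitch, sigma_max) and summarize key outputs.

    Individual failures are recorded (``ok=False``) and the sweep continues.
    The same mesh, solver settings and seed are used for every row.
    """
    if len(list(pitches)) == 0:
        raise ValueError("empty pitch list")
    rows = []
    for s_max in sigma_maxes:
        for pitch in pitches:
            cfg = replace(
                config,
                pillars=replace(config.pillars, p_np=float(pitch)),
                sigma_max=float(s_max),
            )
            try:
                res = run_simulation(cfg, mesh=mesh, progress=progress)
                tab = res.table
                rows.append({
                    "pitch": pitch,
                    "sigma_max": s_max,
                    "ok": True,
                    "mean_lower_stretch": float(tab["mean_lower_stretch"].iloc[-1]),
                    "max_tension_mN_m": float(tab["max_tension_mN_m"].max()),
                    "integrated_force_pN_s": float(
                        np.trapezoid(tab["FL_max_pN"], tab["t"])
                    ),
                    "yap_nc": float(tab["yap_nc"].iloc[-1]),
                    "vol_nuc": float(tab["vol_nuc_um3"].iloc[-1]),
                })
            except Exception as exc:  # noqa: BLE001 - sweep robustness
                rows.append({
                    "pitch": pitch, "sigma_max": s_max, "ok": False,
                    "error": str(exc),
                })
    return pd.DataFrame(rows)
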