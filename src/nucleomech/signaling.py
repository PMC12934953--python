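"""Reaction rate laws, cytosolic pools and steady-state initialization.

Kinetics of the three coupled circuits:

* lamin A/C cycling between the NE-bound pool [L] and the nucleoplasmic
  phosphorylated pool [L]_phos, with dephosphorylation rate saturating in the
  cytoskeletal stiffness proxy p_cyto [F]^2.6 (a Hill-type factor);
* NPC activation by F-actin / lamin / active myosin (mass action) and
  first-order deactivation;
* stretch-gated YAP/TAZ nuclear import through activated NPCs, with a
  well-mixed cytosolic pool partitioned into free and sequestered fractions
  at pseudo-steady state.

All defaults are the published parameter set; the active-myosin level [M]_A
and the nuclear export rate k_out are not part of that printed set (they are
inherited from a prior model lineage) and are therefore required,
documented-default configuration values rather than calibrated constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import N_CONV

__all__ = [
    "KineticParams",
    "CytosolState",
    "hill_stiffness_factor",
    "lamin_cycling_rates",
    "npc_activation_rates",
    "yap_import_rate",
    "cytosolic_yap",
    "yap_boundary_flux",
    "initial_steady_state",
]


@dataclass(frozen=True)
class KineticParams:
    """Reaction-transport constants (units noted per field)."""

    # diffusion (um^2/s)
    DL: float = 0.001
    DL_vol: float = 4.0
    DNPC: float = 0.001
    DY: float = 4.0
    # lamin cycling
    krl: float = 0.001  # s^-1
    kfl: float = 415.5  # um^-2 uM^-1 s^-1 (maximum dephosphorylation rate)
    pcyto: float = 9e-6  # kPa uM^-2.6
    CL: float = 100.0  # kPa
    # NPC activation
    kf_npc: float = 2.8e-7  # um^2 s^-1 uM^-1
    kr_npc: float = 8.7  # s^-1
    # YAP/TAZ transport
    kin_b: float = 1.0  # um^-2 s^-1 uM^-1
    kin: float = 10.0  # s^-1 uM^-1 (per activated NPC density)
    kout: float = 1.0  # um^-2 s^-1 uM^-1 (non-authoritative default)
    alpha0: float = 5.0
    phi_scale: float = 0.2
    # cytosolic YAP kinetics
    kCN: float = 0.56  # s^-1
    kCY: float = 7.6e-4  # uM^-2 s^-1
    kNC: float = 0.14  # s^-1
    # fixed cytosolic levels
    mA: float = 1.5  # uM active myosin (non-authoritative default)
    # totals (quarter cell)
    NY: float = 5.339e5
    NL: float = 3.202e5
    NNPC: float = 594.7
    vol_tot: float = 1024.0  # um^3
    # F-actin field
    f0: float = 140.0  # uM, baseline (flat substrate)
    f1: float = 20.0  # uM
    d_f: float = 0.5  # um
    h0: float = 2.0  # um
    # stiffness coupling
    phi_L: float = 0.5
    L_ref: float = 2980.0  # um^-2

    def __post_init__(self):
        if not (0.0 <= self.phi_L <= 1.0):
            raise ValueError("phi_L must lie in [0, 1]")

    def f0_for_pillars(self, r_np: float, flat: bool) -> float:
        """Baseline F-actin depends on pillar radius (curvature-inhibited
        focal adhesions): 140 uM flat, 100 uM at r=0.2 um, 120 uM at 0.5 um."""
        if flat:
            return 140.0
        if abs(r_np - 0.2) < 0.125:
            return 100.0
        return 120.0


@dataclass
class CytosolState:
    """Well-mixed cytosolic YAP/TAZ pools (uM)."""

    y_cyto: float
    y_free: float
    y_seq: float


def hill_stiffness_factor(f_actin, params: KineticParams):
    """Saturating factor p_cyto [F]^2.6 / (CL + p_cyto [F]^2.6) in [0, 1)."""
    x = params.pcyto * np.asarray(f_actin, dtype=float) ** 2.6
    return x / (params.CL + x)


def lamin_cycling_rates(lamin, lamin_phos, f_actin, params: KineticParams):
    """(phosphorylation flux, dephosphorylation flux), both um^-2 s^-1.

    Phosphorylation removes NE-bound lamin at rate krl [L]; dephosphorylation
    returns nucleoplasmic lamin at kfl * Hill([F]) * [L]_phos.
    """
    phos = params.krl * np.asarray(lamin, dtype=float)
    dephos = params.kfl * hill_stiffness_factor(f_actin, params) * np.asarray(
        lamin_phos, dtype=float
    )
    return phos, dephos


def npc_activation_rates(npc, npc_a, f_actin, lamin, params: KineticParams):
    """(forward, reverse) rates of NPC activation (um^-2 s^-1)."""
    fwd = params.kf_npc * np.asarray(f_actin) * np.asarray(lamin) * params.mA * np.asarray(npc)
    rev = params.kr_npc * np.asarray(npc_a)
    return fwd, rev


def yap_import_rate(alpha_local, alpha_init, npc_a, params: KineticParams):
    """Stretch-gated total import rate k_in,tot (um^-2 s^-1 uM^-1)."""
    alpha_local = np.asarray(alpha_local, dtype=float)
    if np.any(alpha_local <= 0):
        raise ValueError("alpha must be positive")
    base = params.kin_b + params.kin * np.asarray(npc_a)
    return params.phi_scale * base * np.exp((alpha_local - alpha_init) / params.alpha0)


def free_fraction(params: KineticParams) -> float:
    """Pseudo-steady free fraction of cytosolic YAP/TAZ."""
    deseq = params.kCN + params.kCY * params.f0 * params.mA
    return deseq / (params.kNC + deseq)


def cytosolic_yap(yap_total_molecules: float, vol_nuc: float, params: KineticParams) -> CytosolState:
    """Cytosolic pools from global conservation of N_Y molecules.

    ``yap_total_molecules`` is the number of YAP/TAZ molecules currently in
    the nuclear domain (N_conv * integral of [Y]_nuc over the deformed
    volume); ``vol_nuc`` the deformed nuclear volume (um^3).
    """
    if vol_nuc >= params.vol_tot:
        raise ValueError("nuclear volume exceeds total cell volume")
    y_cyto = (params.NY - yap_total_molecules) / (N_CONV * (params.vol_tot - vol_nuc))
    y_cyto = max(y_cyto, 0.0)
    ff = free_fraction(params)
    return CytosolState(y_cyto=y_cyto, y_free=y_cyto * ff, y_seq=y_cyto * (1.0 - ff))


def yap_boundary_flux(yap_nuc, y_free, kin_tot, params: KineticParams):
    """Net nuclear influx (uM um / s) through the NE: import minus efflux."""
    return (np.asarray(kin_tot) * y_free - params.kout * np.asarray(yap_nuc)) / N_CONV


def initial_steady_state(
    area_inner: float,
    area_outer: float,
    vol_nuc: float,
    params: KineticParams,
    f_actin_mean: float,
    mode: str = "effective",
):
    """Uniform well-mixed steady state of the five species.

    ``mode='effective'`` solves the actual fixed point of the cycling
    kinetics with the Hill-saturated dephosphorylation rate evaluated at the
    mean initial F-actin level (the initialized system is then stationary).
    ``mode='literal'`` evaluates the published closed-form rows verbatim
    (bare kfl, printed denominator structure); that state reproduces the
    reference lamin density [L]_ref but is not an exact fixed point of the
    kinetics. Returns (dict of uniform concentrations, CytosolState).
    """
    if min(area_inner, area_outer, vol_nuc) <= 0:
        raise ValueError("areas and volume must be positive")
    p = params
    if mode == "literal":
        lphos = p.NL * p.krl / (p.kfl * vol_nuc * N_CONV + p.krl * area_inner)
        lam = (p.NL - lphos * vol_nuc * N_CONV) / area_inner
    elif mode == "effective":
        kfl_eff = p.kfl * float(hill_stiffness_factor(f_actin_mean, p))
        # pointwise balance krl L = kfl_eff Lphos with NL conserved
        lphos = p.NL * p.krl / (kfl_eff * area_inner + p.krl * N_CONV * vol_nuc)
        lam = kfl_eff * lphos / p.krl
    else:
        raise ValueError("mode must be 'effective' or 'literal'")
    # NPC partition at the local steady state
    k_act = p.kf_npc * f_actin_mean * lam * p.mA
    frac_a = k_act / (k_act + p.kr_npc)
    npc_tot = p.NNPC / area_outer
    npc_a = npc_tot * frac_a
    npc = npc_tot - npc_a
    # YAP/TAZ: influx/efflux balance with the conservation constraint
    ff = free_fraction(p)
    kin_tot0 = p.phi_scale * (p.kin_b + p.kin * npc_a)  # alpha = alpha_init at t=0
    num = p.NY * ff * kin_tot0
    den = p.kout * (p.vol_tot - vol_nuc) + ff * kin_tot0 * vol_nuc
    y_nuc = num / den / N_CONV
    cyto = cytosolic_yap(y_nuc * N_CONV * vol_nuc, vol_nuc, p)
    fields = {
        "lamin": lam,
        "npc": npc,
        "npc_a": npc_a,
        "lamin_phos": lphos,
        "yap_nuc": y_nuc,
    }
    return fields, cyto
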