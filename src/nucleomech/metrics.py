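"""Derived quantities reported from simulation state.

All metrics are pure functions of the recorded state: lower-NE average
stretch (inner surface, below the indentation level), maximum NE tension at
the membrane midplane, YAP/TAZ nuclear-to-cytosolic ratio, lower-region lamin
statistics, pointwise force per lamin subunit, the critical pitch of a sweep
and the time-integrated force proxy for rupture likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mechanics import mooney_rivlin_piola

__all__ = [
    "mean_lower_stretch",
    "critical_pitch",
    "max_tension",
    "yap_nc_ratio",
    "integrated_force",
    "force_per_lamin_field",
    "metrics_row",
]


def _inner_face_data(mesh, maps):
    tris = mesh.surf_tris
    ref = mesh.points[mesh.inner_verts]
    x = maps.x_inner

    def areas(c):
        return 0.5 * np.linalg.norm(
            np.cross(c[tris[:, 1]] - c[tris[:, 0]], c[tris[:, 2]] - c[tris[:, 0]]),
            axis=1,
        )

    a_ref = areas(ref)
    a_def = areas(x)
    centroid_z = x[tris][:, :, 2].mean(axis=1)
    return a_ref, a_def, centroid_z


def mean_lower_stretch(mesh, maps, pillars=None, offset: float = 0.05):
    """Area-weighted mean inner-NE stretch over the lower nuclear region.

    The region is the set of inner-surface elements whose deformed height
    lies below z_center + ``offset``, where z_center is the deformed height
    of the inner NE directly above the central pillar (for a flat substrate:
    the lowest point of the deformed inner NE). Returns NaN if the selection
    is empty.
    """
    a_ref, a_def, cz = _inner_face_data(mesh, maps)
    if pillars is not None and not pillars.flat:
        z_center = float(maps.x_inner[mesh.bottom_column, 2])
    else:
        z_center = float(cz.min())  # flat: lowest inner-NE element
    sel = cz < z_center + offset
    if not np.any(sel):
        return float("nan")
    stretch = a_def[sel] / a_ref[sel]
    w = a_def[sel]
    return float((stretch * w).sum() / w.sum())


def critical_pitch(sweep: pd.DataFrame, column: str = "mean_lower_stretch"):
    """Pitch maximizing the lower-NE stretch in a sweep table.

    Ties break to the smaller pitch. Returns (pitch, at_boundary_flag); a
    maximum on the boundary of the swept range is flagged.
    """
    tab = sweep.sort_values("pitch")
    if "ok" in tab.columns:
        tab = tab[tab["ok"].astype(bool)]
    if len(tab) < 3:
        raise ValueError("need at least 3 pitches to locate a maximum")
    vals = tab[column].to_numpy(dtype=float)
    pitches = tab["pitch"].to_numpy(dtype=float)
    i = int(np.argmax(vals))  # argmax takes the first (= smallest pitch) on ties
    at_boundary = i in (0, len(vals) - 1)
    return float(pitches[i]), at_boundary


def max_tension(prob, U, P) -> float:
    """Maximum NE tension over the membrane surface, in mN/m."""
    gamma = prob.membrane_tension(U, P)  # Pa um
    return float(gamma.max()) * 1e-3


def yap_nc_ratio(yap_nuc, M_vol, y_cyto: float) -> float:
    """Volume-averaged nuclear YAP/TAZ over the cytosolic concentration."""
    mean_nuc = float(M_vol @ yap_nuc) / float(M_vol.sum())
    if y_cyto <= 0:
        return float("inf")
    return mean_nuc / y_cyto


def integrated_force(t, fl_max) -> float:
    """Area under the maximum force-per-lamin curve (pN s)."""
    t = np.asarray(t, dtype=float)
    fl = np.asarray(fl_max, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two time points")
    return float(np.trapezoid(fl, t))


def force_per_lamin_field(prob, U, P, lamin, floor: float = 1.0):
    """|sigma_NE| / [L] (pN) at outer-face quadrature points.

    The true traction is the nominal traction P.N divided by the local area
    stretch (Nanson); lamin is interpolated from the surface vertex field.
    """
    mesh = prob.mesh
    F, pq = prob._eval_at_outer_faces(U, P)
    es = prob._escale_face()[:, None]
    Ppk, J, Finv, I1, I2 = mooney_rivlin_piola(
        F, pq, prob.material.E1, prob.material.E2, es
    )
    Xq = prob.Xq_outer
    N = Xq - mesh.center
    N /= np.linalg.norm(N, axis=-1, keepdims=True)
    T = np.einsum("fqij,fqj->fqi", Ppk, N)
    crd, crr = prob._outer_cross(U, "outer")
    alpha = np.linalg.norm(crd, axis=2) / np.linalg.norm(crr, axis=2)
    tmag = np.linalg.norm(T, axis=-1) / alpha
    lam_face = lamin[mesh.surf_tris].mean(axis=1)  # (ntri,)
    lam_q = np.maximum(lam_face[:, None], floor)
    return tmag / lam_q


def metrics_row(coupler, state, maps, alpha_init) -> dict:
    """One scalar-log row computed from a coupled state (driver callback)."""
    from .signaling import yap_import_rate  # local import to avoid cycles

    prob = coupler.prob
    mesh = coupler.mesh
    kin = coupler.kin
    sol = state.mech
    sp = state.species
    f_out = coupler.f_actin_outer(maps.x_outer)
    kin_tot = yap_import_rate(maps.alpha_outer, alpha_init, sp.npc_a, kin)
    fl = force_per_lamin_field(prob, sol.U, sol.P, sp.lamin)
    # lower-region lamin (reference coordinates X<1.5, Y<1.5, Z<znuc+1)
    Xo = mesh.points[mesh.outer_verts]
    low = (
        (Xo[:, 0] < 1.5)
        & (Xo[:, 1] < 1.5)
        & (Xo[:, 2] < mesh.spec.znuc + 1.0)
    )
    w = maps.M_inner[low]
    lam_low = float((sp.lamin[low] * w).sum() / w.sum()) if w.sum() > 0 else float("nan")
    totals = coupler.trans.totals(sp, maps)
    row = {
        "t": state.t,
        "sigma_cap_Pa": sol.load.sigma_cap,
        "dP_Pa": sol.load.dP,
        "vol_nuc_um3": sol.vol_nuc,
        "area_outer_um2": sol.area_outer,
        "area_inner_um2": sol.area_inner,
        "shell_vol_dev": sol.shell_vol_dev,
        "mean_lower_stretch": mean_lower_stretch(mesh, maps, coupler.cfg.pillars),
        "max_tension_mN_m": max_tension(prob, sol.U, sol.P),
        "npcA_mean": float((maps.M_outer @ sp.npc_a) / maps.M_outer.sum()),
        "yap_nc": yap_nc_ratio(sp.yap_nuc, maps.M_vol, state.y_cyto),
        "lamin_lower_mean": lam_low,
        "FL_max_pN": float(fl.max()),
        "Y_free_uM": state.y_free,
        "Y_cyto_uM": state.y_cyto,
        "kin_tot_mean": float((maps.M_outer @ kin_tot) / maps.M_outer.sum()),
        "f_actin_mean": float((maps.M_outer @ f_out) / maps.M_outer.sum()),
    }
    row.update(totals)
    return row
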