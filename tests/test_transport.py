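"""Transport: dilution conservation, implicit stepping, splitting order,
inner-surface maps and lamin/NPC/YAP conservation properties."""

import numpy as np
import pytest

from nucleomech.fixtures import PrescribedDeformation
from nucleomech.signaling import KineticParams
from nucleomech.transport import (
    N_CONV,
    SpeciesState,
    TransportSystem,
    step_surface_species,
    step_volume_species,
)


@pytest.fixture(scope="module")
def system(coarse_mesh):
    return TransportSystem(coarse_mesh)


def maps_for(system, mesh, kind, s, amplitude=0.2):
    pd = PrescribedDeformation(kind=kind, amplitude=amplitude, center=mesh.center)
    u = pd.displacement(mesh.points, s)
    return system.build_maps(u)


def uniform_state(system, lamin=3000.0, npc=5.0, npc_a=0.1, lphos=0.2, ynuc=0.4):
    return SpeciesState(
        lamin=np.full(system.n_surf, lamin),
        npc=np.full(system.n_surf, npc),
        npc_a=np.full(system.n_surf, npc_a),
        lamin_phos=np.full(system.n_vert, lphos),
        yap_nuc=np.full(system.n_vert, ynuc),
    )


class TestMaps:
    def test_reference_inner_to_outer_area_ratio(self, system, coarse_mesh):
        # concentric map: inner measure / outer measure = ((R0-dT)/R0)^2
        spec = coarse_mesh.spec
        ratio = system.M_inner_ref.sum() / system.M_outer_ref.sum()
        assert ratio == pytest.approx((spec.r_inner / spec.R0) ** 2, rel=1e-9)

    def test_uniform_dilation_scales_measures(self, system, coarse_mesh):
        lam = 1.2
        maps = maps_for(system, coarse_mesh, "dilation", 1.0, amplitude=lam - 1.0)
        assert np.allclose(maps.alpha_outer, lam**2, rtol=1e-12)
        assert np.allclose(maps.alpha_inner, lam**2, rtol=1e-12)
        assert maps.M_vol.sum() == pytest.approx(
            lam**3 * system.M_vol_ref.sum(), rel=1e-12
        )


class TestDilution:
    def test_exact_conservation_and_halving(self, system, coarse_mesh):
        lam = np.sqrt(2.0)  # area doubles
        ref = system.build_maps(np.zeros((system.n_vert, 3)))
        new = maps_for(system, coarse_mesh, "dilation", 1.0, amplitude=lam - 1.0)
        v = np.full(system.n_surf, 5.0)
        v2 = system.dilute(v, ref.M_outer, new.M_outer)
        assert np.allclose(v2, 2.5, rtol=1e-12)
        assert new.M_outer @ v2 == pytest.approx(ref.M_outer @ v, rel=1e-14)

    def test_state_dilution_conserves_all_totals(self, system, coarse_mesh):
        state = uniform_state(system)
        ref = system.build_maps(np.zeros((system.n_vert, 3)))
        tot0 = system.totals(state, ref)
        new = maps_for(system, coarse_mesh, "squash", 1.0, amplitude=0.3)
        system.dilute_state(state, ref, new)
        tot1 = system.totals(state, new)
        for k in tot0:
            assert tot1[k] == pytest.approx(tot0[k], rel=1e-12)


class TestImplicitStep:
    def test_uniform_field_static_domain_unchanged(self, system, coarse_mesh):
        ref = system.build_maps(np.zeros((system.n_vert, 3)))
        c = np.full(system.n_vert, 0.7)
        out = step_volume_species(c, 10.0, ref, ref, D=4.0)
        assert np.allclose(out, 0.7, rtol=1e-12)
        v = np.full(system.n_surf, 1.3)
        out = step_surface_species(v, 10.0, ref, ref, D=0.001)
        assert np.allclose(out, 1.3, rtol=1e-12)

    def test_decay_matches_exponential_to_first_order(self, system):
        ref = system.build_maps(np.zeros((system.n_vert, 3)))
        k = 0.05
        for dt in (1.0, 0.5):
            c = np.full(system.n_vert, 1.0)
            out = step_volume_species(c, dt, ref, ref, D=0.0,
                                      rate_imp=np.full(system.n_vert, k))
            # implicit Euler: 1/(1+k dt) = e^{-k dt} + O(dt^2)
            err = abs(out[0] - np.exp(-k * dt))
            assert err < (k * dt) ** 2

    def test_diffusion_conserves_total(self, system, coarse_mesh):
        rng = np.random.default_rng(5)
        ref = maps_for(system, coarse_mesh, "squash", 1.0, amplitude=0.2)
        c = rng.uniform(0.5, 2.0, system.n_vert)
        tot0 = ref.M_vol @ c
        out = step_volume_species(c, 5.0, ref, ref, D=4.0)
        assert ref.M_vol @ out == pytest.approx(tot0, rel=1e-12)


class TestSplittingOrder:
    def test_first_order_in_dt_under_moving_domain(self, system, coarse_mesh):
        """Halving dt roughly halves the splitting error (O(dt) scheme)."""
        rng = np.random.default_rng(12)
        x = coarse_mesh.points[coarse_mesh.outer_verts] - coarse_mesh.center
        v0 = 5.0 + np.cos(3.0 * np.arctan2(x[:, 1], x[:, 0])) * np.tanh(x[:, 2])

        def advance(nsteps, T=20.0):
            v = v0.copy()
            dt = T / nsteps
            maps = system.build_maps(np.zeros((system.n_vert, 3)))
            for i in range(1, nsteps + 1):
                s = np.sin(np.pi * i * dt / T) * 0.5 + 0.5 * (i * dt / T)
                new = maps_for(system, coarse_mesh, "squash", s, amplitude=0.3)
                v = system.dilute(v, maps.M_outer, new.M_outer)
                v = TransportSystem._implicit_solve(
                    new.M_outer, new.K_outer, 0.05, dt, v
                )
                maps = new
            return v

        fine = advance(64)
        errs = [np.linalg.norm(advance(n) - fine) for n in (8, 16, 32)]
        assert errs[1] < errs[0] * 0.7
        assert errs[2] < errs[1] * 0.7


class TestReactionConservation:
    def test_npc_pair_sum_conserved_under_cycling(self, system, coarse_mesh):
        maps = maps_for(system, coarse_mesh, "squash", 1.0, amplitude=0.25)
        state = uniform_state(system)
        rng = np.random.default_rng(3)
        kf = rng.uniform(0.05, 0.3, system.n_surf)
        tot0 = maps.M_outer @ (state.npc + state.npc_a)
        for _ in range(20):
            system.step_surface_pair(state, maps, 5.0, 0.001, kf, 8.7)
        tot1 = maps.M_outer @ (state.npc + state.npc_a)
        assert tot1 == pytest.approx(tot0, rel=1e-10)
        assert state.npc.min() >= -1e-12
        assert state.npc_a.min() >= -1e-12

    def test_total_lamin_conserved_under_full_cycling(self, system, coarse_mesh):
        """Surface + volume lamin molecules drift < 0.1% per 100 static steps."""
        kin = KineticParams()
        maps = system.build_maps(np.zeros((system.n_vert, 3)))
        state = uniform_state(system, lamin=3000.0, lphos=0.25)
        def total(st):
            return maps.M_inner @ st.lamin + N_CONV * maps.M_vol @ st.lamin_phos
        tot0 = total(state)
        kfl_eff = np.full(system.n_surf, 14.0)
        for _ in range(100):
            system.step_lamin_pair(state, maps, 10.0, kin.DL, kin.DL_vol,
                                   kin.krl, kfl_eff)
        assert total(state) == pytest.approx(tot0, rel=1e-3)
        assert state.lamin.min() >= 0.0

    def test_positivity_preserved(self, system, coarse_mesh):
        maps = system.build_maps(np.zeros((system.n_vert, 3)))
        state = uniform_state(system, lamin=1.0, lphos=1e-6)
        kfl_eff = np.full(system.n_surf, 20.0)
        for _ in range(30):
            system.step_lamin_pair(state, maps, 50.0, 0.001, 4.0, 0.001, kfl_eff)
        floor = -1e-10 * max(state.lamin.max(), 1.0)
        assert state.lamin.min() >= floor
        assert state.lamin_phos.min() >= floor

    def test_clip_negative_counts_and_raises(self, system):
        state = uniform_state(system)
        state.npc[0] = -1e-14
        n = state.clip_negative()
        assert n == 1 and state.npc[0] == 0.0
        state.npc[0] = -1.0
        with pytest.raises(FloatingPointError):
            state.clip_negative()
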