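"""Rate laws, cytosolic pools and steady-state initialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleomech.signaling import (
    CytosolState,
    KineticParams,
    cytosolic_yap,
    free_fraction,
    hill_stiffness_factor,
    initial_steady_state,
    lamin_cycling_rates,
    npc_activation_rates,
    yap_boundary_flux,
    yap_import_rate,
)
from nucleomech.transport import N_CONV

KIN = KineticParams()
# the published initial measures (quarter domain) used as direct inputs
SA_IN0, SA_OUT0, VOL0 = 107.5, 118.4, 152.0


class TestLaminCycling:
    def test_zero_actin_blocks_dephosphorylation(self):
        phos, dephos = lamin_cycling_rates(100.0, 5.0, 0.0, KIN)
        assert dephos == 0.0
        assert phos == pytest.approx(KIN.krl * 100.0)

    def test_hill_factor_arithmetic(self):
        # independent arithmetic: pcyto F^2.6 / (CL + pcyto F^2.6) at F=160
        x = 9e-6 * 160.0**2.6
        assert hill_stiffness_factor(160.0, KIN) == pytest.approx(x / (100.0 + x))

    def test_net_flux_sign(self):
        phos, dephos = lamin_cycling_rates(2000.0, 0.0, 150.0, KIN)
        assert dephos == 0.0 and phos > 0


class TestNpcActivation:
    def test_forward_zero_without_substrate(self):
        fwd, rev = npc_activation_rates(0.0, 1.0, 150.0, 3000.0, KIN)
        assert fwd == 0.0
        assert rev == pytest.approx(KIN.kr_npc)

    def test_steady_fraction_closed_form(self):
        f, lam = 150.0, 3000.0
        k_act = KIN.kf_npc * f * lam * KIN.mA
        frac = k_act / (k_act + KIN.kr_npc)
        # at the predicted partition the fluxes balance
        npc_tot = 5.0
        fwd, rev = npc_activation_rates(
            npc_tot * (1 - frac), npc_tot * frac, f, lam, KIN
        )
        assert fwd == pytest.approx(rev, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        f=st.floats(1.0, 300.0),
        lam=st.floats(1.0, 6000.0),
        npc=st.floats(0.0, 10.0),
    )
    def test_forward_rate_monotone(self, f, lam, npc):
        base, _ = npc_activation_rates(npc, 0.0, f, lam, KIN)
        up, _ = npc_activation_rates(npc, 0.0, f * 1.1 + 1e-6, lam, KIN)
        assert up >= base


class TestYapTransport:
    def test_import_rate_at_reference_stretch(self):
        k = yap_import_rate(1.5, 1.5, 0.0, KIN)
        assert k == pytest.approx(KIN.phi_scale * KIN.kin_b)
        k2 = yap_import_rate(1.5 + KIN.alpha0, 1.5, 0.0, KIN)
        assert k2 == pytest.approx(np.e * k)

    @settings(max_examples=50, deadline=None)
    @given(
        alpha=st.floats(0.5, 4.0),
        npca=st.floats(0.0, 3.0),
        dnpca=st.floats(0.001, 1.0),
        dalpha=st.floats(0.001, 1.0),
    )
    def test_import_rate_monotone_in_both_arguments(self, alpha, npca, dnpca, dalpha):
        k0 = yap_import_rate(alpha, 1.5, npca, KIN)
        assert yap_import_rate(alpha + dalpha, 1.5, npca, KIN) > k0
        assert yap_import_rate(alpha, 1.5, npca + dnpca, KIN) > k0

    def test_boundary_flux_balance(self):
        assert yap_boundary_flux(0.0, 0.0, 1.0, KIN) == 0.0
        ynuc = 0.3
        yfree = KIN.kout * ynuc / 2.0  # kin_tot = 2 balances
        assert yap_boundary_flux(ynuc, yfree, 2.0, KIN) == pytest.approx(0.0)
        assert yap_boundary_flux(0.1, 1.0, 2.0, KIN) > 0

    def test_cytosol_pools_from_conservation(self):
        # all YAP nuclear -> empty cytosol
        c = cytosolic_yap(KIN.NY, VOL0, KIN)
        assert c.y_cyto == 0.0
        # empty nucleus -> NY spread over the cytosolic volume
        c = cytosolic_yap(0.0, VOL0, KIN)
        assert c.y_cyto == pytest.approx(
            KIN.NY / (N_CONV * (KIN.vol_tot - VOL0))
        )
        assert c.y_cyto == pytest.approx(c.y_free + c.y_seq)
        with pytest.raises(ValueError):
            cytosolic_yap(0.0, KIN.vol_tot + 1.0, KIN)

    def test_free_fraction_without_actomyosin(self):
        kin = KineticParams(kCY=0.0)
        assert free_fraction(kin) == pytest.approx(0.56 / 0.70)

    def test_global_conservation_identity(self):
        # Nconv (Ynuc_total + Ycyto (voltot - vol)) == NY by construction
        ynuc_mols = 0.37 * N_CONV * VOL0
        c = cytosolic_yap(ynuc_mols, VOL0, KIN)
        total = ynuc_mols + N_CONV * c.y_cyto * (KIN.vol_tot - VOL0)
        assert total == pytest.approx(KIN.NY, rel=1e-12)


class TestInitialSteadyState:
    def test_literal_rows_reproduce_reference_density(self):
        fields, _ = initial_steady_state(
            SA_IN0, SA_OUT0, VOL0, KIN, f_actin_mean=140.0, mode="literal"
        )
        assert fields["lamin"] == pytest.approx(KIN.L_ref, rel=0.01)
        tot = fields["npc"] + fields["npc_a"]
        assert tot == pytest.approx(KIN.NNPC / SA_OUT0, rel=1e-9)

    def test_low_lamin_preset_halves_density(self):
        import dataclasses

        low = dataclasses.replace(KIN, NL=1.601e5)
        f_wt, _ = initial_steady_state(SA_IN0, SA_OUT0, VOL0, KIN, 140.0, "literal")
        f_lo, _ = initial_steady_state(SA_IN0, SA_OUT0, VOL0, low, 140.0, "literal")
        assert f_lo["lamin"] == pytest.approx(0.5 * f_wt["lamin"], rel=0.01)

    def test_effective_mode_is_fixed_point_of_cycling(self):
        f_mean = 140.0
        fields, _ = initial_steady_state(
            SA_IN0, SA_OUT0, VOL0, KIN, f_mean, mode="effective"
        )
        phos, dephos = lamin_cycling_rates(
            fields["lamin"], fields["lamin_phos"], f_mean, KIN
        )
        assert phos == pytest.approx(dephos, rel=1e-9)
        # total lamin molecules conserved by construction
        tot = fields["lamin"] * SA_IN0 + N_CONV * VOL0 * fields["lamin_phos"]
        assert tot == pytest.approx(KIN.NL, rel=1e-9)

    def test_yap_initialization_is_flux_balanced(self):
        fields, cyt = initial_steady_state(
            SA_IN0, SA_OUT0, VOL0, KIN, 140.0, mode="effective"
        )
        kin_tot = yap_import_rate(1.5, 1.5, fields["npc_a"], KIN)
        flux = yap_boundary_flux(fields["yap_nuc"], cyt.y_free, kin_tot, KIN)
        scale = KIN.kout * fields["yap_nuc"] / N_CONV
        assert abs(flux) < 1e-9 * scale

    def test_rejects_degenerate_measures(self):
        with pytest.raises(ValueError):
            initial_steady_state(0.0, SA_OUT0, VOL0, KIN, 140.0)
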