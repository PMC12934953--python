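"""Driver orchestration, coupling consistency, metrics and I/O round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nucleomech.driver import (
    SimulationConfig,
    force_per_lamin,
    run_simulation,
    stiffness_scale,
)
from nucleomech.geometry import NanopillarArraySpec, ShellGeometrySpec
from nucleomech.io import (
    config_from_dict,
    config_to_dict,
    load_config,
    read_msh,
    save_config,
    write_msh,
    write_result,
)
from nucleomech.metrics import critical_pitch, integrated_force
from nucleomech.signaling import KineticParams

FLAT = NanopillarArraySpec(0.0, 0.0, 0.0, 0.0)
KIN = KineticParams()


def tiny_config(**kw):
    base = dict(
        shell=ShellGeometrySpec(hedge=0.7),
        pillars=FLAT,
        sigma_max=200.0,
        t0_cap=100.0,
        t_end=40.0,
        output_every=20.0,
        contact_mode="ez",
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestStiffnessScale:
    def test_reference_density_gives_unity(self):
        assert stiffness_scale(KIN.L_ref, KIN) == pytest.approx(1.0)

    def test_lamin_free_keeps_membrane_part(self):
        assert stiffness_scale(0.0, KIN) == pytest.approx(1.0 - KIN.phi_L)

    def test_decoupled_when_phi_zero(self):
        kin = dataclasses.replace(KIN, phi_L=0.0)
        assert stiffness_scale(12345.0, kin) == pytest.approx(1.0)


class TestForcePerLamin:
    def test_unit_conversion_example(self):
        # 1000 Pa over 2980 um^-2 -> ~0.336 pN (Pa um^2 = pN)
        assert force_per_lamin(1000.0, 2980.0) == pytest.approx(0.3356, rel=1e-3)
        assert force_per_lamin(0.0, 2980.0) == 0.0

    def test_reciprocal_in_density_with_floor(self):
        f1 = force_per_lamin(500.0, 2000.0)
        f2 = force_per_lamin(500.0, 1000.0)
        assert f2 == pytest.approx(2 * f1)
        assert force_per_lamin(500.0, 0.01) == pytest.approx(500.0)  # floored


class TestCriticalPitch:
    def test_unimodal_peak(self):
        tab = pd.DataFrame({"pitch": [3, 4, 5], "mean_lower_stretch": [1.1, 1.3, 1.2]})
        p, boundary = critical_pitch(tab)
        assert p == 4 and not boundary

    def test_plateau_tie_breaks_small(self):
        tab = pd.DataFrame(
            {"pitch": [3.5, 4.0, 4.5, 5.0], "mean_lower_stretch": [1.1, 1.2, 1.2, 1.0]}
        )
        p, boundary = critical_pitch(tab)
        assert p == 4.0 and not boundary

    def test_monotone_flagged_as_boundary(self):
        tab = pd.DataFrame({"pitch": [3, 4, 5], "mean_lower_stretch": [1.3, 1.2, 1.1]})
        p, boundary = critical_pitch(tab)
        assert p == 3 and boundary

    def test_needs_three_points(self):
        tab = pd.DataFrame({"pitch": [3, 4], "mean_lower_stretch": [1.1, 1.2]})
        with pytest.raises(ValueError):
            critical_pitch(tab)


class TestIntegratedForce:
    def test_constant_series(self):
        assert integrated_force([0, 10, 20], [2.0, 2.0, 2.0]) == pytest.approx(40.0)
        assert integrated_force([0, 5], [0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            integrated_force([0.0], [1.0])


@pytest.fixture(scope="module")
def short_run(coarse_mesh):
    return run_simulation(tiny_config(), mesh=coarse_mesh)


class TestRunSimulation:
    def test_determinism_bitwise(self, coarse_mesh, short_run):
        res2 = run_simulation(tiny_config(), mesh=coarse_mesh)
        pd.testing.assert_frame_equal(short_run.table, res2.table)

    def test_escale_consistency_roundtrip(self, short_run):
        """The stored stiffness field equals the formula applied to the
        stored lamin field (coupling consistency)."""
        st = short_run.final
        mesh = short_run.mesh
        lam_tri = st.species.lamin[mesh.surf_tris].mean(axis=1)
        es_tri = np.asarray(st.escale_elem[: 3 * len(mesh.surf_tris)]).reshape(-1, 3)
        # all three tets of a prism column share the parent-triangle value
        assert np.allclose(es_tri[:, 0], es_tri[:, 1])
        # invert the affine map to recover the L_ref actually used
        phi = KIN.phi_L
        lref = phi * lam_tri / (es_tri[:, 0] - (1 - phi))
        assert np.allclose(lref, lref[0], rtol=1e-9)
        recomputed = (1 - phi) + phi * lam_tri / lref[0]
        assert np.allclose(recomputed, es_tri[:, 0], rtol=1e-12)

    def test_scalar_log_columns_and_monotonic_time(self, short_run):
        tab = short_run.table
        for col in (
            "t", "sigma_cap_Pa", "dP_Pa", "vol_nuc_um3", "area_outer_um2",
            "area_inner_um2", "L_total", "Lphos_total", "NPC_total",
            "NPCA_total", "Ynuc_total", "yap_nc", "Y_free_uM", "Y_cyto_uM",
            "kin_tot_mean", "mean_lower_stretch", "max_tension_mN_m", "FL_max_pN",
        ):
            assert col in tab.columns
        assert tab["t"].is_monotonic_increasing
        assert np.isfinite(tab.drop(columns=["t"]).to_numpy(dtype=float)).all()


class TestResume:
    def test_checkpoint_restart_reproduces_trajectory(self, coarse_mesh):
        # uniform 10-s steps keep the checkpoint on the full run's time grid
        kw = dict(dt_min=10.0, dt_max=10.0, output_every=20.0)
        full = run_simulation(tiny_config(t_end=60.0, **kw), mesh=coarse_mesh)
        half = run_simulation(tiny_config(t_end=30.0, **kw), mesh=coarse_mesh)
        rest = run_simulation(
            tiny_config(t_end=60.0, **kw), mesh=coarse_mesh, resume=half
        )
        a = full.table[full.table["t"] > 30.0].reset_index(drop=True)
        b = rest.table[rest.table["t"] > 30.0].reset_index(drop=True)
        assert len(a) == len(b) > 0
        for col in a.columns:
            np.testing.assert_allclose(
                a[col].to_numpy(float), b[col].to_numpy(float),
                rtol=1e-8, atol=1e-10, err_msg=col,
            )


class TestIO:
    def test_config_roundtrip(self, tmp_path):
        cfg = tiny_config(sigma_max=321.0, init_mode="literal")
        save_config(cfg, tmp_path / "c.yaml")
        back = load_config(tmp_path / "c.yaml")
        assert config_to_dict(back) == config_to_dict(cfg)
        again = config_from_dict(config_to_dict(back))
        assert config_to_dict(again) == config_to_dict(cfg)

    def test_result_archive_roundtrip(self, tmp_path, coarse_mesh):
        res = run_simulation(tiny_config(t_end=20.0), mesh=coarse_mesh)
        manifest = write_result(res, tmp_path / "out")
        assert (tmp_path / "out" / "scalars.csv").exists()
        back = pd.read_csv(tmp_path / "out" / "scalars.csv")
        pd.testing.assert_frame_equal(
            back, res.table.reset_index(drop=True), check_exact=False, rtol=1e-12
        )
        assert manifest["config"]["sigma_max"] == 200.0
        import h5py

        with h5py.File(tmp_path / "out" / "fields.h5") as f:
            assert f["final/lamin"].shape[0] == len(coarse_mesh.unit_dirs)

    def test_msh_roundtrip(self, tmp_path, coarse_mesh):
        write_msh(coarse_mesh, tmp_path / "m.msh")
        pts, tets, tags = read_msh(tmp_path / "m.msh")
        assert np.allclose(pts, coarse_mesh.points)
        assert np.array_equal(tets, coarse_mesh.tets)
        assert np.array_equal(tags, coarse_mesh.region)
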