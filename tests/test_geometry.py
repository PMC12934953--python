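"""Geometry: mesh construction, frames, pillar fields, F-actin."""

import numpy as np
import pytest

from nucleomech._fem import p2_tet_shape, tet_quadrature
from nucleomech.geometry import (
    NanopillarArraySpec,
    ShellGeometrySpec,
    build_reference_mesh,
    factin_concentration,
    pillar_indicator,
    pillar_indicator_smooth,
    pm_distance_and_curvature,
    reference_normal,
    tangent_frame,
)

SPEC200 = NanopillarArraySpec(r_np=0.2, h_np=1.5, p_np=5.0, r_max=7.5)


def shell_volume_curved(mesh):
    pts, w = tet_quadrature(3)
    _, dN = p2_tet_shape(pts)
    conn = np.hstack([mesh.shell_tets, mesh.tet_edges + mesh.n_vertices])
    X = mesh.p2_points[conn]
    J = np.einsum("qad,nak->nqkd", dN, X)
    return float((np.linalg.det(J) * w).sum())


class TestReferenceMesh:
    def test_rejects_degenerate_spec(self):
        with pytest.raises(ValueError):
            ShellGeometrySpec(R0=4.1, dT=4.2)

    @pytest.mark.parametrize("hedge", [0.7, 0.4])
    def test_shell_volume_and_area_match_closed_forms(self, hedge):
        spec = ShellGeometrySpec(hedge=hedge)
        mesh = build_reference_mesh(spec)
        v_exact = np.pi / 3.0 * (spec.R0**3 - spec.r_inner**3)
        assert shell_volume_curved(mesh) == pytest.approx(v_exact, rel=0.02)
        # outer area from the triangulated sphere (P1 faceting underestimates)
        tris = mesh.outer_tri_vertices()
        p = mesh.points
        a = 0.5 * np.linalg.norm(
            np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]]),
            axis=1,
        ).sum()
        assert a == pytest.approx(np.pi * spec.R0**2, rel=0.02)

    def test_volume_error_decreases_superlinearly(self):
        errs = []
        for hedge in (0.8, 0.4):
            spec = ShellGeometrySpec(hedge=hedge)
            mesh = build_reference_mesh(spec)
            v_exact = np.pi / 3.0 * (spec.R0**3 - spec.r_inner**3)
            errs.append(abs(shell_volume_curved(mesh) / v_exact - 1.0))
        # halving the edge shrinks the error at least 4x (>= O(h^2))
        assert errs[1] < errs[0] / 4.0

    def test_inner_surface_on_sphere(self, coarse_mesh):
        spec = coarse_mesh.spec
        p = coarse_mesh.points[coarse_mesh.inner_verts]
        r = np.linalg.norm(p - spec.center, axis=1)
        assert np.allclose(r, spec.r_inner, atol=1e-9)
        tris = coarse_mesh.inner_tri_vertices()
        cen = coarse_mesh.points[tris].mean(axis=1)
        rc = np.linalg.norm(cen - spec.center, axis=1)
        assert np.all(np.abs(rc - spec.r_inner) < spec.hedge / 4.0)


class TestFrames:
    def test_reference_normal_poles_and_equator(self, coarse_shell_spec):
        sp = coarse_shell_spec
        zc = sp.znuc + sp.R0
        assert np.allclose(reference_normal([0, 0, sp.znuc + 2 * sp.R0], sp), [0, 0, 1])
        assert np.allclose(reference_normal([0, 0, sp.znuc], sp), [0, 0, -1])
        assert np.allclose(reference_normal([sp.R0, 0, zc], sp), [1, 0, 0])
        with pytest.raises(ValueError):
            reference_normal(np.array([0.0, 0.0, zc]), sp)

    def test_tangent_frame_example_and_orthonormality(self, coarse_shell_spec):
        sp = coarse_shell_spec
        zc = sp.znuc + sp.R0
        e_t, e_p = tangent_frame(np.array([sp.R0, 0.0, zc]), sp)
        assert np.allclose(e_t, [0, 1, 0])
        assert np.allclose(e_p, np.cross([0, 1, 0], [1, 0, 0]))
        rng = np.random.default_rng(7)
        d = rng.normal(size=(1000, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        X = sp.center + sp.R0 * d
        off_axis = np.hypot(X[:, 0], X[:, 1]) > 1e-6
        e_t, e_p = tangent_frame(X[off_axis], sp)
        n = reference_normal(X[off_axis], sp)
        for a, b in ((e_t, e_p), (e_t, n), (e_p, n)):
            assert np.abs(np.einsum("ik,ik->i", a, b)).max() < 1e-12
        assert np.allclose(np.linalg.norm(e_t, axis=1), 1.0)
        assert np.allclose(np.linalg.norm(e_p, axis=1), 1.0)


class TestPillarFields:
    def test_indicator_lattice_examples(self):
        spec = NanopillarArraySpec(r_np=0.2, h_np=1.5, p_np=2.0, r_max=7.5)
        assert pillar_indicator(0.0, 0.0, spec) == 1
        assert pillar_indicator(1.0, 1.0, spec) == 0
        assert pillar_indicator(2.1, 0.0, spec) == 1

    def test_overlapping_pillars_rejected(self):
        with pytest.raises(ValueError):
            NanopillarArraySpec(r_np=1.5, h_np=1.0, p_np=2.0, r_max=7.5)

    def test_smooth_indicator_values(self):
        spec = SPEC200
        assert pillar_indicator_smooth(0.0, 0.0, spec)[0] == pytest.approx(1.0, abs=1e-6)
        r = spec.r_np + 0.05
        assert pillar_indicator_smooth(r, 0.0, spec)[0] == pytest.approx(
            np.exp(-0.5), abs=1e-6
        )
        assert pillar_indicator_smooth(2.5, 0.0, spec)[0] < 1e-6

    @pytest.mark.parametrize(
        "spec",
        [
            SPEC200,
            NanopillarArraySpec(r_np=0.5, h_np=1.5, p_np=3.0, r_max=7.5),
            NanopillarArraySpec(r_np=0.2, h_np=3.0, p_np=2.0, r_max=7.5),
        ],
    )
    def test_smooth_indicator_tracks_sharp_indicator(self, spec):
        g = np.linspace(-6, 6, 121)
        xx, yy = np.meshgrid(g, g)
        sharp = pillar_indicator(xx.ravel(), yy.ravel(), spec)
        smooth = pillar_indicator_smooth(xx.ravel(), yy.ravel(), spec)
        assert np.all(smooth >= sharp - 0.4)

    def test_pm_distance_branches(self):
        spec = SPEC200
        d_top, _, _ = pm_distance_and_curvature(0.0, 0.0, 1.0, spec, dsteric=0.2)
        assert d_top[0] == pytest.approx(1.2)
        _, d_side, h = pm_distance_and_curvature(1.0, 0.0, -0.5, spec, dsteric=0.2)
        assert d_side[0] == pytest.approx(0.8)
        assert h == pytest.approx(2.0)


class TestFActin:
    kwargs = dict(f1=20.0, d_f=0.5, h0=2.0, dsteric=0.2)

    def test_flat_substrate_contact_value(self):
        flat = NanopillarArraySpec(0.0, 0.0, 0.0, 0.0)
        f = factin_concentration(0.0, 0.0, -0.2, flat, f0=140.0, **self.kwargs)
        assert f[0] == pytest.approx(160.0)
        far = factin_concentration(0.0, 0.0, 50.0, flat, f0=140.0, **self.kwargs)
        assert far[0] == pytest.approx(140.0, abs=1e-6)

    def test_pillar_side_value(self):
        # touching the PM on the pillar side (d_side = 0): the curvature
        # factor e^(H/h0) = e amplifies the side term to 20 e ~ 54.4 uM
        f = factin_concentration(
            0.2, 0.0, -1.0, SPEC200, f0=100.0, **self.kwargs
        )
        assert f[0] == pytest.approx(100.0 + 20.0 * np.e, rel=1e-6)

    def test_continuity_over_pillar_shoulder(self):
        xs = np.linspace(0.0, 1.5, 601)
        f = factin_concentration(
            xs, np.zeros_like(xs), np.full_like(xs, 0.1), SPEC200,
            f0=100.0, **self.kwargs
        )
        assert np.all(f >= 100.0)
        # no jumps: successive samples differ by less than a small bound
        assert np.abs(np.diff(f)).max() < 0.5
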