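"""Surface fitting and morphology observables: sphere/ellipsoid analytics,
order parameters, inertia moments and windowed statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesiflow import morphology as mo, synthetic as sy


def _sphere_points(n, R, center=(0, 0, 0), seed=0):
    u = sy.fibonacci_sphere(n)
    return np.asarray(center) + R * u


def _prolate_points(n, a, b):
    """Points exactly on the spheroid x^2/b^2 + y^2/b^2 + z^2/a^2 = 1."""
    u = sy.fibonacci_sphere(n)
    return u * [b, b, a]


def _prolate_area(a, b):
    """Closed-form prolate spheroid area (a > b)."""
    e = np.sqrt(1.0 - b**2 / a**2)
    return 2.0 * np.pi * b**2 * (1.0 + a / (b * e) * np.arcsin(e))


class TestFitSurface:
    def test_sphere_area_and_volume_are_analytic(self):
        R = 5.0
        surf = mo.fit_surface(_sphere_points(400, R))
        assert surf.area == pytest.approx(4 * np.pi * R**2, rel=0.01)
        assert surf.volume == pytest.approx(4 / 3 * np.pi * R**3, rel=0.01)

    def test_normals_are_unit_and_outward_on_sphere(self):
        surf = mo.fit_surface(_sphere_points(400, 3.0, center=(1, 2, 3)))
        assert np.allclose(np.linalg.norm(surf.normals, axis=2), 1.0, atol=1e-9)
        rad = surf.points - np.array([1.0, 2.0, 3.0])
        assert np.all(np.einsum("tpk,tpk->tp", surf.normals, rad) > 0)

    def test_prolate_ellipsoid_area_matches_closed_form(self):
        a, b = 6.0, 4.0
        surf = mo.fit_surface(_prolate_points(4000, a, b), center=np.zeros(3),
                              n_theta=48, n_phi=96, smoothing=0.06)
        assert surf.area == pytest.approx(_prolate_area(a, b), rel=0.02)
        assert surf.volume == pytest.approx(4 / 3 * np.pi * a * b * b, rel=0.02)

    def test_refining_the_grid_reduces_sphere_area_error(self):
        # the sphere is grid-exact; perturb slightly so the error is finite
        rng = np.random.default_rng(1)
        pts = _sphere_points(2000, 5.0)
        pts *= (1 + 0.05 * np.sin(3 * np.arccos(np.clip(pts[:, 2] / 5.0, -1, 1))))[:, None]
        errs = []
        for n_theta in (8, 16, 32):
            surf = mo.fit_surface(pts, center=np.zeros(3), n_theta=n_theta,
                                  n_phi=2 * n_theta, smoothing=0.08)
            dense = mo.fit_surface(pts, center=np.zeros(3), n_theta=64,
                                   n_phi=128, smoothing=0.08)
            errs.append(abs(surf.area - dense.area))
        assert errs[2] < errs[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10 points"):
            mo.fit_surface(np.random.default_rng(0).normal(size=(5, 3)))

    def test_angular_coverage_gap_rejected(self):
        # points only on the upper hemisphere leave the south pole uncovered
        pts = _sphere_points(400, 5.0)
        pts = pts[pts[:, 2] > 1.0]
        with pytest.raises(ValueError, match="coverage"):
            mo.fit_surface(pts, center=np.zeros(3), smoothing=0.1)


class TestCurvatureOrderParameter:
    def test_perfect_sphere_gives_one(self):
        surf = mo.fit_surface(_sphere_points(500, 4.0))
        assert mo.curvature_order_parameter(surf) == pytest.approx(1.0, abs=1e-6)

    def test_normals_perpendicular_to_radial_give_minus_half(self):
        # degenerate fixture: override the fitted normals with tangential ones
        surf = mo.fit_surface(_sphere_points(500, 4.0))
        rad = surf.points - surf.center
        rad /= np.linalg.norm(rad, axis=2, keepdims=True)
        tang = np.cross(rad, [0.0, 0.0, 1.0])
        norms = np.linalg.norm(tang, axis=2, keepdims=True)
        surf.normals = tang / norms
        assert mo.curvature_order_parameter(surf) == pytest.approx(-0.5, abs=1e-9)

    def test_bumpy_sphere_matches_dense_integration_oracle(self):
        # r(theta) = R (1 + eps sin(3 theta)): axisymmetric bump
        R, eps = 5.0, 0.03
        u = sy.fibonacci_sphere(6000)
        theta_p = np.arccos(np.clip(u[:, 2], -1, 1))
        pts = R * (1 + eps * np.sin(3 * theta_p))[:, None] * u
        surf = mo.fit_surface(pts, center=np.zeros(3), n_theta=48, n_phi=96,
                              smoothing=0.05)
        got = mo.curvature_order_parameter(surf)

        # independent dense quadrature with analytic normals
        th = np.linspace(1e-4, np.pi - 1e-4, 20000)
        r = R * (1 + eps * np.sin(3 * th))
        dr = R * 3 * eps * np.cos(3 * th)
        # cos(angle(normal, radial)) = 1/sqrt(1+(r'/r)^2) for axisymmetric r
        c2 = 1.0 / (1.0 + (dr / r) ** 2)
        p2 = 1.5 * c2 - 0.5
        dA = r * np.sqrt(r**2 + dr**2) * np.sin(th)
        expect = np.trapezoid(p2 * dA, th) / np.trapezoid(dA, th)
        assert got == pytest.approx(expect, rel=0.01)


class TestAreaPerLipid:
    def test_sphere_analytic_value(self):
        surf = mo.fit_surface(_sphere_points(100, 5.0))
        assert mo.area_per_lipid(surf, 100) == pytest.approx(np.pi, rel=0.02)

    def test_doubling_lipids_halves_area_per_lipid(self):
        surf = mo.fit_surface(_sphere_points(100, 5.0))
        assert mo.area_per_lipid(surf, 200) == pytest.approx(
            mo.area_per_lipid(surf, 100) / 2.0, rel=1e-12)

    def test_zero_lipids_rejected(self):
        surf = mo.fit_surface(_sphere_points(100, 5.0))
        with pytest.raises(ValueError):
            mo.area_per_lipid(surf, 0)


class TestBilayerThickness:
    def test_concentric_spheres_give_constant_gap(self):
        outer = mo.fit_surface(_sphere_points(300, 10.0), center=np.zeros(3))
        inner = mo.fit_surface(_sphere_points(300, 6.0), center=np.zeros(3))
        mean, gaps = mo.bilayer_thickness(outer, inner)
        assert mean == pytest.approx(4.0, rel=1e-9)
        assert np.allclose(gaps, 4.0, atol=1e-9)

    def test_concentric_ellipsoids_match_analytic_gap(self):
        a, b = 6.0, 4.0
        outer = mo.fit_surface(_prolate_points(4000, a, b), center=np.zeros(3),
                               n_theta=48, n_phi=96, smoothing=0.06)
        inner = mo.fit_surface(_prolate_points(4000, a * 0.7, b * 0.7),
                               center=np.zeros(3), n_theta=48, n_phi=96, smoothing=0.06)
        _, gaps = mo.bilayer_thickness(outer, inner)
        # analytic radial gap at the sampled polar angles: 0.3 * r_outer(theta)
        expect = 0.3 * outer.radii
        assert np.abs(gaps / expect - 1.0).max() < 0.01

    def test_identical_surfaces_warn_and_return_zero(self):
        surf = mo.fit_surface(_sphere_points(300, 5.0))
        with pytest.warns(UserWarning, match="identical"):
            mean, _ = mo.bilayer_thickness(surf, surf)
        assert mean == 0.0

    def test_intersecting_surfaces_rejected(self):
        outer = mo.fit_surface(_sphere_points(300, 5.0))
        inner = mo.fit_surface(_sphere_points(300, 6.0))
        with pytest.raises(ValueError, match="intersect"):
            mo.bilayer_thickness(outer, inner)


class TestOrderParameterSCD:
    def test_all_trans_chain_along_normal_gives_minus_half(self):
        chain = np.zeros((1, 8, 3))
        chain[0, :, 2] = np.arange(8) * 0.25  # straight chain along z
        scd = mo.order_parameter_scd(chain, np.array([[0.0, 0.0, 1.0]]))
        assert np.allclose(scd, -0.5, atol=1e-12)

    def test_isotropic_chains_average_to_zero(self):
        rng = np.random.default_rng(0)
        n = 100_000
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        chains = np.stack([np.zeros((n, 3)), dirs * 0.25, dirs * 0.5], axis=1)
        scd = mo.order_parameter_scd(chains, np.tile([0.0, 0.0, 1.0], (n, 1)))
        # standard error of P2 over n isotropic samples: sqrt(1/5)/sqrt(n)
        se = 0.5 * np.sqrt(0.2 / n)
        assert abs(scd[0]) < 3 * se

    def test_generator_order_target_recovered(self, small_vesicle):
        _, system, labels = small_vesicle
        target = -0.15
        tspec = sy.TrajectorySpec(n_frames=20, dt=0.1, chain_order_target=target, seed=9)
        traj, _, _ = sy.generate_trajectory(system, labels, tspec)
        vals = []
        for f in range(traj.n_frames):
            frame = traj.unwrapped[f]
            sel = labels.lipid_leaflet == sy.OUTER
            chains = np.concatenate([frame[labels.head_index[sel]][:, None, :],
                                     frame[labels.tail_indices[sel]]], axis=1)
            normals = labels.lipid_direction[sel]
            vals.append(mo.order_parameter_scd(chains, normals).mean())
        assert np.mean(vals) == pytest.approx(target, rel=0.05)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scd_always_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        chains = rng.normal(size=(5, 6, 3)).cumsum(axis=1)
        normals = rng.normal(size=(5, 3))
        scd = mo.order_parameter_scd(chains, normals)
        assert np.all(scd >= -0.5 - 1e-12) and np.all(scd <= 1.0 + 1e-12)

    def test_short_chains_rejected(self):
        with pytest.raises(ValueError, match="3 sites"):
            mo.order_parameter_scd(np.zeros((1, 2, 3)), np.array([[0, 0, 1.0]]))


class TestRoundness:
    def test_sphere_gives_one(self):
        surf = mo.fit_surface(_sphere_points(400, 5.0))
        assert mo.roundness_index(surf) == pytest.approx(1.0, abs=1e-4)

    def test_two_to_one_prolate_matches_closed_form(self):
        a, b = 8.0, 4.0
        surf = mo.fit_surface(_prolate_points(4000, a, b), center=np.zeros(3),
                              n_theta=48, n_phi=96, smoothing=0.06)
        V = 4 / 3 * np.pi * a * b * b
        expect = np.pi ** (1 / 3) * (6 * V) ** (2 / 3) / _prolate_area(a, b)
        assert mo.roundness_index(surf) == pytest.approx(expect, rel=0.02)

    def test_isoperimetric_bound_holds(self):
        rng = np.random.default_rng(3)
        pts = _sphere_points(1500, 5.0)
        pts *= (1 + 0.1 * rng.standard_normal(len(pts)))[:, None]
        surf = mo.fit_surface(pts, center=np.zeros(3), smoothing=0.25)
        assert mo.roundness_index(surf) <= 1.0 + 1e-9


class TestMomentsOfInertia:
    def test_spherical_shell_is_isotropic(self):
        pts = _sphere_points(2000, 5.0)
        I = mo.moments_of_inertia(pts)
        assert I[2] / I[0] == pytest.approx(1.0, rel=0.01)

    def test_matches_hand_computed_tensor(self):
        pts = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]])
        got = mo.moments_of_inertia(pts, masses=1.0)
        com = pts.mean(axis=0)
        d = pts - com
        I = np.zeros((3, 3))
        for p in d:
            I += (p @ p) * np.eye(3) - np.outer(p, p)
        expect = np.sort(np.linalg.eigvalsh(I))
        assert np.allclose(got, expect, atol=1e-12)

    def test_rigid_rotation_leaves_moments_unchanged(self):
        from vesiflow.synthetic import _rotation_matrix

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 3))
        I0 = mo.moments_of_inertia(pts)
        R = _rotation_matrix(np.array([1.0, 0.3, -0.5]), 1.2)
        I1 = mo.moments_of_inertia(pts @ R.T + [3.0, -1.0, 2.0])
        assert np.allclose(I1, I0, rtol=1e-9)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            mo.moments_of_inertia(line)


class TestWindowedStats:
    def test_constant_series(self):
        t = np.arange(100.0)
        df = mo.windowed_stats(np.full(100, 7.0), t, 25.0)
        assert (df["min"] == 7.0).all() and (df["max"] == 7.0).all() \
            and (df["mean"] == 7.0).all()

    def test_arithmetic_oracle_window_means(self):
        values = np.arange(1.0, 101.0)
        times = np.arange(100.0)
        df = mo.windowed_stats(values, times, 25.0)
        assert list(df["mean"]) == [13.0, 38.0, 63.0, 88.0]
        assert not df["partial"].any()

    def test_window_equal_to_span_gives_global_stats(self):
        values = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        times = np.arange(5.0)
        df = mo.windowed_stats(values, times, 5.0)
        assert len(df) == 1
        assert df.loc[0, "min"] == 1.0 and df.loc[0, "max"] == 5.0

    def test_trailing_partial_window_is_flagged(self):
        values = np.arange(1.0, 31.0)
        df = mo.windowed_stats(values, np.arange(30.0), 25.0)
        assert len(df) == 2
        assert not df.loc[0, "partial"]
        assert df.loc[1, "partial"]
        assert df.loc[1, "n"] == 5

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            mo.windowed_stats(np.ones(5), np.arange(5.0), 0.0)


class TestAssignLeaflets:
    def test_generator_labels_recovered_exactly(self, small_vesicle):
        _, system, labels = small_vesicle
        heads = system.positions[labels.head_index]
        tails = system.positions[labels.tail_indices[:, -1]]
        la = mo.assign_leaflets(heads, tails, center=labels.center)
        assert np.array_equal(la.leaflet, labels.lipid_leaflet)
        assert la.n_inner + la.n_outer == labels.n_lipids

    def test_single_lipid_with_outward_tail_is_inner(self):
        head = np.array([[1.0, 0.0, 0.0]])
        tail = np.array([[2.0, 0.0, 0.0]])
        la = mo.assign_leaflets(head, tail, center=np.zeros(3))
        assert la.leaflet[0] == mo.INNER

    def test_planar_fallback_assigns_by_z_side(self):
        rng = np.random.default_rng(0)
        n = 40
        xy = rng.uniform(0, 10, (n, 2))
        z = np.where(np.arange(n) < 20, 2.0, -2.0)
        heads = np.column_stack([xy, z])
        tails = heads - np.column_stack([np.zeros((n, 2)), np.sign(z)])
        la = mo.assign_leaflets(heads, tails, mode="planar")
        assert np.all(la.leaflet[:20] == mo.OUTER)
        assert np.all(la.leaflet[20:] == mo.INNER)

    def test_degenerate_all_heads_at_center_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mo.assign_leaflets(np.zeros((5, 3)), np.ones((5, 3)), center=np.zeros(3))


class TestMetricInvariance:
    def test_rotation_translation_invariance_of_sphere_suite(self):
        from vesiflow.synthetic import _rotation_matrix

        pts = _sphere_points(300, 5.0)
        R = _rotation_matrix(np.array([0.3, 1.0, 0.2]), 0.9)
        shift = np.array([10.0, -4.0, 6.0])
        s0 = mo.fit_surface(pts, center=np.zeros(3))
        s1 = mo.fit_surface(pts @ R.T + shift, center=shift)
        assert s1.area == pytest.approx(s0.area, rel=1e-9)
        assert s1.volume == pytest.approx(s0.volume, rel=1e-9)
        assert mo.roundness_index(s1) == pytest.approx(mo.roundness_index(s0), rel=1e-9)
        assert mo.curvature_order_parameter(s1) == pytest.approx(
            mo.curvature_order_parameter(s0), rel=1e-9)
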