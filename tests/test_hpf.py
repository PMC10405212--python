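"""Hybrid particle-field engine: density assignment, mean-field potential
and forces, lattice Ewald electrostatics, and NVE propagation."""

import numpy as np
import pytest

from vesiflow import hpf
from vesiflow.system import ParticleSystem


def _system(pos, types, charges, box, type_names):
    return ParticleSystem(positions=pos, types=types, charges=charges,
                          box=box, type_names=type_names)


# ---------------------------------------------------------------------------
# density assignment


class TestAssignDensity:
    def test_single_particle_integrates_to_one(self):
        s = _system([[1.234, 2.345, 0.456]], [0], [0.0], [3.0, 4.0, 5.0], ["W"])
        field = hpf.assign_density(s, (6, 7, 8))
        assert field.counts() == pytest.approx([1.0], rel=1e-12)

    def test_commensurate_lattice_gives_uniform_density(self):
        # particles on every cell corner of the assignment grid
        n = 4
        xs = np.arange(n) * (2.0 / n)
        pos = np.array(np.meshgrid(xs, xs, xs, indexing="ij")).reshape(3, -1).T
        s = _system(pos, np.zeros(len(pos), int), np.zeros(len(pos)),
                    [2.0, 2.0, 2.0], ["W"])
        field = hpf.assign_density(s, (n, n, n))
        phi = field.phi[0]
        assert np.abs(phi - phi.mean()).max() < 1e-12 * phi.mean()

    def test_matches_independent_histogram_oracle(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 4.0, (100, 3))
        box = np.array([4.0, 4.0, 4.0])
        grid = (5, 5, 5)
        s = _system(pos, np.zeros(100, int), np.zeros(100), box, ["W"])
        field = hpf.assign_density(s, grid)
        # independent trilinear (cloud-in-cell) histogram, looped per particle
        expect = np.zeros(grid)
        spacing = box / np.array(grid)
        for p in pos:
            u = p / spacing
            i0 = np.floor(u).astype(int)
            f = u - i0
            for a in (0, 1):
                for b in (0, 1):
                    for c in (0, 1):
                        w = ((f[0] if a else 1 - f[0]) * (f[1] if b else 1 - f[1])
                             * (f[2] if c else 1 - f[2]))
                        idx = (i0 + [a, b, c]) % grid
                        expect[tuple(idx)] += w
        expect /= spacing.prod()
        assert np.allclose(field.phi[0], expect, atol=1e-12)

    def test_mass_conserved_per_type(self):
        rng = np.random.default_rng(4)
        n = 200
        s = _system(rng.uniform(0, 6, (n, 3)), rng.integers(0, 3, n),
                    np.zeros(n), [6.0, 6.0, 6.0], ["A", "B", "C"])
        field = hpf.assign_density(s, (9, 10, 11))
        counts = np.bincount(s.types, minlength=3).astype(float)
        assert np.allclose(field.counts(), counts, rtol=1e-9)

    def test_zero_box_edge_rejected(self):
        with pytest.raises(ValueError):
            _system([[0, 0, 0]], [0], [0.0], [1.0, 0.0, 1.0], ["W"])


# ---------------------------------------------------------------------------
# mean-field potential and forces


class TestFieldPotential:
    def test_uniform_reference_density_with_zero_chi_is_constant(self):
        phi = np.full((1, 4, 4, 4), 2.0)
        field = hpf.DensityField(phi=phi, box=np.array([4.0] * 3), spacing=np.array([1.0] * 3))
        chi = hpf.ChiMatrix(np.zeros((1, 1)), kappa=0.05)
        V = hpf.field_potential(field, chi, phi0=2.0)
        assert np.abs(V).max() < 1e-14

    def test_matches_scalar_formula_oracle_at_single_point(self):
        # two types, one lattice point, hand-set densities
        phi_a, phi_b, chi_ab, kappa, phi0 = 1.3, 0.6, 2.5, 0.08, 1.0
        phi = np.array([[[[phi_a]]], [[[phi_b]]]])
        field = hpf.DensityField(phi=phi, box=np.ones(3), spacing=np.ones(3))
        chi = hpf.ChiMatrix(np.array([[0.0, chi_ab], [chi_ab, 0.0]]), kappa=kappa)
        V = hpf.field_potential(field, chi, phi0=phi0)
        expect_a = chi_ab * phi_b + (phi_a + phi_b - 1.0) / kappa
        expect_b = chi_ab * phi_a + (phi_a + phi_b - 1.0) / kappa
        assert V[0, 0, 0, 0] == pytest.approx(expect_a, rel=1e-12)
        assert V[1, 0, 0, 0] == pytest.approx(expect_b, rel=1e-12)

    def test_chi_term_linear_in_chi(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0.5, 1.5, (2, 3, 3, 3))
        field = hpf.DensityField(phi=phi, box=np.ones(3) * 3, spacing=np.ones(3))
        kappa = 0.1
        base = hpf.field_potential(field, hpf.ChiMatrix(np.zeros((2, 2)), kappa=kappa), phi0=1.0)
        c1 = hpf.field_potential(field, hpf.ChiMatrix(np.array([[0, 1.0], [1.0, 0]]), kappa=kappa), phi0=1.0)
        c2 = hpf.field_potential(field, hpf.ChiMatrix(np.array([[0, 2.0], [2.0, 0]]), kappa=kappa), phi0=1.0)
        assert np.allclose(c2 - base, 2.0 * (c1 - base), rtol=1e-12)

    def test_type_mismatch_rejected(self):
        field = hpf.DensityField(phi=np.ones((2, 2, 2, 2)), box=np.ones(3) * 2,
                                 spacing=np.ones(3))
        chi = hpf.ChiMatrix(np.zeros((3, 3)), kappa=0.1)
        with pytest.raises(ValueError, match="mismatch"):
            hpf.field_potential(field, chi)


class TestFieldForces:
    @pytest.mark.parametrize("method,bound", [("mesh", 0.0), ("kernel", 1e-12)])
    def test_uniform_potential_gives_zero_force(self, method, bound):
        # mesh differencing of a constant is exactly zero; the kernel-weight
        # route cancels to machine precision
        rng = np.random.default_rng(1)
        s = _system(rng.uniform(0, 5, (20, 3)), np.zeros(20, int), np.zeros(20),
                    [5.0] * 3, ["W"])
        V = np.full((1, 6, 6, 6), 3.7)
        F = hpf.field_forces(s, V, method=method)
        assert np.abs(F).max() <= bound

    @pytest.mark.parametrize("method", ["mesh", "kernel"])
    def test_linear_potential_gives_constant_slope_force(self, method):
        # V = s*x on grid nodes (periodic sawtooth); interior particles far
        # from the wrap discontinuity must feel F_x = -s exactly
        n = 10
        box = np.array([10.0, 10.0, 10.0])
        slope = 2.0
        V = np.broadcast_to((slope * np.arange(n))[:, None, None], (n, n, n)).copy()[None]
        pos = np.array([[3.3, 5.1, 2.7], [4.9, 1.2, 8.8], [5.5, 5.5, 5.5]])
        s = _system(pos, np.zeros(3, int), np.zeros(3), box, ["W"])
        F = hpf.field_forces(s, V, method=method)
        assert np.allclose(F[:, 0], -slope, rtol=1e-10)
        assert np.abs(F[:, 1:]).max() < 1e-10

    def test_mesh_mode_conserves_total_momentum(self):
        rng = np.random.default_rng(2)
        n = 150
        s = _system(rng.uniform(0, 6, (n, 3)), rng.integers(0, 2, n),
                    np.zeros(n), [6.0] * 3, ["A", "B"])
        chi = hpf.ChiMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]), kappa=0.1)
        field = hpf.assign_density(s, (8, 8, 8))
        V = hpf.field_potential(field, chi)
        F = hpf.field_forces(s, V, method="mesh")
        rms = np.sqrt((F**2).mean())
        assert np.abs(F.sum(axis=0)).max() < 1e-6 * rms


class TestTranslationalInvariance:
    def test_energies_unchanged_by_one_lattice_spacing_shift(self):
        rng = np.random.default_rng(7)
        n = 60
        box = np.array([6.0, 6.0, 6.0])
        grid = (12, 12, 12)
        pos = rng.uniform(0, 6, (n, 3))
        types = rng.integers(0, 2, n)
        q = np.tile([1.0, -1.0], n // 2)
        chi = hpf.ChiMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), kappa=0.1)
        energies = []
        for shift in (0.0, 0.5):  # 0.5 nm = one lattice spacing
            s = _system(np.mod(pos + shift, 6.0), types, q, box, ["A", "B"])
            field = hpf.assign_density(s, grid)
            e_field = hpf.field_energy(field, chi, phi0=1.0)
            e_coul = hpf.total_coulomb_energy(s, grid)["total"]
            energies.append((e_field, e_coul))
        (f0, c0), (f1, c1) = energies
        assert f1 == pytest.approx(f0, rel=1e-9)
        assert c1 == pytest.approx(c0, rel=1e-9)


# ---------------------------------------------------------------------------
# electrostatics


class TestLatticeEwald:
    def test_uniform_neutral_charge_gives_constant_potential(self):
        lattice = hpf.ChargeLattice(Q=np.zeros((8, 8, 8)), box=np.ones(3) * 4,
                                    spacing=np.ones(3) * 0.5, alpha=1.0)
        psi = hpf.ewald_long_range(lattice)
        assert np.abs(psi - psi.flat[0]).max() < 1e-12

    def test_non_neutral_lattice_warns(self):
        Q = np.zeros((8, 8, 8))
        Q[0, 0, 0] = 1.0
        lattice = hpf.ChargeLattice(Q=Q, box=np.ones(3) * 4,
                                    spacing=np.ones(3) * 0.5, alpha=1.0)
        with pytest.warns(UserWarning, match="neutral"):
            hpf.ewald_long_range(lattice)

    def test_pair_energy_matches_direct_periodic_sum(self, charge_pair_system,
                                                     pair_reference_energy):
        res = hpf.total_coulomb_energy(charge_pair_system, (32, 32, 32))
        assert res["total"] == pytest.approx(pair_reference_energy, rel=0.01)

    def test_alpha_invariance_of_total_energy(self, charge_pair_system):
        res0 = hpf.total_coulomb_energy(charge_pair_system, (32, 32, 32))
        a0 = res0["alpha"]
        totals = [hpf.total_coulomb_energy(charge_pair_system, (32, 32, 32),
                                           alpha=a0 * f)["total"]
                  for f in (1 / np.sqrt(2), 1.0, np.sqrt(2))]
        spread = (max(totals) - min(totals)) / abs(np.mean(totals))
        assert spread < 0.005

    def test_coulomb_limit_across_separations(self, charge_pair_system):
        from vesiflow.reference import coulomb_energy_reference

        box = charge_pair_system.box
        for sep in (2.0, 4.0):
            pos = np.array([[5 - sep / 2, 5.17, 5.23], [5 + sep / 2, 5.17, 5.23]])
            s = _system(pos, [0, 0], [1.0, -1.0], box, ["N"])
            ref = coulomb_energy_reference(pos, s.charges, box)
            res = hpf.total_coulomb_energy(s, (32, 32, 32))
            assert res["total"] == pytest.approx(ref, rel=0.01)


class TestChiE:
    def test_zero_charges_give_zero(self):
        params = hpf.ShortRangeParams(z=6, sigma=0.5)
        assert hpf.chi_e(params, q=0.0) == 0.0

    def test_default_coordination_number_is_cubic_lattice(self):
        assert hpf.ShortRangeParams().z == 6

    def test_matches_independent_combination_rule(self):
        params = hpf.ShortRangeParams(z=6, sigma=0.5, u_qq=1.2, u_qn=0.3, u_nn=-0.1)
        expect = 6 * (0.3 - 0.5 * (1.2 + (-0.1)))
        assert hpf.chi_e(params) == pytest.approx(expect, rel=1e-12)

    def test_formula_hook_is_swappable(self):
        params = hpf.ShortRangeParams(z=4, sigma=0.3)
        assert hpf.chi_e(params, formula=lambda p, lb, q: p.z * p.sigma) == pytest.approx(1.2)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            hpf.ShortRangeParams(sigma=-1.0)


class TestShortRangePotential:
    def _lattice(self, Q):
        return hpf.ChargeLattice(Q=Q, box=np.ones(3) * 4, spacing=np.ones(3) * 0.5,
                                 alpha=1.0)

    def test_zero_charge_density_gives_zero(self):
        psi = hpf.short_range_potential(self._lattice(np.zeros((8, 8, 8))),
                                        hpf.ShortRangeParams())
        assert np.abs(psi).max() == 0.0

    def test_single_charged_cell_is_local_maximum_with_monotone_decay(self):
        Q = np.zeros((8, 8, 8))
        Q[4, 4, 4] = -1.0  # negative chi_e times negative charge: use |psi|
        psi = np.abs(hpf.short_range_potential(self._lattice(Q), hpf.ShortRangeParams()))
        assert psi[4, 4, 4] == psi.max()
        line = psi[4:, 4, 4]  # along +x from the charge (4 cells to the wrap midpoint)
        assert np.all(np.diff(line[:4]) <= 1e-15)

    def test_mirror_symmetric_charges_give_mirror_symmetric_field(self):
        Q = np.zeros((8, 8, 8))
        Q[2, 4, 4] = 1.0
        Q[6, 4, 4] = 1.0  # mirror images about x=4
        psi = hpf.short_range_potential(self._lattice(Q), hpf.ShortRangeParams())
        # mirror about the plane x=4: index i -> (8 - i) mod 8
        idx = (8 - np.arange(8)) % 8
        assert np.abs(psi - psi[idx]).max() < 1e-12


# ---------------------------------------------------------------------------
# NVE propagation


class TestNVE:
    def test_zero_forces_give_straight_lines_and_constant_ke(self):
        # uniform commensurate density, zero chi: no forces at all
        n = 4
        xs = (np.arange(n) + 0.25) * (4.0 / n)
        pos = np.array(np.meshgrid(xs, xs, xs, indexing="ij")).reshape(3, -1).T
        m = len(pos)
        vel = np.tile([[0.3, -0.2, 0.1]], (m, 1))
        s = ParticleSystem(positions=pos, types=np.zeros(m, int), charges=np.zeros(m),
                           box=[4.0] * 3, velocities=vel, type_names=["W"])
        chi = hpf.ChiMatrix(np.zeros((1, 1)), kappa=0.1)
        traj, en = hpf.nve_propagate(s, chi, (n, n, n), dt=0.01, n_steps=100)
        assert np.allclose(en["kinetic"], en["kinetic"][0], rtol=1e-12)
        expect = pos + (100 * 0.01) * np.array([0.3, -0.2, 0.1])  # t = 1, wrapped
        assert np.allclose(traj[-1], np.mod(expect, 4.0), atol=1e-10)

    def test_energy_drift_below_one_percent_of_kinetic(self, nve_runs):
        en = nve_runs["half_dt"]
        drift = abs(en["total"][-1] - en["total"][0])
        assert drift < 0.01 * en["kinetic"].mean()

    def test_drift_decreases_when_dt_halves(self, nve_runs):
        d_full = abs(nve_runs["dt"]["total"][-1] - nve_runs["dt"]["total"][0])
        d_half = abs(nve_runs["half_dt"]["total"][-1] - nve_runs["half_dt"]["total"][0])
        assert d_half < d_full

    def test_force_blowup_aborts_with_diagnostic(self):
        rng = np.random.default_rng(0)
        n = 20
        s = ParticleSystem(positions=rng.uniform(0, 2, (n, 3)), types=np.zeros(n, int),
                           charges=np.zeros(n), box=[2.0] * 3,
                           velocities=np.zeros((n, 3)), type_names=["W"])
        chi = hpf.ChiMatrix(np.zeros((1, 1)), kappa=1e-12)
        with pytest.raises(RuntimeError, match="blow-up"):
            hpf.nve_propagate(s, chi, (4, 4, 4), dt=10.0, n_steps=10, max_force=1e-3)

    def test_invalid_arguments_rejected(self):
        s = ParticleSystem(positions=[[0.5] * 3], types=[0], charges=[0.0],
                           box=[1.0] * 3, type_names=["W"])
        chi = hpf.ChiMatrix(np.zeros((1, 1)), kappa=0.1)
        with pytest.raises(ValueError):
            hpf.nve_propagate(s, chi, (2, 2, 2), dt=-1.0, n_steps=1)
        with pytest.raises(ValueError):
            hpf.nve_propagate(s, chi, (2, 2, 2), dt=0.1, n_steps=1, field_update_every=0)
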