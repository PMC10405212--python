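"""Shared fixtures.  Expensive simulations (NVE runs, Brownian calibration,
Ewald oracle) are session-scoped so unit and acceptance tests share them."""

from __future__ import annotations

import numpy as np
import pytest

from vesiflow import hpf, synthetic as sy
from vesiflow.system import ParticleSystem


@pytest.fixture(scope="session")
def small_vesicle():
    """A reduced two-leaflet vesicle (50/24 lipids) with exact labels."""
    spec = sy.VesicleSpec(
        outer_radius=5.0, inner_radius=3.0, n_outer=50, n_inner=24,
        n_water_cavity=40, n_water_bulk=300, box=(18.0, 18.0, 18.0), seed=11)
    system, labels = sy.build_vesicle(spec)
    return spec, system, labels


@pytest.fixture(scope="session")
def charge_pair_system():
    """A +/- unit charge pair, off-lattice, in a 10 nm periodic box."""
    box = np.array([10.0, 10.0, 10.0])
    pos = np.array([[3.48, 5.17, 5.23], [6.52, 5.17, 5.23]])
    return ParticleSystem(positions=pos, types=[0, 0], charges=[1.0, -1.0],
                          box=box, type_names=["N"])


@pytest.fixture(scope="session")
def pair_reference_energy(charge_pair_system):
    """Direct periodic Coulomb sum (independent pairwise Ewald oracle)."""
    from vesiflow.reference import coulomb_energy_reference

    s = charge_pair_system
    return coulomb_energy_reference(s.positions, s.charges, s.box)


@pytest.fixture(scope="session")
def nve_runs():
    """Two NVE runs of a 100-particle neutral binary mixture, the second at
    half the time step, sharing initial conditions."""
    rng = np.random.default_rng(42)
    n = 100
    box = np.array([5.0, 5.0, 5.0])
    system = ParticleSystem(
        positions=rng.uniform(0, 5, (n, 3)), types=rng.integers(0, 2, n),
        charges=np.zeros(n), box=box,
        velocities=rng.normal(0, 1, (n, 3)), type_names=["A", "B"])
    chi = hpf.ChiMatrix(np.array([[0.0, 5.0], [5.0, 0.0]]), kappa=0.1)
    out = {}
    for key, (dt, steps) in {"dt": (2e-3, 10_000), "half_dt": (1e-3, 20_000)}.items():
        _, energies = hpf.nve_propagate(system, chi, (8, 8, 8), dt=dt,
                                        n_steps=steps, store_every=steps // 100)
        out[key] = energies
    return out


@pytest.fixture(scope="session")
def brownian_recovery():
    """Free Brownian fixtures at the study's bulk/cavity water diffusion
    magnitudes (3.5 and 2.4 x 1e-5 cm^2/s), 1e4 steps x 400 molecules, with
    the recovered Einstein-relation estimates (2-30% lag window, where all
    origins are well averaged)."""
    from vesiflow.permeation import msd_diffusion

    out = {}
    for D, seed in ((3.5, 1), (2.4, 2)):
        pos = sy.brownian_positions(400, 10_000, dt=0.01, D=D, seed=seed)
        est, err = msd_diffusion(pos, dt=0.01, fit_window=(0.02, 0.3))
        out[D] = (est, err)
    return out


@pytest.fixture(scope="session")
def backmap_roundtrip_library():
    """Conformer library whose designated entry is the source of the CG
    projection used for round-trip tests."""
    mapping = sy.default_lipid_mapping(n_tail_beads=5)
    library, cg_sites = sy.make_library_fixture(40, mapping, seed=5)
    return mapping, library, cg_sites
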