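"""Minimal hybrid particle-field (hPF) engine.

In the hPF scheme pairwise nonbonded interactions are replaced by an external
potential that depends on mesh-interpolated particle densities.  For bead
type K the density-dependent potential is

    V_K(l) = k_B T [ sum_K' chi_KK' phi_K'(l) + (1/kappa) (sum_K' phi_K'(l) - 1) ]

with phi the *normalized* number density (bulk reference = 1), chi the
Flory-Huggins-style mean-field interaction matrix and kappa the
compressibility.  Forces are F_i = -grad V at the particle position.

Electrostatics follow a lattice Ewald treatment: particle charges are spread
to the mesh (cloud-in-cell), the long-range potential is obtained by solving
Poisson's equation in reciprocal space with a Gaussian-filtered charge
density (splitting parameter alpha), and the complementary short-range part
is either the pairwise erfc sum (used for energy checks) or a mean-field
Flory-Huggins chi_e density form.

Units: lengths nm, charges e, energies k_B T (reduced; the Bjerrum length
l_B carries the electrostatic scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erfc

from vesiflow.system import ParticleSystem

__all__ = [
    "ChiMatrix",
    "DensityField",
    "ChargeLattice",
    "ShortRangeParams",
    "assign_density",
    "assign_charge",
    "field_potential",
    "field_energy",
    "field_forces",
    "ewald_long_range",
    "long_range_energy",
    "short_range_pair_energy",
    "total_coulomb_energy",
    "chi_e",
    "short_range_potential",
    "nve_propagate",
]


# ---------------------------------------------------------------------------
# data types


@dataclass
class ChiMatrix:
    """Mean-field interaction matrix chi_KK' (units of k_B T) plus the
    compressibility kappa.  The diagonal convention is chi_KK = 0 unless the
    model says otherwise; kappa is the inverse strength of the density
    restraint (smaller kappa = stiffer)."""

    chi: np.ndarray
    kappa: float
    temperature: float = 300.0
    kBT: float = 1.0  # reduced-unit energy scale

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.ndim != 2 or self.chi.shape[0] != self.chi.shape[1]:
            raise ValueError("chi must be a square matrix")
        if not np.allclose(self.chi, self.chi.T, atol=1e-12):
            raise ValueError("chi must be symmetric")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def n_types(self) -> int:
        return self.chi.shape[0]


@dataclass
class DensityField:
    """Per-type number densities phi_K on an N1 x N2 x N3 mesh.

    ``phi`` has shape (n_types, N1, N2, N3) in particles/nm^3; the integral
    of phi_K over the box equals the particle count of type K.
    """

    phi: np.ndarray
    box: np.ndarray
    spacing: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.phi.shape[1:]

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def counts(self) -> np.ndarray:
        """Integral of each phi_K over the box (should equal type counts)."""
        return self.phi.sum(axis=(1, 2, 3)) * self.cell_volume


@dataclass
class ChargeLattice:
    """Charge density Q(l) on the mesh plus electrostatic parameters.

    ``Q`` is in e/nm^3.  ``alpha`` is the Ewald splitting parameter (1/nm),
    ``l_B`` the Bjerrum length (nm; 0.7 nm for water at 300 K with
    eps_r ~ 80).  ``psi_long``/``psi_short`` are filled by the solvers, in
    units of k_B T per unit charge.
    """

    Q: np.ndarray
    box: np.ndarray
    spacing: np.ndarray
    alpha: float
    l_B: float = 0.7
    eps_r: float = 80.0
    psi_long: np.ndarray | None = None
    psi_short: np.ndarray | None = None

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def total_charge(self) -> float:
        return float(self.Q.sum() * self.cell_volume)


@dataclass
class ShortRangeParams:
    """Lattice-model parameters for the short-range electrostatic chi_e.

    z is the lattice coordination number (6 for the 3D cubic lattice), sigma
    the particle diameter (nm).  u_qq / u_qn / u_nn are the pairwise
    short-range energies (k_B T) of adjacent charge/charge, charge/neutral
    and neutral/neutral site pairs; if u_qq is None it defaults to the
    contact Coulomb energy l_B q^2 / sigma.
    """

    z: int = 6
    sigma: float = 0.5
    u_qq: float | None = None
    u_qn: float = 0.0
    u_nn: float = 0.0

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("coordination number z must be >= 1")
        if self.sigma <= 0:
            raise ValueError("particle diameter sigma must be positive")


# ---------------------------------------------------------------------------
# cloud-in-cell machinery


def _cic(positions: np.ndarray, box: np.ndarray, grid_shape: tuple[int, int, int]):
    """Cloud-in-cell stencil: node flat-indices (N,8), weights (N,8) and
    weight gradients (N,8,3) for each particle."""
    grid = np.asarray(grid_shape, dtype=int)
    spacing = box / grid
    u = np.mod(positions, box) / spacing  # in [0, N)
    i0 = np.floor(u).astype(int)
    f = u - i0
    i0 = np.mod(i0, grid)
    i1 = np.mod(i0 + 1, grid)

    # per-dimension weights for lower/upper node
    w = np.stack([1.0 - f, f], axis=0)  # (2, N, 3)
    dw = np.stack([-np.ones_like(f), np.ones_like(f)], axis=0) / spacing  # (2, N, 3)

    n = len(positions)
    idx = np.empty((n, 8), dtype=np.int64)
    wgt = np.empty((n, 8))
    dwgt = np.empty((n, 8, 3))
    corner = 0
    strides = np.array([grid[1] * grid[2], grid[2], 1])
    nodes = np.stack([i0, i1], axis=0)  # (2, N, 3)
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                ix = nodes[a, :, 0] * strides[0] + nodes[b, :, 1] * strides[1] + nodes[c, :, 2]
                idx[:, corner] = ix
                wx, wy, wz = w[a, :, 0], w[b, :, 1], w[c, :, 2]
                wgt[:, corner] = wx * wy * wz
                dwgt[:, corner, 0] = dw[a, :, 0] * wy * wz
                dwgt[:, corner, 1] = wx * dw[b, :, 1] * wz
                dwgt[:, corner, 2] = wx * wy * dw[c, :, 2]
                corner += 1
    return idx, wgt, dwgt


def _spread(values: np.ndarray, idx: np.ndarray, wgt: np.ndarray, grid_shape) -> np.ndarray:
    """Scatter per-particle values onto the mesh (flat accumulation)."""
    out = np.zeros(int(np.prod(grid_shape)))
    np.add.at(out, idx.ravel(), (values[:, None] * wgt).ravel())
    return out.reshape(grid_shape)


def _gather(lattice: np.ndarray, idx: np.ndarray, wgt: np.ndarray) -> np.ndarray:
    """Interpolate a lattice field at the particle positions."""
    return (lattice.ravel()[idx] * wgt).sum(axis=1)


def assign_density(system: ParticleSystem, grid_shape) -> DensityField:
    """Spread particles onto the mesh with the cloud-in-cell (trilinear)
    kernel, one density field per bead type.

    The kernel conserves mass exactly: the integral of phi_K over the box is
    the particle count of type K.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g <= 0 for g in grid_shape):
        raise ValueError("grid shape entries must be positive")
    if np.any(system.box <= 0):
        raise ValueError("box edges must be positive")
    spacing = system.box / np.asarray(grid_shape)
    cellvol = float(np.prod(spacing))
    idx, wgt, _ = _cic(system.positions, system.box, grid_shape)
    n_types = system.n_types
    phi = np.zeros((n_types,) + grid_shape)
    for k in range(n_types):
        mask = system.types == k
        if mask.any():
            phi[k] = _spread(np.ones(mask.sum()), idx[mask], wgt[mask], grid_shape) / cellvol
    return DensityField(phi=phi, box=system.box.copy(), spacing=spacing)


def assign_charge(system: ParticleSystem, grid_shape, alpha: float | None = None,
                  l_B: float = 0.7, eps_r: float = 80.0) -> ChargeLattice:
    """Spread particle charges onto the mesh (cloud-in-cell).

    If ``alpha`` is None the Gaussian screening width 1/alpha is set to two
    lattice spacings (the default splitting choice).
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    spacing = system.box / np.asarray(grid_shape)
    if alpha is None:
        alpha = 1.0 / (2.0 * float(spacing.max()))
    idx, wgt, _ = _cic(system.positions, system.box, grid_shape)
    Q = _spread(system.charges, idx, wgt, grid_shape) / float(np.prod(spacing))
    return ChargeLattice(Q=Q, box=system.box.copy(), spacing=spacing, alpha=alpha,
                         l_B=l_B, eps_r=eps_r)


# ---------------------------------------------------------------------------
# mean-field potential, energy and forces


def field_potential(fieldd: DensityField, chi: ChiMatrix, phi0: float | None = None) -> np.ndarray:
    """Per-type external potential V_K(l) in k_B T.

    ``phi0`` is the bulk reference density (particles/nm^3) used to normalize
    phi so that the incompressibility term reads (sum phi_n - 1); defaults to
    the mean total density of the field.
    """
    if fieldd.phi.shape[0] != chi.n_types:
        raise ValueError(
            f"type count mismatch: field has {fieldd.phi.shape[0]}, chi has {chi.n_types}"
        )
    if phi0 is None:
        phi0 = float(fieldd.phi.sum(axis=0).mean())
    if phi0 <= 0:
        raise ValueError("reference density must be positive")
    phin = fieldd.phi / phi0  # dimensionless
    total = phin.sum(axis=0)
    V = np.einsum("kl,l...->k...", chi.chi, phin)
    V += (total - 1.0) / chi.kappa
    return chi.kBT * V


def field_energy(fieldd: DensityField, chi: ChiMatrix, phi0: float | None = None) -> float:
    """Total mean-field energy W[phi] (k_B T), the functional whose density
    derivative is :func:`field_potential`."""
    if phi0 is None:
        phi0 = float(fieldd.phi.sum(axis=0).mean())
    phin = fieldd.phi / phi0
    total = phin.sum(axis=0)
    w = 0.5 * np.einsum("k...,kl,l...->...", phin, chi.chi, phin)
    w += (total - 1.0) ** 2 / (2.0 * chi.kappa)
    return float(chi.kBT * phi0 * w.sum() * fieldd.cell_volume)


def field_forces(system: ParticleSystem, potential: np.ndarray, method: str = "mesh") -> np.ndarray:
    """Forces F_i = -grad V_{type(i)} evaluated at the particle positions.

    method="mesh": central-difference gradient on the lattice, interpolated
    back with the same cloud-in-cell weights.  This discretization conserves
    total momentum exactly (the summed force of a closed system vanishes).

    method="kernel": the exact gradient of the discrete energy functional,
    F_i = -sum_l V(l) grad w_l(r_i), using the analytic derivative of the
    trilinear weights.  This is the conservative choice used by the NVE
    integrator.
    """
    if potential.ndim != 4:
        raise ValueError("potential must be (n_types, N1, N2, N3)")
    grid_shape = potential.shape[1:]
    spacing = system.box / np.asarray(grid_shape)
    idx, wgt, dwgt = _cic(system.positions, system.box, grid_shape)
    forces = np.zeros_like(system.positions)
    if method == "mesh":
        for k in range(potential.shape[0]):
            mask = system.types == k
            if not mask.any():
                continue
            Vk = potential[k]
            for ax in range(3):
                g = (np.roll(Vk, -1, axis=ax) - np.roll(Vk, 1, axis=ax)) / (2.0 * spacing[ax])
                forces[mask, ax] = -_gather(g, idx[mask], wgt[mask])
    elif method == "kernel":
        flat = potential.reshape(potential.shape[0], -1)
        for k in range(potential.shape[0]):
            mask = system.types == k
            if not mask.any():
                continue
            Vl = flat[k][idx[mask]]  # (n, 8)
            forces[mask] = -np.einsum("nc,ncd->nd", Vl, dwgt[mask])
    else:
        raise ValueError(f"unknown force method {method!r}")
    return forces


# ---------------------------------------------------------------------------
# lattice electrostatics


def _k_vectors(grid_shape, box):
    ks = [2.0 * np.pi * np.fft.fftfreq(n, d=L / n) for n, L in zip(grid_shape, box)]
    KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
    return KX, KY, KZ


def _cic_window(grid_shape, box):
    """Fourier transform of the CIC assignment window (per-axis sinc^2)."""
    W = np.ones(grid_shape)
    for ax, (n, L) in enumerate(zip(grid_shape, box)):
        k = 2.0 * np.pi * np.fft.fftfreq(n, d=L / n)
        arg = k * (L / n) / 2.0
        s = np.sinc(arg / np.pi) ** 2  # np.sinc(x) = sin(pi x)/(pi x)
        shape = [1, 1, 1]
        shape[ax] = n
        W = W * s.reshape(shape)
    return W


def ewald_long_range(lattice: ChargeLattice, deconvolve_order: int = 1) -> np.ndarray:
    """Long-range electrostatic potential psi_long(l) in k_B T / e.

    Solves Poisson's equation in reciprocal space for the Gaussian-filtered
    charge density (forward/inverse discrete Fourier transform):

        psi_hat(m) = 4 pi l_B exp(-|m|^2 / 4 alpha^2) Q_hat(m) / |m|^2

    The k=0 mode is set to zero (tinfoil boundary); a non-neutral lattice is
    equivalent to adding a uniform neutralizing background and triggers a
    warning.  ``deconvolve_order`` divides by the CIC assignment window to
    undo the charge-spreading smoothing of the mesh density.
    """
    grid_shape = lattice.Q.shape
    if abs(lattice.total_charge()) > 1e-9 * max(1.0, np.abs(lattice.Q).sum() * lattice.cell_volume):
        warnings.warn(
            "lattice is not charge neutral: zeroing the k=0 mode applies a "
            "uniform neutralizing background (tinfoil convention)",
            stacklevel=2,
        )
    KX, KY, KZ = _k_vectors(grid_shape, lattice.box)
    k2 = KX**2 + KY**2 + KZ**2
    with np.errstate(divide="ignore", invalid="ignore"):
        G = 4.0 * np.pi * lattice.l_B * np.exp(-k2 / (4.0 * lattice.alpha**2)) / k2
    G.flat[0] = 0.0
    if deconvolve_order:
        G = G / _cic_window(grid_shape, lattice.box) ** deconvolve_order
    psi = np.fft.ifftn(G * np.fft.fftn(lattice.Q)).real
    lattice.psi_long = psi
    return psi


def _mesh_self_artifact(system: ParticleSystem, grid_shape, g: np.ndarray) -> float:
    """Sum_i q_i^2 sum_k g(k) (P_i(k) - 1): the spurious self-interaction a
    CIC-assigned, window-deconvolved point charge has with its own mesh
    images.  P_i is separable over axes and depends only on the fractional
    cell offset of particle i."""
    box = system.box
    grid = np.asarray(grid_shape)
    d = box / grid
    u = np.mod(system.positions, box) / d
    f = u - np.floor(u)
    axes = []
    for a in range(3):
        k = 2.0 * np.pi * np.fft.fftfreq(grid[a], d=d[a])
        one_minus_cos = 1.0 - np.cos(k * d[a])
        denom = np.sinc(k * d[a] / (2.0 * np.pi)) ** 4
        # (n_particles, n_k) per-axis factor of P_i
        axes.append((1.0 - 2.0 * f[:, a, None] * (1.0 - f[:, a, None]) * one_minus_cos[None, :]) / denom[None, :])
    total = 0.0
    q2 = system.charges**2
    for i in np.nonzero(q2)[0]:
        P = axes[0][i][:, None, None] * axes[1][i][None, :, None] * axes[2][i][None, None, :]
        total += q2[i] * float(np.sum(g * (P - 1.0)))
    return total


def long_range_energy(system: ParticleSystem, lattice: ChargeLattice) -> float:
    """Reciprocal-space energy of the Gaussian-filtered mesh charges (k_B T).

    Computed from the window-deconvolved structure factor,

        E = (2 pi l_B / V) sum_{k!=0} g(k) |S(k)|^2 - corrections,

    subtracting (i) the mesh self-interaction artifact of each CIC-assigned
    charge and (ii) the standard continuum Gaussian self term
    alpha l_B / sqrt(pi) sum_i q_i^2.
    """
    grid_shape = lattice.Q.shape
    KX, KY, KZ = _k_vectors(grid_shape, lattice.box)
    k2 = KX**2 + KY**2 + KZ**2
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.exp(-k2 / (4.0 * lattice.alpha**2)) / k2
    g.flat[0] = 0.0
    W = _cic_window(grid_shape, lattice.box)
    S = np.fft.fftn(lattice.Q) * lattice.cell_volume / W
    V = float(np.prod(lattice.box))
    e = np.sum(g * np.abs(S) ** 2)
    e -= _mesh_self_artifact(system, grid_shape, g)
    e *= 2.0 * np.pi * lattice.l_B / V
    e -= lattice.l_B * lattice.alpha / np.sqrt(np.pi) * float(np.dot(system.charges, system.charges))
    return float(e)


def short_range_pair_energy(system: ParticleSystem, alpha: float, l_B: float = 0.7,
                            r_cut: float | None = None) -> float:
    """Real-space Ewald complement: sum_{i<j} l_B q_i q_j erfc(alpha r)/r over
    minimum-image pairs within r_cut (k_B T)."""
    if r_cut is None:
        r_cut = min(5.5 / alpha, 0.499 * float(system.box.min()))
    pos = system.wrapped_positions()
    tree = cKDTree(pos, boxsize=system.box)
    pairs = tree.query_pairs(r_cut, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    d -= system.box * np.round(d / system.box)
    r = np.linalg.norm(d, axis=1)
    q = system.charges
    return float(l_B * np.sum(q[pairs[:, 0]] * q[pairs[:, 1]] * erfc(alpha * r) / r))


def total_coulomb_energy(system: ParticleSystem, grid_shape, alpha: float | None = None,
                         l_B: float = 0.7) -> dict:
    """Total hPF electrostatic energy: mesh long-range + pairwise erfc
    short-range (k_B T).  Returns the components as a dict."""
    lattice = assign_charge(system, grid_shape, alpha=alpha, l_B=l_B)
    ewald_long_range(lattice)
    e_long = long_range_energy(system, lattice)
    e_short = short_range_pair_energy(system, lattice.alpha, l_B=l_B)
    return {"long": e_long, "short": e_short, "total": e_long + e_short,
            "alpha": lattice.alpha}


# ---------------------------------------------------------------------------
# short-range mean-field (Flory-Huggins) electrostatics


def chi_e(params: ShortRangeParams, l_B: float = 0.7, q: float = 1.0,
          formula: Callable[[ShortRangeParams, float, float], float] | None = None) -> float:
    """Flory-Huggins parameter for the short-range electrostatic part.

    Default combination rule (lattice model, z nearest neighbours):

        chi_e = z [ u_qn - (u_qq + u_nn) / 2 ]

    with u_qq defaulting to the contact Coulomb energy l_B q^2 / sigma, and
    u_qn / u_nn = 0 unless set.  The exact pairwise prefactors are model
    input, so the whole rule is swappable via ``formula``.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    if formula is not None:
        return float(formula(params, l_B, q))
    u_qq = params.u_qq if params.u_qq is not None else l_B * q * q / params.sigma
    return float(params.z * (params.u_qn - 0.5 * (u_qq + params.u_nn)))


def short_range_potential(lattice: ChargeLattice, params: ShortRangeParams,
                          q: float = 1.0) -> np.ndarray:
    """Density-field form of the short-range electrostatic potential (k_B T/e).

    The chi_e parameter weights a locally smoothed charge density (Gaussian
    of width sigma, i.e. one particle diameter):

        psi_short(l) = chi_e * sigma^3 * (G_sigma * Q)(l)

    which is maximal at charge density maxima and decays monotonically away
    from an isolated charge.
    """
    ce = chi_e(params, l_B=lattice.l_B, q=q)
    grid_shape = lattice.Q.shape
    KX, KY, KZ = _k_vectors(grid_shape, lattice.box)
    k2 = KX**2 + KY**2 + KZ**2
    G = np.exp(-0.5 * k2 * params.sigma**2)
    psi = ce * params.sigma**3 * np.fft.ifftn(G * np.fft.fftn(lattice.Q)).real
    lattice.psi_short = psi
    return psi


# ---------------------------------------------------------------------------
# toy NVE propagation


def nve_propagate(system: ParticleSystem, chi: ChiMatrix, grid_shape, dt: float,
                  n_steps: int, field_update_every: int = 1, masses: np.ndarray | float = 1.0,
                  phi0: float | None = None, force_method: str = "kernel",
                  max_force: float = 1e8, store_every: int = 1):
    """Leapfrog (velocity-Verlet) NVE propagation under the mean-field forces.

    The density field (and hence the potential lattice) is refreshed every
    ``field_update_every`` steps; forces are re-interpolated at the current
    positions every step.  Returns ``(trajectory_positions, energies)`` where
    ``energies`` is a dict of kinetic / potential / total arrays sampled every
    ``store_every`` steps.

    Raises RuntimeError with a diagnostic if any force magnitude exceeds
    ``max_force`` (field blow-up).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if field_update_every < 1:
        raise ValueError("field_update_every must be >= 1")
    sys = system.copy()
    if sys.velocities is None:
        sys.velocities = np.zeros_like(sys.positions)
    m = np.broadcast_to(np.atleast_1d(np.asarray(masses, dtype=float)), (sys.n_atoms,))[:, None]

    # lock the density normalization at the start so the functional is fixed
    fieldd = assign_density(sys, grid_shape)
    if phi0 is None:
        phi0 = float(fieldd.phi.sum(axis=0).mean())
    V = field_potential(fieldd, chi, phi0=phi0)
    F = field_forces(sys, V, method=force_method)

    n_out = n_steps // store_every + 1
    traj = np.empty((n_out, sys.n_atoms, 3))
    ekin = np.empty(n_out)
    epot = np.empty(n_out)
    out = 0

    def record(i_out):
        traj[i_out] = sys.positions
        ekin[i_out] = 0.5 * float((m * sys.velocities**2).sum())
        epot[i_out] = field_energy(fieldd, chi, phi0=phi0)

    record(out)
    out += 1
    for step in range(1, n_steps + 1):
        fmax = np.abs(F).max() if len(F) else 0.0
        if fmax > max_force:
            raise RuntimeError(
                f"force blow-up at step {step}: |F|max = {fmax:.3e} exceeds {max_force:.3e}; "
                "reduce dt or soften chi/kappa"
            )
        sys.velocities += 0.5 * dt * F / m
        sys.positions += dt * sys.velocities
        sys.positions = np.mod(sys.positions, sys.box)
        if step % field_update_every == 0:
            fieldd = assign_density(sys, grid_shape)
            V = field_potential(fieldd, chi, phi0=phi0)
        F = field_forces(sys, V, method=force_method)
        sys.velocities += 0.5 * dt * F / m
        if step % store_every == 0:
            record(out)
            out += 1
    energies = {"kinetic": ekin[:out], "potential": epot[:out],
                "total": ekin[:out] + epot[:out],
                "time": np.arange(out) * dt * store_every}
    return traj[:out], energies
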