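"""Synthetic vesicle systems and trajectories with exact ground truth.

The generator emulates a quasi-spherical two-leaflet vesicle of doubly
charged glycolipids: head beads carrying -2e sit on outer/inner spherical
shells (440/204 lipids by default, matching the study composition), divalent
counterions neutralize each leaflet's charge on the matching side of the
membrane, and single-bead waters fill the interior cavity and the bulk.

Trajectories superpose (i) region-wise Brownian solvent motion with
controllable diffusion coefficients, (ii) scripted membrane-crossing solvent
events realized as piecewise-linear radial paths with small lateral jitter,
(iii) optional breathing / ellipsoidal deformation of the vesicle, and
(iv) an acyl-chain tilt distribution with a prescribed S_CD order parameter.
Every label (leaflet, solvent region, crossing event) is recorded at build
time and is exact by construction: analysis stages are scored against the
generator, never the other way around.

Units: nm, ns, e.  Diffusion coefficients are given in 1e-5 cm^2/s, which
conveniently equals nm^2/ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from vesiflow.backmap import CGMapping, StructureLibrary, bead_centers
from vesiflow.system import ParticleSystem, Trajectory

# bead classes following the CG lipid model (P head, G/L linker, C chain,
# W water, N ion); the simplified template uses P, C, W, N
TYPE_NAMES = ["P", "G", "L", "C", "W", "N"]
P, G, L, C, W, N = range(6)

INNER, OUTER = 0, 1

__all__ = [
    "VesicleSpec",
    "TrajectorySpec",
    "ScriptedCrossing",
    "VesicleLabels",
    "PackingError",
    "build_vesicle",
    "neutralizing_counterions",
    "generate_trajectory",
    "brownian_positions",
    "water_hydrogens",
    "make_library_fixture",
    "default_lipid_mapping",
    "fibonacci_sphere",
    "TYPE_NAMES",
]


class PackingError(ValueError):
    """Requested particle count cannot be placed at the minimum spacing."""


# ---------------------------------------------------------------------------
# specifications


@dataclass
class VesicleSpec:
    """Geometry and composition of a synthetic vesicle.

    Defaults follow the study system: 440 outer / 204 inner lipids, each
    carrying -2e on the head bead, neutralized by +2e counterions split
    between cavity and exterior in proportion to the leaflet charge.
    """

    outer_radius: float = 7.0
    inner_radius: float = 4.0
    n_outer: int = 440
    n_inner: int = 204
    lipid_charge: int = -2
    counterion_valence: int = 2
    n_water_cavity: int = 57
    n_water_bulk: int = 2046
    box: tuple[float, float, float] = (24.0, 24.0, 24.0)
    seed: int = 0
    n_tail: int = 6
    tail_spacing: float = 0.25
    min_lipid_spacing: float = 0.45

    def __post_init__(self) -> None:
        if not self.inner_radius < self.outer_radius:
            raise ValueError("inner_radius must be smaller than outer_radius")
        for name in ("n_outer", "n_inner", "n_water_cavity", "n_water_bulk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.counterion_valence <= 0:
            raise ValueError("counterion_valence must be positive")
        total = abs(self.lipid_charge) * (self.n_outer + self.n_inner)
        if total % self.counterion_valence:
            raise ValueError(
                "neutrality unachievable: |lipid_charge| * n_lipids not "
                "divisible by the counterion valence"
            )


@dataclass
class ScriptedCrossing:
    """One deterministic membrane-crossing solvent event.

    ``direction`` is "inward" (bulk -> cavity), "outward" (cavity -> bulk)
    or "reflected" (same-side return).  ``molecule`` indexes the water
    molecules of the system (0-based ordinal).
    The molecule is inside the membrane for frames [entry, exit) and reaches
    its destination region at ``exit``.
    """

    molecule: int
    entry_frame: int
    exit_frame: int
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("inward", "outward", "reflected"):
            raise ValueError(f"unknown crossing direction {self.direction!r}")
        if not self.entry_frame < self.exit_frame:
            raise ValueError("entry frame must precede exit frame")
        if self.entry_frame < 1:
            raise ValueError("entry frame must be >= 1 (frame 0 fixes the origin region)")


@dataclass
class TrajectorySpec:
    """Parameters of a synthetic vesicle trajectory.

    ``solvent_diffusion`` maps region name to D in 1e-5 cm^2/s (= nm^2/ns);
    defaults use the bulk/cavity water magnitudes of the study (3.5 / 2.4).
    ``chain_order_target`` prescribes the acyl-chain S_CD (valid range
    [-0.5, 0.25]; None keeps chains radial, i.e. S_CD = -0.5).
    """

    n_frames: int = 100
    dt: float = 0.1
    deformation_mode: str = "none"
    deformation_amplitude: float = 0.0
    deformation_period: float = 10.0
    solvent_diffusion: dict = field(default_factory=lambda: {"cavity": 2.4, "bulk": 3.5})
    scripted_crossings: Sequence[ScriptedCrossing] = field(default_factory=list)
    chain_order_target: float | None = None
    crossing_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.deformation_mode not in ("none", "breathing", "ellipsoidal"):
            raise ValueError(f"unknown deformation mode {self.deformation_mode!r}")
        if self.deformation_amplitude < 0:
            raise ValueError("deformation amplitude must be >= 0")
        for ev in self.scripted_crossings:
            if ev.exit_frame > self.n_frames:
                raise ValueError("scripted crossing extends past the last frame")
        if self.chain_order_target is not None and not (-0.5 <= self.chain_order_target <= 0.25):
            raise ValueError("chain_order_target must lie in [-0.5, 0.25]")


@dataclass
class VesicleLabels:
    """Exact ground truth attached to a built vesicle."""

    center: np.ndarray
    r_inner: float
    r_outer: float
    lipid_leaflet: np.ndarray          # (n_lipids,) INNER/OUTER
    lipid_direction: np.ndarray        # (n_lipids, 3) outward unit vector of placement
    head_index: np.ndarray             # (n_lipids,) atom index of the head bead
    tail_indices: np.ndarray           # (n_lipids, n_tail)
    water_indices: np.ndarray          # (n_waters,) atom indices
    water_region: np.ndarray           # (n_waters,) "cavity" | "bulk"
    ion_indices: np.ndarray
    ion_region: np.ndarray

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_leaflet)

    @property
    def n_waters(self) -> int:
        return len(self.water_indices)

    def lipid_atoms(self, i: int) -> np.ndarray:
        return np.concatenate(([self.head_index[i]], self.tail_indices[i]))


# ---------------------------------------------------------------------------
# placement helpers


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (deterministic Fibonacci
    lattice; no rejection sampling)."""
    if n == 0:
        return np.zeros((0, 3))
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def neutralizing_counterions(n_lipids: int, lipid_charge: int, valence: int) -> int:
    """Number of counterions of the given valence neutralizing n_lipids
    lipids of the given (signed) charge.

    (440, -2, +2) -> 440; exact integer arithmetic, fractional ions raise.
    """
    if valence <= 0:
        raise ValueError("valence must be positive")
    total = abs(lipid_charge) * n_lipids
    if total % valence:
        raise ValueError(
            f"cannot neutralize {total} e with ions of valence {valence}: "
            "no fractional ions"
        )
    return total // valence


def _sphere_capacity_check(n: int, radius: float, min_spacing: float, what: str) -> None:
    if n == 0:
        return
    area_per = 4.0 * np.pi * radius**2 / n
    if area_per < min_spacing**2:
        raise PackingError(
            f"{what}: {n} sites on a sphere of radius {radius} nm leave "
            f"{area_per:.3f} nm^2 each, below the ({min_spacing} nm)^2 minimum"
        )


def build_vesicle(spec: VesicleSpec):
    """Build the vesicle system plus its exact ground-truth labels.

    Lipids are placed head-out on the outer shell and head-in on the inner
    shell on deterministic Fibonacci lattices; counterions go to the cavity
    (inner leaflet's charge) and the exterior (outer leaflet's); waters fill
    the cavity and the bulk.  The total charge is exactly zero.

    Returns ``(ParticleSystem, VesicleLabels)``.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    center = box / 2.0
    tail_len = spec.n_tail * spec.tail_spacing
    if spec.n_outer or spec.n_inner:
        if spec.outer_radius + 1.0 > box.min() / 2.0:
            raise PackingError("vesicle does not fit in the box with a 1 nm margin")
        if tail_len >= (spec.outer_radius - spec.inner_radius):
            raise PackingError("tails longer than the membrane gap; reduce n_tail or spacing")
    _sphere_capacity_check(spec.n_outer, spec.outer_radius, spec.min_lipid_spacing, "outer leaflet")
    _sphere_capacity_check(spec.n_inner, spec.inner_radius, spec.min_lipid_spacing, "inner leaflet")

    pos, typ, chg = [], [], []
    head_index, tail_indices, leaflet, lipdir = [], [], [], []

    def add_lipid(direction: np.ndarray, leaf: int) -> None:
        r_head = spec.outer_radius if leaf == OUTER else spec.inner_radius
        # tails run from the head toward the membrane interior
        tdir = -direction if leaf == OUTER else direction
        head = center + r_head * direction
        head_index.append(len(pos))
        pos.append(head)
        typ.append(TYPE_NAMES[P])
        chg.append(float(spec.lipid_charge))
        tails = []
        for k in range(spec.n_tail):
            tails.append(len(pos))
            pos.append(head + (k + 1) * spec.tail_spacing * tdir)
            typ.append(TYPE_NAMES[C])
            chg.append(0.0)
        tail_indices.append(tails)
        leaflet.append(leaf)
        lipdir.append(direction)

    for d in fibonacci_sphere(spec.n_outer):
        add_lipid(d, OUTER)
    for d in fibonacci_sphere(spec.n_inner):
        add_lipid(d, INNER)

    # counterions: one population per leaflet, on the leaflet's solvent side
    n_ion_in = neutralizing_counterions(spec.n_inner, spec.lipid_charge, spec.counterion_valence)
    n_ion_out = neutralizing_counterions(spec.n_outer, spec.lipid_charge, spec.counterion_valence)
    ion_indices, ion_region = [], []
    q_ion = float(spec.counterion_valence) * (-np.sign(spec.lipid_charge) or 1.0)
    for d in fibonacci_sphere(n_ion_in):
        ion_indices.append(len(pos))
        pos.append(center + (spec.inner_radius - 0.3) * d)
        typ.append(TYPE_NAMES[N])
        chg.append(q_ion)
        ion_region.append("cavity")
    for d in fibonacci_sphere(n_ion_out):
        ion_indices.append(len(pos))
        pos.append(center + (spec.outer_radius + 0.3) * d)
        typ.append(TYPE_NAMES[N])
        chg.append(q_ion)
        ion_region.append("bulk")

    # waters: uniform in the cavity ball / in the bulk shell outside
    water_indices, water_region = [], []
    r_cav = max(spec.inner_radius - 0.6, 0.2)
    if spec.n_water_cavity:
        u = rng.random(spec.n_water_cavity)
        d = _random_directions(rng, spec.n_water_cavity)
        r = r_cav * u ** (1.0 / 3.0)
        for p in center + r[:, None] * d:
            water_indices.append(len(pos))
            pos.append(p)
            typ.append(TYPE_NAMES[W])
            chg.append(0.0)
            water_region.append("cavity")
    if spec.n_water_bulk:
        placed = 0
        r_excl = spec.outer_radius + 0.6 if (spec.n_outer or spec.n_inner) else 0.0
        attempts = 0
        while placed < spec.n_water_bulk:
            attempts += 1
            if attempts > 200 * spec.n_water_bulk + 1000:
                raise PackingError("cannot place bulk waters outside the vesicle; box too small")
            p = rng.uniform(0.0, 1.0, 3) * box
            if np.linalg.norm(p - center) <= r_excl:
                continue
            water_indices.append(len(pos))
            pos.append(p)
            typ.append(TYPE_NAMES[W])
            chg.append(0.0)
            water_region.append("bulk")
            placed += 1

    # per-molecule residue bookkeeping: lipids, then ions, then waters
    resids = np.zeros(len(pos), dtype=int)
    resnames = [""] * len(pos)
    rid = 0
    for i in range(len(head_index)):
        rid += 1
        for a in [head_index[i]] + tail_indices[i]:
            resids[a] = rid
            resnames[a] = "LIP"
    for a in ion_indices:
        rid += 1
        resids[a] = rid
        resnames[a] = "ION"
    for a in water_indices:
        rid += 1
        resids[a] = rid
        resnames[a] = "SOL"

    type_index = {name: k for k, name in enumerate(TYPE_NAMES)}
    system = ParticleSystem(
        positions=np.asarray(pos).reshape(-1, 3),
        types=np.array([type_index[t] for t in typ], dtype=int),
        charges=np.asarray(chg, dtype=float),
        box=box,
        velocities=np.zeros((len(pos), 3)),
        type_names=TYPE_NAMES,
        names=list(typ),
        resids=resids,
        resnames=resnames,
    )
    labels = VesicleLabels(
        center=center,
        r_inner=spec.inner_radius,
        r_outer=spec.outer_radius,
        lipid_leaflet=np.asarray(leaflet, dtype=int),
        lipid_direction=np.asarray(lipdir, dtype=float).reshape(len(head_index), 3)
        if head_index else np.zeros((0, 3)),
        head_index=np.asarray(head_index, dtype=int),
        tail_indices=np.asarray(tail_indices, dtype=int)
        if head_index else np.zeros((0, spec.n_tail), dtype=int),
        water_indices=np.asarray(water_indices, dtype=int),
        water_region=np.asarray(water_region, dtype=object),
        ion_indices=np.asarray(ion_indices, dtype=int),
        ion_region=np.asarray(ion_region, dtype=object),
    )
    return system, labels


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# trajectories


def _deformation_scale(tspec: TrajectorySpec, frame: int) -> np.ndarray:
    """Per-axis scale factors of the vesicle at a frame."""
    if tspec.deformation_mode == "none" or tspec.deformation_amplitude == 0.0:
        return np.ones(3)
    phase = 2.0 * np.pi * frame * tspec.dt / tspec.deformation_period
    a = tspec.deformation_amplitude * np.sin(phase)
    if tspec.deformation_mode == "breathing":
        return np.full(3, 1.0 + a)
    # ellipsoidal: volume-preserving prolate/oblate wobble along z
    s = 1.0 + a
    return np.array([1.0 / np.sqrt(s), 1.0 / np.sqrt(s), s])


def _effective_radius(delta: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Radius in the deformed metric: |S^-1 (r - c)|."""
    return np.linalg.norm(delta / scale, axis=-1)


def generate_trajectory(system: ParticleSystem, labels: VesicleLabels,
                        tspec: TrajectorySpec):
    """Generate a synthetic trajectory plus its ground-truth event log.

    Returns ``(Trajectory, events, region_labels)``:

    * ``Trajectory.positions`` (n_frames, n_atoms, 3), wrapped;
      ``Trajectory.unwrapped`` carries unwrapped solvent coordinates
      (identical to positions for non-solvent atoms).
    * ``events``: DataFrame (molecule_id, entry_frame, exit_frame,
      residence_ns, direction) listing every scripted crossing.
    * ``region_labels``: (n_frames, n_waters) array of "cavity" /
      "membrane" / "bulk" strings, exact by construction.
    """
    rng = np.random.default_rng(tspec.seed)
    n_frames, dt = tspec.n_frames, tspec.dt
    center, box = labels.center, system.box
    n_at = system.n_atoms
    waters = labels.water_indices
    n_w = len(waters)

    scripted = {ev.molecule: ev for ev in tspec.scripted_crossings}
    if len(scripted) != len(tspec.scripted_crossings):
        raise ValueError("a molecule may carry at most one scripted crossing")
    for ev in tspec.scripted_crossings:
        if ev.molecule < 0 or ev.molecule >= n_w:
            raise ValueError(f"scripted molecule {ev.molecule} is not a solvent molecule")

    # chain tilt realizing the S_CD target: S_CD = -1/2 P2(cos tilt)
    if tspec.chain_order_target is None:
        tilt = 0.0
    else:
        p2 = -2.0 * tspec.chain_order_target
        tilt = float(np.arccos(np.sqrt((2.0 * p2 + 1.0) / 3.0)))

    positions = np.empty((n_frames, n_at, 3))
    unwrapped = np.empty((n_frames, n_at, 3))
    region_labels = np.empty((n_frames, n_w), dtype=object)

    # persistent solvent state
    wpos = system.positions[waters].copy() if n_w else np.zeros((0, 3))
    base_region = labels.water_region.copy()
    membrane_gap = 0.4  # nm clearance kept between free solvent and the head shells

    # scripted radial schedules (nm) per molecule, precomputed
    sched = {}
    max_scale = 1.0 + (tspec.deformation_amplitude if tspec.deformation_mode != "none" else 0.0)
    for mol, ev in scripted.items():
        sched[mol] = _scripted_radii(ev, labels, n_frames, rng)
        r_max_path = sched[mol].max() * max_scale
        if r_max_path + 0.2 > box.min() / 2.0:
            raise ValueError(
                f"scripted path of molecule {mol} would exit the box "
                f"(radius {r_max_path:.2f} nm vs box/2 = {box.min()/2:.2f} nm)"
            )
    scripted_dirs = {mol: _random_directions(rng, 1)[0] for mol in scripted}

    n_tail = labels.tail_indices.shape[1] if labels.n_lipids else 0
    tail_spacing = 0.0
    if labels.n_lipids and n_tail:
        tail_spacing = float(np.linalg.norm(
            system.positions[labels.tail_indices[0][0]] - system.positions[labels.head_index[0]]
        ))

    for f in range(n_frames):
        scale = _deformation_scale(tspec, f)
        r_in_f, r_out_f = labels.r_inner, labels.r_outer  # radii in the scaled metric
        frame = system.positions.copy()

        # lipids: heads ride the (possibly deformed) shells, tails tilted
        if labels.n_lipids:
            dirs = labels.lipid_direction
            leaf = labels.lipid_leaflet
            r_head = np.where(leaf == OUTER, labels.r_outer, labels.r_inner)
            heads = center + (r_head[:, None] * dirs) * scale
            frame[labels.head_index] = heads
            if n_tail:
                tdirs = _tilted_directions(dirs, tilt, rng)
                tdirs = np.where(leaf[:, None] == OUTER, -tdirs, tdirs)
                for k in range(n_tail):
                    frame[labels.tail_indices[:, k]] = heads + (k + 1) * tail_spacing * tdirs

        # solvent: Brownian inside its region, scripted molecules override
        if n_w:
            for region, D in tspec.solvent_diffusion.items():
                mask = base_region == region
                if not mask.any():
                    continue
                step = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(int(mask.sum()), 3))
                if f > 0:
                    wpos[mask] += step
            # reflect free waters back into their region (deformed metric)
            delta = wpos - center
            reff = _effective_radius(delta, scale)
            cav = (base_region == "cavity")
            hi = r_in_f - membrane_gap
            bad = cav & (reff > hi)
            if bad.any():
                wpos[bad] = center + delta[bad] * ((2 * hi - reff[bad]).clip(0.05) / reff[bad])[:, None] * 1.0
            blk = (base_region == "bulk")
            lo = r_out_f + membrane_gap
            bad = blk & (reff < lo)
            if bad.any():
                wpos[bad] = center + delta[bad] * ((2 * lo - reff[bad]) / reff[bad])[:, None]
            # keep bulk waters inside the box by mirror reflection at the
            # walls, so wrapped and unwrapped geometry coincide
            if blk.any():
                folded = np.mod(wpos[blk], 2.0 * box)
                wpos[blk] = np.where(folded > box, 2.0 * box - folded, folded)

            # scripted override: deterministic radial path + lateral jitter
            for mol, radii in sched.items():
                u = scripted_dirs[mol]
                lateral = rng.normal(0.0, tspec.crossing_noise, 3)
                lateral -= u * (lateral @ u)
                wpos[mol] = center + (radii[f] * u + lateral) * scale

            delta = wpos - center
            reff = _effective_radius(delta, scale)
            lab = np.where(reff < r_in_f, "cavity", np.where(reff > r_out_f, "bulk", "membrane"))
            region_labels[f] = lab
            frame[waters] = wpos

        unwrapped[f] = frame
        positions[f] = np.mod(frame, box)

    rows = []
    for ev in tspec.scripted_crossings:
        rows.append({
            "molecule_id": ev.molecule,
            "entry_frame": ev.entry_frame,
            "exit_frame": ev.exit_frame,
            "residence_ns": (ev.exit_frame - ev.entry_frame) * dt,
            "direction": ev.direction,
        })
    events = pd.DataFrame(rows, columns=["molecule_id", "entry_frame", "exit_frame",
                                         "residence_ns", "direction"])
    traj = Trajectory(positions=positions, boxes=box.copy(), dt=dt, unwrapped=unwrapped,
                      metadata={"seed": tspec.seed, "deformation": tspec.deformation_mode,
                                "chain_order_target": tspec.chain_order_target})
    return traj, events, region_labels


def _scripted_radii(ev: ScriptedCrossing, labels: VesicleLabels, n_frames: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Radial schedule (one radius per frame) realizing a scripted event.

    Membrane occupancy is exactly frames [entry, exit); the molecule starts
    in its origin region and lands in the destination region at exit.
    """
    r_in, r_out = labels.r_inner, labels.r_outer
    h = 0.08 * (r_out - r_in)  # how far inside the membrane the path starts/ends
    r_cav = r_in - 0.8
    r_blk = r_out + 0.8
    radii = np.empty(n_frames)
    if ev.direction == "inward":
        origin, dest = r_blk, r_cav
        start, end = r_out - h, r_in + h
    elif ev.direction == "outward":
        origin, dest = r_cav, r_blk
        start, end = r_in + h, r_out - h
    else:  # reflected: enter from the bulk side and return to it
        origin, dest = r_blk, r_blk
        start = end = r_out - h
    radii[: ev.entry_frame] = origin
    span = ev.exit_frame - ev.entry_frame
    if ev.direction == "reflected":
        mid = 0.5 * (r_in + r_out)
        half = max(span // 2, 1)
        down = np.linspace(start, mid, half + 1)[:-1]
        up = np.linspace(mid, end, span - half + 1)[:-1]
        radii[ev.entry_frame: ev.exit_frame] = np.concatenate([down, up])[:span]
    else:
        radii[ev.entry_frame: ev.exit_frame] = np.linspace(start, end, span)
    radii[ev.exit_frame:] = dest
    return radii


def _tilted_directions(dirs: np.ndarray, tilt: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors at a fixed polar angle ``tilt`` from each direction, with
    random azimuth (axially symmetric tilt distribution)."""
    if tilt == 0.0:
        return dirs.copy()
    n = len(dirs)
    # orthonormal frame per direction
    a = np.where(np.abs(dirs[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(dirs, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    az = rng.uniform(0.0, 2.0 * np.pi, n)
    return (np.cos(tilt) * dirs
            + np.sin(tilt) * (np.cos(az)[:, None] * e1 + np.sin(az)[:, None] * e2))


def brownian_positions(n_molecules: int, n_frames: int, dt: float, D: float,
                       seed: int = 0, origin_spread: float = 10.0) -> np.ndarray:
    """Free (unconfined, unwrapped) Brownian motion fixture: (n_frames,
    n_molecules, 3) positions with per-step displacement variance 2 D dt per
    dimension.  Used to calibrate diffusion estimators via the Einstein
    relation."""
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, origin_spread, size=(1, n_molecules, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, n_molecules, 3))
    return np.concatenate([start, start + np.cumsum(steps, axis=0)], axis=0)


# ---------------------------------------------------------------------------
# conformer library fixtures


def water_hydrogens(oxygen_positions: np.ndarray, seed: int = 0,
                    bond_length: float = 0.1, hoh_angle_deg: float = 104.5):
    """Two explicit hydrogen sites per water oxygen, randomly oriented with
    the water geometry (0.1 nm O-H, 104.5 deg H-O-H).  Returns ``(h_pos,
    h_parent)`` with two rows per oxygen; used for geometric hydrogen-bond
    analysis of the single-bead CG solvent."""
    opos = np.asarray(oxygen_positions, dtype=float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    n = len(opos)
    e1 = _random_directions(rng, n)
    helper = _random_directions(rng, n)
    e2 = np.cross(e1, helper)
    e2 /= np.maximum(np.linalg.norm(e2, axis=1, keepdims=True), 1e-12)
    half = np.deg2rad(hoh_angle_deg) / 2.0
    h1 = opos + bond_length * (np.cos(half) * e1 + np.sin(half) * e2)
    h2 = opos + bond_length * (np.cos(half) * e1 - np.sin(half) * e2)
    h_pos = np.empty((2 * n, 3))
    h_pos[0::2] = h1
    h_pos[1::2] = h2
    h_parent = np.repeat(np.arange(n), 2)
    return h_pos, h_parent


def default_lipid_mapping(n_tail_beads: int = 6, atoms_per_bead: int = 4) -> CGMapping:
    """CG mapping of the simplified lipid: one P head bead plus a linear run
    of C tail beads, ``atoms_per_bead`` heavy atoms each."""
    beads = []
    idx = 0
    beads.append(("P", list(range(idx, idx + atoms_per_bead))))
    idx += atoms_per_bead
    for _ in range(n_tail_beads):
        beads.append(("C", list(range(idx, idx + atoms_per_bead))))
        idx += atoms_per_bead
    return CGMapping(beads=beads)


def _base_conformer(mapping: CGMapping, bead_spacing: float = 0.35,
                    atom_spread: float = 0.12, helix_radius: float = 0.06) -> np.ndarray:
    """Deterministic reference conformation: bead centers on a gentle helix
    along z (non-collinear, so rigid superposition is well-posed), member
    atoms on a small tetrahedron around each center."""
    tet = atom_spread * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float) / np.sqrt(3.0)
    coords = np.zeros((mapping.n_atoms, 3))
    for b, (_, atoms) in enumerate(mapping.beads):
        c = np.array([helix_radius * np.cos(1.1 * b),
                      helix_radius * np.sin(1.1 * b),
                      b * bead_spacing])
        for j, a in enumerate(atoms):
            coords[a] = c + tet[j % 4] * (1.0 + 0.05 * (j // 4))
    return coords


def make_library_fixture(n_conformers: int, mapping: CGMapping, seed: int = 0,
                         bend_sigma: float = 0.15, atom_noise: float = 0.02,
                         bead_spacing: float = 0.35):
    """Structure library of smoothly deformed copies of the base conformer.

    The designated conformer (index 0) is the base geometry verbatim;
    the other entries bend the bead chain by cumulative random rotations and
    add small per-atom noise.  Returns ``(StructureLibrary, cg_sites)`` with
    ``cg_sites`` the CG projection (bead centroids) of the designated
    conformer, for round-trip tests.
    """
    if n_conformers < 1:
        raise ValueError("need at least one conformer")
    rng = np.random.default_rng(seed)
    base = _base_conformer(mapping, bead_spacing=bead_spacing)
    confs = np.empty((n_conformers, mapping.n_atoms, 3))
    confs[0] = base
    for m in range(1, n_conformers):
        confs[m] = _bend(base, mapping, rng, bend_sigma, atom_noise)
    lib = StructureLibrary(conformations=confs, mapping=mapping)
    return lib, bead_centers(base, mapping)


def _bend(base: np.ndarray, mapping: CGMapping, rng: np.random.Generator,
          bend_sigma: float, atom_noise: float) -> np.ndarray:
    """Cumulatively rotate successive beads about random axes through the
    previous bead center (a crude torsional wiggle), plus atomic noise."""
    coords = base.copy()
    R = np.eye(3)
    pivot = np.zeros(3)
    for b, (_, atoms) in enumerate(mapping.beads):
        if b > 0:
            axis = _random_directions(rng, 1)[0]
            angle = rng.normal(0.0, bend_sigma)
            R = _rotation_matrix(axis, angle) @ R
            pivot = coords[list(mapping.beads[b - 1][1])].mean(axis=0)
        idx = list(atoms)
        coords[idx] = (coords[idx] - pivot) @ R.T + pivot
    coords += rng.normal(0.0, atom_noise, coords.shape)
    return coords


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
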