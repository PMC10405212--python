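"""Core in-memory containers: particle systems and trajectories.

Coordinates are stored in nm, times in ns, charges in units of the elementary
charge e.  Boxes are orthorhombic and periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class ParticleSystem:
    """A periodic collection of (possibly charged) particles.

    Parameters
    ----------
    positions : (N, 3) array, nm
    types : (N,) int array
        Index into ``type_names`` (bead classes such as P, G, L, C, W, N).
    charges : (N,) array, e
    box : (3,) array, nm
        Orthorhombic periodic box edges.
    velocities : (N, 3) array, nm/ps, optional
    type_names : sequence of str
        Label per type index.
    names : per-particle atom names (optional, used by writers).
    resids / resnames : per-particle residue bookkeeping (optional).
    """

    positions: np.ndarray
    types: np.ndarray
    charges: np.ndarray
    box: np.ndarray
    velocities: np.ndarray | None = None
    type_names: Sequence[str] = field(default_factory=list)
    names: Sequence[str] | None = None
    resids: np.ndarray | None = None
    resnames: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.types = np.asarray(self.types, dtype=int).reshape(-1)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if len(self.types) != n or len(self.charges) != n:
            raise ValueError("positions, types and charges must have equal length")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if not self.type_names:
            self.type_names = [f"T{i}" for i in range(int(self.types.max()) + 1 if n else 0)]

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def wrapped_positions(self) -> np.ndarray:
        """Positions folded into [0, L) in each dimension."""
        return np.mod(self.positions, self.box)

    def wrap(self) -> None:
        self.positions = self.wrapped_positions()

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            types=self.types.copy(),
            charges=self.charges.copy(),
            box=self.box.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            type_names=list(self.type_names),
            names=None if self.names is None else list(self.names),
            resids=None if self.resids is None else np.asarray(self.resids).copy(),
            resnames=None if self.resnames is None else list(self.resnames),
        )


@dataclass
class Trajectory:
    """Coordinate time series for one system.

    ``positions`` has shape (n_frames, n_atoms, 3) in nm.  ``dt`` is the frame
    spacing in ns; analysis code reads it from here rather than assuming a
    value.  ``boxes`` may be a single (3,) box (constant) or (n_frames, 3).
    ``unwrapped`` optionally carries unwrapped coordinates for diffusion
    analysis.
    """

    positions: np.ndarray
    boxes: np.ndarray
    dt: float
    unwrapped: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must be (n_frames, n_atoms, 3)")
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.dt

    def box_at(self, frame: int) -> np.ndarray:
        if self.boxes.ndim == 1:
            return self.boxes
        return self.boxes[frame]
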