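"""Coarse-grained to atomistic back-mapping.

Atomistic molecules are rebuilt from CG bead centers by searching a library
of atomistic conformations: each trial conformer's bead-center sites are
rigidly superposed (proper rotation + translation, Kabsch) onto the CG
sites, and the trial is accepted if the maximum per-site deviation after the
fit is below a fixed tolerance (0.2 nm by default).  The accepted conformer's
atoms are placed with the fitted transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_TOLERANCE_NM = 0.2

__all__ = [
    "CGMapping",
    "StructureLibrary",
    "BackmapResult",
    "bead_centers",
    "superpose",
    "backmap_molecule",
    "backmap_system",
    "DEFAULT_TOLERANCE_NM",
]


@dataclass
class CGMapping:
    """Bead definition for one molecule type: an ordered list of
    (bead type label, member heavy-atom indices).

    Each heavy atom belongs to exactly one bead; beads group about four heavy
    atoms (3-5 tolerated at chain termini).
    """

    beads: Sequence[tuple[str, Sequence[int]]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, atoms in self.beads:
            atoms = list(atoms)
            if not atoms:
                raise ValueError(f"bead {label!r} has no member atoms")
            if seen & set(atoms):
                raise ValueError("an atom is assigned to more than one bead")
            seen.update(atoms)
        self._atom_count = len(seen)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_atoms(self) -> int:
        return self._atom_count


@dataclass
class StructureLibrary:
    """M atomistic conformations of one molecule type with precomputed
    bead-center sites.

    ``conformations`` has shape (M, n_atoms, 3) nm; ``sites`` (M, n_beads, 3).
    """

    conformations: np.ndarray
    mapping: CGMapping
    sites: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.conformations = np.asarray(self.conformations, dtype=float)
        if self.conformations.ndim != 3:
            raise ValueError("conformations must be (M, n_atoms, 3)")
        if len(self.conformations) == 0:
            self.sites = np.zeros((0, self.mapping.n_beads, 3))
        else:
            self.sites = np.stack([bead_centers(c, self.mapping) for c in self.conformations])

    def __len__(self) -> int:
        return self.conformations.shape[0]


@dataclass
class BackmapResult:
    """Outcome of fitting one CG molecule against a library."""

    library_index: int
    rotation: np.ndarray
    translation: np.ndarray
    site_deviations: np.ndarray
    max_deviation: float
    accepted: bool


def bead_centers(conformation: np.ndarray, mapping: CGMapping) -> np.ndarray:
    """Back-mapping sites: the centroid of each bead's member heavy atoms."""
    conformation = np.asarray(conformation, dtype=float)
    n = conformation.shape[0]
    out = np.empty((mapping.n_beads, 3))
    for b, (_, atoms) in enumerate(mapping.beads):
        atoms = np.asarray(atoms, dtype=int)
        if atoms.min() < 0 or atoms.max() >= n:
            raise IndexError(
                f"bead {b} references atom indices outside [0, {n})"
            )
        out[b] = conformation[atoms].mean(axis=0)
    return out


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Kabsch algorithm: centroids are removed, the optimal *proper* rotation
    (det = +1, mirror solutions rejected) is obtained from the SVD of the
    cross-covariance matrix, and the translation follows from the centroids.

    Returns ``(rotation, translation, deviations)`` such that
    ``mobile @ rotation.T + translation`` best matches ``target``;
    ``deviations`` are the per-site distances after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("site sets must have identical shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 sites for a rigid superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    A = mobile - mc
    B = target - tc
    # degenerate (collinear) geometry has rank < 2
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError("degenerate site geometry: sites are collinear")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    dev = np.linalg.norm(moved - target, axis=1)
    return R, t, dev


def backmap_molecule(cg_sites: np.ndarray, library: StructureLibrary,
                     tolerance: float = DEFAULT_TOLERANCE_NM,
                     mode: str = "first", criterion: str = "max_site"):
    """Fit library conformers onto the CG sites of one molecule.

    mode="first": conformers are tried in library order and the first one
    whose acceptance statistic is below ``tolerance`` wins; mode="best"
    evaluates every conformer and keeps the smallest statistic.  If no entry
    passes, the best one is returned with ``accepted=False``.

    criterion="max_site" accepts on the maximum per-site deviation after the
    rigid fit; criterion="rmsd" uses the whole-molecule site RMSD instead.

    Returns ``(BackmapResult, placed_atoms)``.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cg_sites = np.asarray(cg_sites, dtype=float)
    if cg_sites.shape != library.sites.shape[1:]:
        raise ValueError(
            f"CG site count {cg_sites.shape} does not match library sites "
            f"{library.sites.shape[1:]}"
        )

    def stat(dev: np.ndarray) -> float:
        if criterion == "max_site":
            return float(dev.max())
        if criterion == "rmsd":
            return float(np.sqrt(np.mean(dev**2)))
        raise ValueError(f"unknown acceptance criterion {criterion!r}")

    best = None  # (stat, index, R, t, dev)
    for m in range(len(library)):
        R, t, dev = superpose(library.sites[m], cg_sites)
        s = stat(dev)
        if best is None or s < best[0]:
            best = (s, m, R, t, dev)
        if mode == "first" and s < tolerance:
            break
        if mode not in ("first", "best"):
            raise ValueError(f"unknown search mode {mode!r}")

    s, m, R, t, dev = best
    result = BackmapResult(
        library_index=m,
        rotation=R,
        translation=t,
        site_deviations=dev,
        max_deviation=float(dev.max()),
        accepted=s < tolerance,
    )
    placed = library.conformations[m] @ R.T + t
    return result, placed


def backmap_system(cg_molecule_sites: Sequence[np.ndarray],
                   libraries: Sequence[StructureLibrary] | StructureLibrary,
                   tolerance: float = DEFAULT_TOLERANCE_NM,
                   mode: str = "first", criterion: str = "max_site",
                   strict: bool = False):
    """Back-map every CG molecule of a system.

    ``libraries`` is either one library shared by all molecules or a sequence
    with one entry per molecule.  Solvent and ion beads are not back-mapped
    geometrically (solvent is re-inserted by the synthetic builder); pass
    only the lipid molecules here.

    Returns ``(placed, report)``: a list of atom-coordinate arrays and a
    DataFrame with one row per molecule (molecule_id, library_index,
    max_dev_nm, accepted).  With ``strict=True`` any rejected molecule raises.
    """
    n = len(cg_molecule_sites)
    if isinstance(libraries, StructureLibrary):
        libraries = [libraries] * n
    if len(libraries) != n:
        raise ValueError("need one library per molecule")
    placed_all = []
    rows = []
    for i, (sites, lib) in enumerate(zip(cg_molecule_sites, libraries)):
        res, placed = backmap_molecule(sites, lib, tolerance=tolerance,
                                       mode=mode, criterion=criterion)
        placed_all.append(placed)
        rows.append({"molecule_id": i, "library_index": res.library_index,
                     "max_dev_nm": res.max_deviation, "accepted": res.accepted})
    report = pd.DataFrame(rows, columns=["molecule_id", "library_index",
                                         "max_dev_nm", "accepted"])
    if strict and n and not report["accepted"].all():
        bad = report.loc[~report["accepted"], "molecule_id"].tolist()
        raise RuntimeError(f"back-mapping failed for molecules {bad} at tolerance {tolerance} nm")
    return placed_all, report


def acceptance_rate(report: pd.DataFrame) -> float:
    """Fraction of accepted molecules in a back-mapping report."""
    if len(report) == 0:
        return float("nan")
    return float(report["accepted"].mean())
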