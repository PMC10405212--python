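"""Readers and writers for standard structure/trajectory formats.

GRO files (nm, fixed columns) are parsed natively so that malformed records
can be reported with their line number; PDB (Angstrom, converted to nm) and
XTC trajectories go through MDAnalysis.  All coordinates are nm internally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from vesiflow.system import ParticleSystem, Trajectory

__all__ = [
    "read_structure",
    "write_structure",
    "read_gro",
    "write_gro",
    "read_pdb",
    "write_trajectory_xtc",
    "read_trajectory",
    "write_events_tsv",
    "read_events_tsv",
    "write_json_sidecar",
    "provenance_header",
]

_TYPE_FROM_NAME = {"P": 0, "G": 1, "L": 2, "C": 3, "W": 4, "N": 5}
_TYPE_NAMES = ["P", "G", "L", "C", "W", "N"]


class ParseError(ValueError):
    pass


def _types_from_names(names) -> np.ndarray:
    return np.array([_TYPE_FROM_NAME.get(str(n).strip()[:1].upper(), 0) for n in names], dtype=int)


def read_gro(path) -> ParticleSystem:
    """Read a GRO coordinate file (nm).  Malformed records raise a
    ParseError naming the offending line."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated file ({len(lines)} lines)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as e:
        raise ParseError(f"{path}: line 2: cannot parse atom count: {lines[1]!r}") from e
    if len(lines) < n_atoms + 3:
        raise ParseError(
            f"{path}: line {len(lines)}: truncated file, expected {n_atoms} atom "
            f"records plus a box line"
        )
    pos = np.empty((n_atoms, 3))
    vel = np.zeros((n_atoms, 3))
    names, resids, resnames = [], [], []
    has_vel = False
    for i in range(n_atoms):
        ln = lines[2 + i]
        lineno = 3 + i
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            pos[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
            if len(ln.rstrip()) > 44:
                vel[i] = [float(ln[44:52]), float(ln[52:60]), float(ln[60:68])]
                has_vel = True
        except (ValueError, IndexError) as e:
            raise ParseError(f"{path}: line {lineno}: malformed atom record: {ln!r}") from e
    box_fields = lines[2 + n_atoms].split()
    try:
        box = np.array([float(x) for x in box_fields[:3]])
    except (ValueError, IndexError) as e:
        raise ParseError(f"{path}: line {3 + n_atoms}: malformed box line") from e
    return ParticleSystem(
        positions=pos, types=_types_from_names(names), charges=np.zeros(n_atoms),
        box=box, velocities=vel if has_vel else None, type_names=_TYPE_NAMES,
        names=names, resids=np.array(resids), resnames=resnames,
    )


def write_gro(system: ParticleSystem, path, title: str = "vesiflow",
              header_comment: str | None = None) -> None:
    """Write a GRO coordinate file (nm, fixed columns).  ``header_comment``
    (provenance) is folded into the title line."""
    path = Path(path)
    names = system.names or [system.type_names[t] for t in system.types]
    resids = system.resids if system.resids is not None else np.arange(1, system.n_atoms + 1)
    resnames = system.resnames or [str(n)[:3].upper() or "MOL" for n in names]
    if header_comment:
        title = f"{title} | {header_comment}"
    with path.open("w") as fh:
        fh.write(title[:1000] + "\n")
        fh.write(f"{system.n_atoms:5d}\n")
        vel = system.velocities
        for i in range(system.n_atoms):
            rid = int(resids[i]) % 100000
            line = (f"{rid:5d}{str(resnames[i])[:5]:<5s}{str(names[i])[:5]:>5s}"
                    f"{(i + 1) % 100000:5d}"
                    f"{system.positions[i, 0]:8.3f}{system.positions[i, 1]:8.3f}{system.positions[i, 2]:8.3f}")
            if vel is not None:
                line += f"{vel[i, 0]:8.4f}{vel[i, 1]:8.4f}{vel[i, 2]:8.4f}"
            fh.write(line + "\n")
        fh.write(f"{system.box[0]:10.5f}{system.box[1]:10.5f}{system.box[2]:10.5f}\n")


def read_pdb(path) -> ParticleSystem:
    """Read a PDB file via MDAnalysis; coordinates converted Angstrom -> nm."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    pos = u.atoms.positions / 10.0
    names = [a.name for a in u.atoms]
    box = u.dimensions[:3] / 10.0 if u.dimensions is not None and u.dimensions[:3].any() \
        else np.full(3, max(1.0, pos.ptp(axis=0).max() + 2.0))
    return ParticleSystem(positions=pos, types=_types_from_names(names),
                          charges=np.zeros(len(names)), box=box,
                          type_names=_TYPE_NAMES, names=names)


def read_structure(path) -> ParticleSystem:
    """Read a coordinate file, dispatching on extension (.gro or .pdb)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".gro":
        return read_gro(path)
    if suffix == ".pdb":
        return read_pdb(path)
    raise ValueError(f"unrecognized structure format {suffix!r} (use .gro or .pdb)")


def write_structure(system: ParticleSystem, path, **kw) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".gro":
        write_gro(system, path, **kw)
        return
    raise ValueError(f"unsupported output format {suffix!r} (use .gro)")


def write_trajectory_xtc(traj: Trajectory, system: ParticleSystem, path) -> None:
    """Write an XTC trajectory (MDAnalysis; nm -> Angstrom)."""
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    with mda.Writer(str(path), traj.n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.positions[f] * 10.0
            box = traj.box_at(f)
            u.dimensions = [box[0] * 10, box[1] * 10, box[2] * 10, 90, 90, 90]
            u.trajectory.ts.time = f * traj.dt * 1000.0  # ps
            w.write(u.atoms)


def read_trajectory(path, topology) -> Trajectory:
    """Read a trajectory (XTC/TRR/DCD) against a GRO/PDB topology; yields an
    in-memory Trajectory in nm/ns.  Frame atom counts must match."""
    import MDAnalysis as mda

    top_sys = read_structure(topology)
    u = mda.Universe(str(topology), str(path))
    if len(u.atoms) != top_sys.n_atoms:
        raise ValueError(
            f"atom count mismatch: trajectory has {len(u.atoms)}, topology "
            f"has {top_sys.n_atoms}"
        )
    frames, boxes, times = [], [], []
    for ts in u.trajectory:
        frames.append(u.atoms.positions / 10.0)
        boxes.append(ts.dimensions[:3] / 10.0)
        times.append(ts.time / 1000.0)  # ps -> ns
    if not frames:
        return Trajectory(positions=np.zeros((0, top_sys.n_atoms, 3)),
                          boxes=top_sys.box, dt=1.0)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return Trajectory(positions=np.stack(frames), boxes=np.stack(boxes),
                      dt=dt if dt > 0 else 1.0)


def write_events_tsv(events_df, path, header: str | None = None) -> None:
    """Ground-truth / detected event log as TSV with provenance comments."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        events_df.to_csv(fh, sep="\t", index=False)


def read_events_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


def write_json_sidecar(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def provenance_header(seed: int | None = None, config_hash: str | None = None) -> str:
    from vesiflow import __version__

    parts = [f"vesiflow {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts)
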