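"""Membrane permeation analysis: crossing events, residence times,
crossing histograms, inside/outside fractions and self-diffusion.

A crossing event opens when a solvent molecule enters the membrane region
from the cavity or the bulk and closes at the next non-membrane label; the
direction is classified from (origin, destination): bulk -> cavity is
inward, cavity -> bulk is outward, and same-side returns are "reflected"
(fast reversible penetration).  Events that are open at the trajectory
boundaries are censored: reported, but excluded from residence statistics.

Residence-time classes follow the two observed regimes: "fast" events
shorter than 1 ns, "confined" molecules resident longer than 270 ns, and
everything between as "intermediate".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CrossingEvent",
    "ResidenceClasses",
    "detect_crossings",
    "residence_distribution",
    "crossing_histogram",
    "inside_outside_fraction",
    "msd_diffusion",
    "events_to_frame",
]

VALID_LABELS = {"cavity", "membrane", "bulk"}


@dataclass
class CrossingEvent:
    """One membrane visit of one solvent molecule."""

    molecule: int
    entry_frame: int
    exit_frame: int
    residence_ns: float
    direction: str  # inward | outward | reflected_in | reflected_out
    censored: bool = False


@dataclass
class ResidenceClasses:
    """Residence-time regime thresholds (ns): fast < 1, confined > 270."""

    fast: float = 1.0
    confined: float = 270.0
    members: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fast <= 0 or self.confined <= 0:
            raise ValueError("thresholds must be positive")
        if not self.fast < self.confined:
            raise ValueError("fast threshold must be below the confined threshold")


def _direction(origin: str, dest: str) -> str:
    if origin == "bulk" and dest == "cavity":
        return "inward"
    if origin == "cavity" and dest == "bulk":
        return "outward"
    if origin == dest == "cavity":
        return "reflected_in"
    return "reflected_out"


def detect_crossings(labels: np.ndarray, dt: float) -> list[CrossingEvent]:
    """Detect membrane-crossing events from per-frame region labels.

    ``labels`` is (n_frames, n_molecules) with entries in {"cavity",
    "membrane", "bulk"}.  Pure function of the labels: identical input
    yields identical events.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    labels = np.asarray(labels, dtype=object)
    if labels.ndim == 1:
        labels = labels[:, None]
    found = set(np.unique(labels.astype(str)))
    unknown = found - VALID_LABELS
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    n_frames, n_mol = labels.shape
    events: list[CrossingEvent] = []
    for m in range(n_mol):
        seq = labels[:, m]
        origin: str | None = None
        entry: int | None = None
        if seq[0] == "membrane":
            entry, origin = 0, None  # open at trajectory start: censored
        for f in range(1, n_frames):
            prev, cur = seq[f - 1], seq[f]
            if cur == "membrane" and prev != "membrane":
                entry, origin = f, prev
            elif cur != "membrane" and prev == "membrane":
                if origin is None:
                    events.append(CrossingEvent(m, entry, f, (f - entry) * dt,
                                                f"reflected_{'in' if cur == 'cavity' else 'out'}",
                                                censored=True))
                else:
                    events.append(CrossingEvent(m, entry, f, (f - entry) * dt,
                                                _direction(origin, str(cur))))
                entry, origin = None, None
        if entry is not None:  # still inside the membrane at the end
            events.append(CrossingEvent(m, entry, n_frames - 1,
                                        (n_frames - 1 - entry) * dt,
                                        "reflected_out" if origin in (None, "bulk") else "reflected_in",
                                        censored=True))
    return events


def events_to_frame(events: list[CrossingEvent]) -> pd.DataFrame:
    """Events as a tidy DataFrame (one row per event)."""
    return pd.DataFrame(
        [{"molecule_id": e.molecule, "entry_frame": e.entry_frame,
          "exit_frame": e.exit_frame, "residence_ns": e.residence_ns,
          "direction": e.direction, "censored": e.censored} for e in events],
        columns=["molecule_id", "entry_frame", "exit_frame", "residence_ns",
                 "direction", "censored"])


def residence_distribution(events: list[CrossingEvent],
                           classes: ResidenceClasses | None = None,
                           bins: int | np.ndarray = 20):
    """Residence-time histogram plus the fast/intermediate/confined
    partition of molecules.  Censored events are flagged separately and do
    not enter the histogram or the classes.

    Returns ``(hist, edges, classes)`` with ``classes.members`` mapping
    class name -> set of molecule ids (plus "censored").
    """
    classes = classes or ResidenceClasses()
    closed = [e for e in events if not e.censored]
    res = np.array([e.residence_ns for e in closed])
    hist, edges = np.histogram(res, bins=bins) if len(res) else (np.zeros(1, dtype=int), np.array([0.0, 1.0]))
    members = {"fast": set(), "intermediate": set(), "confined": set(),
               "censored": {e.molecule for e in events if e.censored}}
    for e in closed:
        if e.residence_ns < classes.fast:
            members["fast"].add(e.molecule)
        elif e.residence_ns > classes.confined:
            members["confined"].add(e.molecule)
        else:
            members["intermediate"].add(e.molecule)
    classes.members = members
    return hist, edges, classes


def crossing_histogram(events: list[CrossingEvent], bin_width: float = 10.0,
                       dt: float = 1.0, t_max: float | None = None):
    """Events binned by entry time (default 10 ns bars).

    Returns ``(counts, edges)``; the total over bins equals the event count.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    t_entry = np.array([e.entry_frame * dt for e in events])
    if t_max is None:
        t_max = float(t_entry.max()) + bin_width if len(t_entry) else bin_width
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    counts, _ = np.histogram(t_entry, bins=edges)
    return counts, edges


def inside_outside_fraction(labels: np.ndarray) -> pd.DataFrame:
    """Percentage of waters inside (cavity), outside (bulk) and in the
    membrane, per frame; the three sum to 100."""
    labels = np.asarray(labels, dtype=object)
    if labels.ndim == 1:
        labels = labels[:, None]
    n_frames, n_mol = labels.shape
    if n_mol == 0:
        raise ValueError("zero waters")
    s = labels.astype(str)
    inside = (s == "cavity").sum(axis=1) * 100.0 / n_mol
    outside = (s == "bulk").sum(axis=1) * 100.0 / n_mol
    membrane = (s == "membrane").sum(axis=1) * 100.0 / n_mol
    return pd.DataFrame({"frame": np.arange(n_frames), "inside_pct": inside,
                         "outside_pct": outside, "membrane_pct": membrane})


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Mean squared displacement over lag times for one molecule set,
    (n_frames, n_mol, 3) -> (n_frames,), via the FFT autocorrelation
    algorithm (all time origins)."""
    n, m, _ = x.shape
    nfft = 1 << (2 * n - 1).bit_length()
    # S2: autocorrelation term
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft((f * f.conj()).real.sum(axis=2), n=nfft, axis=0)[:n]
    counts = np.arange(n, 0, -1)[:, None]
    s2 = acf / counts
    # S1: sum of squares term
    sq = (x**2).sum(axis=2)
    ssum = 2.0 * sq.sum(axis=0)
    s1 = np.empty((n, m))
    run = ssum.copy()
    s1[0] = run / n
    for k in range(1, n):
        run -= sq[k - 1] + sq[n - k]
        s1[k] = run / (n - k)
    return (s1 - 2.0 * s2).mean(axis=1)


def msd_diffusion(positions: np.ndarray, dt: float,
                  fit_window: tuple[float, float] = (0.1, 0.5),
                  box: np.ndarray | None = None, n_blocks: int = 5):
    """Self-diffusion coefficient from the Einstein relation.

    ``positions``: unwrapped (n_frames, n_molecules, 3) in nm.  D is the MSD
    slope / 6 over the lag-time window given as fractions of the trajectory
    span (default 10-50%, excluding both the short-time regime and the
    poorly averaged long lags).  Returned in nm^2/ns, numerically equal to
    1e-5 cm^2/s.  The uncertainty is the standard error over molecule
    blocks.

    Wrapped coordinates (frame-to-frame jumps larger than half a box edge)
    are rejected: unwrap first.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3:
        raise ValueError("positions must be (n_frames, n_molecules, 3)")
    n_frames, n_mol, _ = positions.shape
    if n_frames < 10:
        raise ValueError("too few frames for a diffusion estimate")
    if box is not None:
        box = np.asarray(box, dtype=float)
        jumps = np.abs(np.diff(positions, axis=0))
        if np.any(jumps > box / 2.0):
            raise ValueError(
                "wrapped coordinates detected (jump > box/2); unwrap the "
                "trajectory before fitting diffusion"
            )

    lo = max(1, int(fit_window[0] * n_frames))
    hi = max(lo + 2, int(fit_window[1] * n_frames))

    def fit(block: np.ndarray) -> float:
        msd = _msd_fft(block)
        lags = np.arange(n_frames) * dt
        # weight down the long lags, whose MSD estimates average few
        # independent displacement origins
        w = 1.0 / lags[lo:hi]
        slope = np.polyfit(lags[lo:hi], msd[lo:hi], 1, w=w)[0]
        return slope / 6.0

    D = fit(positions)
    if n_mol >= n_blocks and n_blocks > 1:
        splits = np.array_split(np.arange(n_mol), n_blocks)
        ds = np.array([fit(positions[:, s]) for s in splits])
        err = float(ds.std(ddof=1) / np.sqrt(n_blocks))
    else:
        err = float("nan")
    return float(D), err
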