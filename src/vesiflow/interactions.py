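"""Pair structure and hydrogen bonding: radial distribution functions,
coordination numbers, geometric H-bond counting and water region labels.

Coordination numbers integrate the RDF,  CN = 4 pi rho int_0^rc g(r) r^2 dr,
with the cutoff either given explicitly or detected as the first minimum of
the smoothed g(r).  Hydrogen bonds follow the geometric criterion of a
donor-acceptor distance cutoff (0.35 nm) combined with an X-D...A angle
cutoff (30 degrees), X being the atom bonded to the donor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree

__all__ = [
    "RDFProfile",
    "HBondCriterion",
    "rdf",
    "coordination_number",
    "direct_coordination_count",
    "hbond_count",
    "classify_waters",
    "classify_waters_radial",
]

DEFAULT_HBOND_CUTOFF_NM = 0.35
DEFAULT_HBOND_ANGLE_DEG = 30.0


@dataclass
class RDFProfile:
    """g(r) for one particle pair (e.g. PO4/Ca2+, PO4/OW, Ca2+/OW)."""

    pair: str
    r: np.ndarray
    g: np.ndarray
    partner_density: float  # nm^-3
    n_frames: int

    def first_minimum(self, window: int = 7) -> float:
        """First strict local minimum of the smoothed g(r) after the first
        peak; raises when none is detectable (use an explicit cutoff)."""
        g = self.g
        if len(g) >= window:
            gs = savgol_filter(g, window | 1, 3)
        else:
            gs = g
        peak = None
        for i in range(1, len(gs) - 1):
            if peak is None:
                if gs[i] > gs[i - 1] and gs[i] >= gs[i + 1] and gs[i] > 1.2:
                    peak = i
            else:
                if gs[i] < gs[i - 1] and gs[i] <= gs[i + 1]:
                    return float(self.r[i])
        raise ValueError(
            f"no detectable first minimum in g(r) for pair {self.pair!r}; "
            "pass an explicit cutoff"
        )


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition: D...A distance cutoff (nm) and
    X-D...A angle cutoff (degrees, 0 < angle <= 90)."""

    cutoff: float = DEFAULT_HBOND_CUTOFF_NM
    angle: float = DEFAULT_HBOND_ANGLE_DEG

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle <= 90:
            raise ValueError("angle cutoff must be in (0, 90] degrees")


def _frames(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None] if x.ndim == 2 else x


def rdf(group_a: np.ndarray, group_b: np.ndarray, box: np.ndarray,
        r_max: float, n_bins: int = 100, pair: str = "A/B") -> RDFProfile:
    """Radial distribution function between two particle groups.

    ``group_a`` / ``group_b`` are (n, 3) single frames or (n_frames, n, 3)
    stacks; minimum-image periodic distances; normalization by the ideal-gas
    shell count at the partner density N_b / V.
    """
    box = np.asarray(box, dtype=float)
    if r_max >= box.min() / 2.0:
        raise ValueError("r_max must be below half the smallest box edge")
    A = _frames(group_a)
    B = _frames(group_b)
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise ValueError("empty group")
    if A.shape[0] != B.shape[0]:
        raise ValueError("frame counts differ between groups")
    same = A.shape == B.shape and np.shares_memory(A, B) or (A.shape == B.shape and np.array_equal(A, B))
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    for fa, fb in zip(A, B):
        ta = cKDTree(np.mod(fa, box), boxsize=box)
        tb = cKDTree(np.mod(fb, box), boxsize=box)
        c = ta.count_neighbors(tb, edges, cumulative=False)[1:]  # drop r<edges[0]=0 bin
        counts += c
    n_frames = A.shape[0]
    N_a, N_b = A.shape[1], B.shape[1]
    V = float(np.prod(box))
    rho_b = (N_b - (1 if same else 0)) / V if same else N_b / V
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = N_a * rho_b * shell * n_frames
    if same:
        counts = counts - 0  # self pairs fall in the r=0 bin, already dropped by edges[0]=0
    g = np.where(ideal > 0, counts / ideal, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(pair=pair, r=centers, g=g, partner_density=N_b / V, n_frames=n_frames)


def coordination_number(profile: RDFProfile, cutoff: float | None = None) -> float:
    """CN = 4 pi rho int_0^cutoff g(r) r^2 dr (trapezoidal); with no cutoff
    the detected first minimum of the smoothed g(r) is used."""
    if cutoff is None:
        cutoff = profile.first_minimum()
    if cutoff > profile.r[-1] + (profile.r[1] - profile.r[0]):
        raise ValueError("cutoff beyond the profile range")
    mask = profile.r < cutoff
    r = profile.r[mask]
    g = profile.g[mask]
    # close the integration interval exactly at r=0 and r=cutoff
    g_cut = float(np.interp(cutoff, profile.r, profile.g))
    r = np.concatenate([[0.0], r, [cutoff]])
    g = np.concatenate([[g[0] if len(g) else 0.0], g, [g_cut]])
    integral = np.trapezoid(g * r**2, r)
    return float(4.0 * np.pi * profile.partner_density * integral)


def direct_coordination_count(group_a: np.ndarray, group_b: np.ndarray,
                              box: np.ndarray, cutoff: float) -> float:
    """Direct-count coordination: mean number of B partners within the
    cutoff of each A particle (frames averaged)."""
    box = np.asarray(box, dtype=float)
    A = _frames(group_a)
    B = _frames(group_b)
    total = 0.0
    same = A.shape == B.shape and np.array_equal(A, B)
    for fa, fb in zip(A, B):
        ta = cKDTree(np.mod(fa, box), boxsize=box)
        tb = cKDTree(np.mod(fb, box), boxsize=box)
        c = ta.count_neighbors(tb, cutoff)
        if same:
            c -= fa.shape[0]
        total += c
    return total / (A.shape[0] * A.shape[1])


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def hbond_count(donor_pos: np.ndarray, hydrogen_pos: np.ndarray,
                acceptor_pos: np.ndarray, hydrogen_donor: np.ndarray,
                criterion: HBondCriterion | None = None,
                box: np.ndarray | None = None,
                convention: str = "XDA") -> list[tuple[int, int, int]]:
    """Geometric hydrogen bonds in one frame.

    A bond (hydrogen h with parent donor d, acceptor a) is counted when the
    D...A distance is <= the cutoff and the angle criterion holds:

    * convention="XDA" (the caption definition, X = the H bonded to the
      donor): angle at D between D->X and D->A <= cutoff angle;
    * convention="DHA": deviation from linearity at the hydrogen,
      180 deg - angle(D-H...A) <= cutoff angle.

    ``hydrogen_donor[i]`` is the donor index of hydrogen i (must be valid).
    Returns the list of (hydrogen, donor, acceptor) index triples.
    """
    criterion = criterion or HBondCriterion()
    donor_pos = np.asarray(donor_pos, dtype=float).reshape(-1, 3)
    hydrogen_pos = np.asarray(hydrogen_pos, dtype=float).reshape(-1, 3)
    acceptor_pos = np.asarray(acceptor_pos, dtype=float).reshape(-1, 3)
    hydrogen_donor = np.asarray(hydrogen_donor, dtype=int)
    if len(hydrogen_donor) != len(hydrogen_pos):
        raise ValueError("need one parent donor index per hydrogen")
    if len(hydrogen_donor) and (hydrogen_donor.min() < 0 or hydrogen_donor.max() >= len(donor_pos)):
        raise ValueError("hydrogen with no valid parent donor")
    if box is not None:
        box = np.asarray(box, dtype=float)

    if box is not None:
        td = cKDTree(np.mod(donor_pos, box), boxsize=box)
        ta = cKDTree(np.mod(acceptor_pos, box), boxsize=box)
    else:
        td = cKDTree(donor_pos)
        ta = cKDTree(acceptor_pos)
    neighbors = td.query_ball_tree(ta, criterion.cutoff)

    cos_cut = np.cos(np.deg2rad(criterion.angle))
    bonds: list[tuple[int, int, int]] = []
    for h, d in enumerate(hydrogen_donor):
        dh = _min_image(hydrogen_pos[h] - donor_pos[d], box)
        for a in neighbors[d]:
            da = _min_image(acceptor_pos[a] - donor_pos[d], box)
            r_da = np.linalg.norm(da)
            if r_da < 1e-9:  # donor and acceptor are the same site
                continue
            if convention == "XDA":
                cosang = float(dh @ da) / (np.linalg.norm(dh) * r_da)
                ok = cosang >= cos_cut
            elif convention == "DHA":
                hd = -dh
                ha = _min_image(acceptor_pos[a] - hydrogen_pos[h], box)
                cosang = float(hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                # linear D-H...A means angle(D-H-A) = 180 deg
                ok = cosang <= -np.cos(np.deg2rad(criterion.angle))
            else:
                raise ValueError(f"unknown angle convention {convention!r}")
            if ok:
                bonds.append((h, int(d), int(a)))
    return bonds


def classify_waters(positions: np.ndarray, center: np.ndarray,
                    inner_surface, outer_surface) -> np.ndarray:
    """Region labels per water: "cavity" inside the inner head-group
    surface, "membrane" between the surfaces, "bulk" outside.  Surfaces are
    :class:`vesiflow.morphology.FittedSurface` objects."""
    if inner_surface is None or outer_surface is None:
        raise ValueError("fitted surfaces unavailable")
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    d = positions - np.asarray(center, dtype=float)
    r = np.linalg.norm(d, axis=1)
    theta = np.arccos(np.clip(np.where(r > 0, d[:, 2] / np.maximum(r, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(d[:, 1], d[:, 0])
    r_in = inner_surface.radius_at(theta, phi)
    r_out = outer_surface.radius_at(theta, phi)
    return np.where(r < r_in, "cavity", np.where(r > r_out, "bulk", "membrane")).astype(object)


def classify_waters_radial(positions: np.ndarray, center: np.ndarray,
                           r_inner: float, r_outer: float) -> np.ndarray:
    """Fixed-radius fallback for rigid spherical fixtures."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    r = np.linalg.norm(positions - np.asarray(center, dtype=float), axis=1)
    return np.where(r < r_inner, "cavity", np.where(r > r_outer, "bulk", "membrane")).astype(object)
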