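"""Vesicle morphology: leaflet assignment, closed-surface fitting, and the
shape/order observables derived from the fitted surfaces.

A leaflet's head-group positions are converted to a radius field r(theta,
phi) on an angular grid by kernel-weighted averaging of the point radii
(great-circle Gaussian weights).  Normals, area and volume follow
analytically from the fitted field; polar integration uses cell-exact
integrals of sin(theta) so that a perfect sphere is reproduced to machine
precision.

Observables:

* curvature order parameter: area-weighted <P2(cos angle(normal, radial))>,
  1 for a perfect sphere;
* area per lipid A_L = area / n_lipids (nm^2);
* bilayer thickness D_HH: radial head-to-head distance between the two
  fitted surfaces (nm), solid-angle weighted;
* deuterium order parameter S_CD versus the local surface normal;
* roundness (sphericity) psi = pi^(1/3) (6V)^(2/3) / A, 1 iff sphere;
* principal moments of inertia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LeafletAssignment",
    "FittedSurface",
    "assign_leaflets",
    "fit_surface",
    "curvature_order_parameter",
    "area_per_lipid",
    "bilayer_thickness",
    "order_parameter_scd",
    "roundness_index",
    "moments_of_inertia",
    "windowed_stats",
]

INNER, OUTER = 0, 1


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels (INNER=0 / OUTER=1) plus a confidence score
    in [0.5, 1]: 1 when the radial-position and head-tail-orientation
    indicators agree, 0.5 when they conflict."""

    leaflet: np.ndarray
    confidence: np.ndarray

    @property
    def n_inner(self) -> int:
        return int(np.sum(self.leaflet == INNER))

    @property
    def n_outer(self) -> int:
        return int(np.sum(self.leaflet == OUTER))


@dataclass
class FittedSurface:
    """Closed surface r(theta, phi) sampled on an angular grid.

    ``theta`` (n_t,) are polar midpoints, ``phi`` (n_p,) azimuths, ``radii``
    (n_t, n_p) nm.  ``points``/``normals`` are grid positions and outward
    unit normals, ``weights`` the exact solid-angle cell integrals
    (sum = 4 pi), ``area_elements`` the per-cell surface areas.
    """

    center: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    radii: np.ndarray
    points: np.ndarray
    normals: np.ndarray
    weights: np.ndarray
    area_elements: np.ndarray
    area: float
    volume: float

    def radius_at(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the radius field (periodic in phi,
        clamped at the poles)."""
        theta = np.atleast_1d(theta)
        phi = np.mod(np.atleast_1d(phi), 2.0 * np.pi)
        n_t, n_p = self.radii.shape
        dt = np.pi / n_t
        dp = 2.0 * np.pi / n_p
        ft = np.clip(theta / dt - 0.5, 0.0, n_t - 1.0)
        it0 = np.floor(ft).astype(int)
        it1 = np.minimum(it0 + 1, n_t - 1)
        wt = ft - it0
        fp = phi / dp - 0.5
        ip0 = np.mod(np.floor(fp).astype(int), n_p)
        ip1 = np.mod(ip0 + 1, n_p)
        wp = np.mod(fp, 1.0)
        r = ((1 - wt) * (1 - wp) * self.radii[it0, ip0]
             + (1 - wt) * wp * self.radii[it0, ip1]
             + wt * (1 - wp) * self.radii[it1, ip0]
             + wt * wp * self.radii[it1, ip1])
        return r


def assign_leaflets(head_positions: np.ndarray, tail_positions: np.ndarray,
                    center: np.ndarray | None = None, mode: str = "radial") -> LeafletAssignment:
    """Assign each lipid to the inner or outer leaflet.

    mode="radial" (vesicles): a lipid is *inner* when its head lies radially
    inside the midsurface between the two head-group shells AND the
    head-to-tail vector points radially outward; otherwise *outer*.  The two
    indicators normally agree; the radial one wins on conflict with a reduced
    confidence score.

    mode="planar" (flat bilayer fallback): assignment by z-side of the head
    midplane, tails toward the midplane; "upper" maps to OUTER.
    """
    head_positions = np.asarray(head_positions, dtype=float).reshape(-1, 3)
    tail_positions = np.asarray(tail_positions, dtype=float).reshape(-1, 3)
    if len(head_positions) < 1:
        raise ValueError("need at least one lipid")
    if mode == "planar":
        mid = head_positions[:, 2].mean()
        leaf = np.where(head_positions[:, 2] >= mid, OUTER, INNER)
        return LeafletAssignment(leaflet=leaf, confidence=np.ones(len(leaf)))
    if center is None:
        center = head_positions.mean(axis=0)
    center = np.asarray(center, dtype=float)
    r_head = np.linalg.norm(head_positions - center, axis=1)
    if np.all(r_head < 1e-9):
        raise ValueError("degenerate geometry: all heads at the center")
    mid = _two_shell_midradius(r_head)
    inner_by_radius = r_head < mid
    radial = (head_positions - center)
    with np.errstate(invalid="ignore"):
        radial /= np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-12)
    outward = np.einsum("ij,ij->i", tail_positions - head_positions, radial) > 0
    # heads exactly on the midsurface (e.g. a single shell) are decided by
    # the head-to-tail orientation alone
    ambiguous = np.isclose(r_head, mid, rtol=1e-9, atol=1e-12)
    leaf = np.where(ambiguous, np.where(outward, INNER, OUTER),
                    np.where(inner_by_radius, INNER, OUTER))
    confidence = np.where(ambiguous | (inner_by_radius == outward), 1.0, 0.5)
    return LeafletAssignment(leaflet=leaf, confidence=confidence)


def _two_shell_midradius(r: np.ndarray) -> float:
    """Midpoint between the two radius populations (split at the largest
    gap of the sorted radii; degenerates gracefully to the median)."""
    if len(r) < 2:
        return float(r.mean())
    s = np.sort(r)
    gaps = np.diff(s)
    i = int(np.argmax(gaps))
    if gaps[i] <= 0:
        return float(np.median(r))
    lower = s[: i + 1].mean()
    upper = s[i + 1:].mean()
    return 0.5 * (lower + upper)


def fit_surface(points: np.ndarray, center: np.ndarray | None = None,
                n_theta: int = 32, n_phi: int = 64,
                smoothing: float | None = None) -> FittedSurface:
    """Fit a closed surface r(theta, phi) to reference points (head groups).

    The radius field is the Gaussian-kernel weighted average of the point
    radii, with great-circle angular distances; normals come from analytic
    differentiation of the fitted field; area and volume by quadrature with
    cell-exact sin(theta) weights.

    ``smoothing`` is the kernel width in radians; by default it adapts to
    max(grid spacing, 1.5 x mean inter-point spacing).  Angular coverage
    gaps larger than ~3 kernel widths raise a coverage error.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    if n < 10:
        raise ValueError("need at least 10 points distributed over the shell")
    if center is None:
        center = points.mean(axis=0)
    center = np.asarray(center, dtype=float)
    delta = points - center
    r_pts = np.linalg.norm(delta, axis=1)
    if np.any(r_pts < 1e-9):
        raise ValueError("a reference point coincides with the center")
    u_pts = delta / r_pts[:, None]

    d_theta = np.pi / n_theta
    theta = (np.arange(n_theta) + 0.5) * d_theta
    d_phi = 2.0 * np.pi / n_phi
    phi = np.arange(n_phi) * d_phi
    if smoothing is None:
        mean_spacing = np.sqrt(4.0 * np.pi / n)
        smoothing = max(d_theta, d_phi, 1.5 * mean_spacing)

    st, ct = np.sin(theta), np.cos(theta)
    grid_u = np.empty((n_theta, n_phi, 3))
    grid_u[..., 0] = st[:, None] * np.cos(phi)[None, :]
    grid_u[..., 1] = st[:, None] * np.sin(phi)[None, :]
    grid_u[..., 2] = ct[:, None]

    # great-circle angle between every node and every point
    cosang = np.clip(np.einsum("tpk,nk->tpn", grid_u, u_pts), -1.0, 1.0)
    ang = np.arccos(cosang)
    nearest = ang.min(axis=2)
    if np.any(nearest > 3.0 * smoothing):
        worst = float(nearest.max())
        raise ValueError(
            f"angular coverage gap: a grid node is {worst:.2f} rad from the "
            f"nearest point (> 3 x kernel width {smoothing:.2f} rad)"
        )
    w = np.exp(-0.5 * (ang / smoothing) ** 2)
    radii = (w * r_pts[None, None, :]).sum(axis=2) / w.sum(axis=2)

    return _surface_from_radii(center, theta, phi, radii)


def _surface_from_radii(center, theta, phi, radii) -> FittedSurface:
    n_theta, n_phi = radii.shape
    d_theta = np.pi / n_theta
    d_phi = 2.0 * np.pi / n_phi
    st, ct = np.sin(theta), np.cos(theta)

    # derivatives of the radius field (phi periodic; theta one-sided at poles)
    dr_dphi = (np.roll(radii, -1, axis=1) - np.roll(radii, 1, axis=1)) / (2.0 * d_phi)
    dr_dtheta = np.gradient(radii, d_theta, axis=0)

    # unit vectors of the spherical frame at each node
    rhat = np.empty((n_theta, n_phi, 3))
    rhat[..., 0] = st[:, None] * np.cos(phi)[None, :]
    rhat[..., 1] = st[:, None] * np.sin(phi)[None, :]
    rhat[..., 2] = ct[:, None]
    that = np.empty_like(rhat)
    that[..., 0] = ct[:, None] * np.cos(phi)[None, :]
    that[..., 1] = ct[:, None] * np.sin(phi)[None, :]
    that[..., 2] = -st[:, None]
    phat = np.zeros_like(rhat)
    phat[..., 0] = -np.sin(phi)[None, :]
    phat[..., 1] = np.cos(phi)[None, :]

    points = center + radii[..., None] * rhat

    # outward normal of r(theta,phi):  n ~ rhat - (r_t/r) that - (r_p/(r s)) phat
    inv_r = 1.0 / radii
    gt = dr_dtheta * inv_r
    gp = dr_dphi * inv_r / np.maximum(st[:, None], 1e-12)
    normals = rhat - gt[..., None] * that - gp[..., None] * phat
    norm = np.linalg.norm(normals, axis=2, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero-length surface normal")
    normals = normals / norm

    # exact integral of sin(theta) over each polar cell -> sphere-exact areas
    edges = np.linspace(0.0, np.pi, n_theta + 1)
    sin_int = np.cos(edges[:-1]) - np.cos(edges[1:])
    weights = np.repeat(sin_int[:, None], n_phi, axis=1) * d_phi  # sums to 4 pi

    # dA = r^2 sqrt(1 + (r_t/r)^2 + (r_p/(r s))^2) dOmega
    metric = np.sqrt(1.0 + gt**2 + gp**2)
    area_elements = radii**2 * metric * weights
    area = float(area_elements.sum())
    volume = float((radii**3 / 3.0 * weights).sum())
    return FittedSurface(center=np.asarray(center, dtype=float), theta=theta, phi=phi,
                         radii=radii, points=points, normals=normals, weights=weights,
                         area_elements=area_elements, area=area, volume=volume)


def curvature_order_parameter(surface: FittedSurface,
                              reference_center: np.ndarray | None = None) -> float:
    """Area-weighted <P2(cos theta)> with theta the angle between the local
    outward normal and the radial direction from the reference center.
    Equals 1 for a perfect sphere, -0.5 when normals are everywhere
    perpendicular to the radial direction."""
    c = surface.center if reference_center is None else np.asarray(reference_center, float)
    rad = surface.points - c
    norm = np.linalg.norm(rad, axis=2, keepdims=True)
    rad = rad / np.maximum(norm, 1e-12)
    cos = np.clip(np.einsum("tpk,tpk->tp", surface.normals, rad), -1.0, 1.0)
    p2 = 1.5 * cos**2 - 0.5
    return float((p2 * surface.area_elements).sum() / surface.area_elements.sum())


def area_per_lipid(surface: FittedSurface, n_lipids: int) -> float:
    """A_L = fitted leaflet area / lipid count (nm^2)."""
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    return surface.area / n_lipids


def bilayer_thickness(outer: FittedSurface, inner: FittedSurface):
    """Head-to-head thickness D_HH: per-node radial gap between the outer
    and inner head-group surfaces, plus its solid-angle weighted mean.

    Returns ``(mean, gaps)``.  Intersecting surfaces raise; identical
    surfaces return zero with a warning.
    """
    if outer.radii.shape != inner.radii.shape:
        raise ValueError("surfaces must share the angular grid")
    gaps = outer.radii - inner.radii
    if np.any(gaps < 0):
        raise ValueError("surfaces intersect: outer radius below inner radius")
    if np.all(gaps == 0):
        warnings.warn("surfaces are identical; thickness is zero", stacklevel=2)
    mean = float((gaps * outer.weights).sum() / outer.weights.sum())
    return mean, gaps


def order_parameter_scd(chains: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Deuterium order parameter profile S_CD(n) for united-atom chains.

    ``chains``: (n_lipids, n_carbons, 3) chain-site positions; ``normals``:
    (n_lipids, 3) local surface normal at each lipid.  Hydrogens are absent,
    so the C-H order parameter is reconstructed from backbone geometry via
    the axial-symmetry identity

        S_CD(n) = -1/2 <P2(cos theta_n)>,

    theta_n the angle between the local chain axis C_{n-1}->C_{n+1} and the
    normal.  An all-trans chain along the normal gives exactly -0.5; an
    isotropic chain ensemble averages to 0.  Output length is n_carbons - 2
    (interior carbons).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 3 or chains.shape[1] < 3:
        raise ValueError("need chains of at least 3 sites: (n_lipids, n_carbons, 3)")
    normals = np.asarray(normals, dtype=float).reshape(-1, 3)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    axis = chains[:, 2:, :] - chains[:, :-2, :]
    axis = axis / np.maximum(np.linalg.norm(axis, axis=2, keepdims=True), 1e-12)
    cos = np.einsum("lck,lk->lc", axis, normals)
    p2 = 1.5 * cos**2 - 0.5
    return -0.5 * p2.mean(axis=0)


def roundness_index(surface: FittedSurface) -> float:
    """Sphericity psi = pi^(1/3) (6 V)^(2/3) / A, equal to 1 iff the surface
    is a sphere (isoperimetric inequality bounds it by 1)."""
    if surface.volume <= 0:
        raise ValueError("nonpositive enclosed volume")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * surface.volume) ** (2.0 / 3.0) / surface.area)


def moments_of_inertia(positions: np.ndarray, masses: np.ndarray | float = 1.0) -> np.ndarray:
    """Ascending principal moments (I1, I2, I3) about the center of mass
    (mass nm^2).  Collinear point sets are degenerate and raise."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(positions) < 3:
        raise ValueError("need at least 3 points")
    m = np.broadcast_to(np.atleast_1d(np.asarray(masses, dtype=float)), (len(positions),))
    com = (m[:, None] * positions).sum(axis=0) / m.sum()
    d = positions - com
    if np.linalg.matrix_rank(d, tol=1e-9 * max(1.0, np.abs(d).max())) < 2:
        raise ValueError("degenerate (collinear) point set")
    r2 = (d**2).sum(axis=1)
    I = np.einsum("n,nij->ij", m,
                  r2[:, None, None] * np.eye(3)[None] - d[:, :, None] * d[:, None, :])
    return np.sort(np.linalg.eigvalsh(I))


def windowed_stats(values: np.ndarray, times: np.ndarray, window: float) -> pd.DataFrame:
    """Min/max/mean over non-overlapping, left-aligned time windows.

    The trailing partial window (if any) is reported with its actual span
    and flagged ``partial=True``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) != len(times):
        raise ValueError("values and times must align")
    dt_est = float(np.median(np.diff(times))) if len(times) > 1 else window
    rows = []
    start = float(times[0])
    while start <= times[-1] + 1e-12:
        end = start + window
        mask = (times >= start - 1e-12) & (times < end - 1e-12)
        if not mask.any():
            break
        sel = values[mask]
        actual_end = float(times[mask][-1])
        # a complete uniform window ends one sample short of `end`
        partial = actual_end < end - dt_est - 1e-9
        rows.append({
            "t_start": start,
            "t_end": actual_end,
            "min": float(sel.min()),
            "max": float(sel.max()),
            "mean": float(sel.mean()),
            "n": int(mask.sum()),
            "partial": bool(partial),
        })
        start = end
    return pd.DataFrame(rows)
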