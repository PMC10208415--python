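"""Per-tooth boundary planes along the arch curve and single-tooth VOIs.

Candidate separation planes are evaluated with the cost

    C_plane = alpha * (1/Np) * sum_u I(p_u)
            + beta  * sum_u I(p_u) * | grad I(p_u) / |I(p_u)| x n |

over Np sample points laid out on the plane, where n is the plane normal and
both the intensity I and its gradient are trilinearly interpolated.  A plane
sliding through an inter-tooth gap sees low mean intensity and little
boundary-crossing gradient, so gap positions are minima of the cost profile
along the arch curve.  The profile is smoothed with a normalized Hanning
window to suppress the high-frequency dips the dark pulp cavities cause
inside each tooth, and each retained minimum is refined by an exhaustive
rotation search about the x and y axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_core import DomainError, ImageVolume, PulpSegError, VolumeOfInterest

__all__ = [
    "SeparationPlane",
    "PlaneCostParams",
    "CostProfile",
    "SeparationError",
    "plane_cost",
    "cost_profile",
    "find_candidate_stations",
    "refine_plane",
    "extract_voi",
]


class SeparationError(PulpSegError):
    """Separation planes enclose no voxels."""


@dataclass(eq=False)
class SeparationPlane:
    """Oriented plane a'x + b'y + c'z - d' = 0 with (a', b', c') the unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, float).reshape(3)
        n = np.asarray(self.normal, float).reshape(3)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = n / nn

    @property
    def constants(self):
        """(a', b', c', d') with d' = n . point."""
        a, b, c = self.normal
        return (float(a), float(b), float(c), float(np.dot(self.normal, self.point)))

    def signed(self, points):
        """Signed value a'x + b'y + c'z - d' for (N, 3) points (mm)."""
        pts = np.asarray(points, float)
        return pts @ self.normal - np.dot(self.normal, self.point)

    def flipped(self):
        return SeparationPlane(self.point.copy(), -self.normal)


@dataclass
class PlaneCostParams:
    """Parameters of the candidate-plane cost evaluation.

    alpha, beta        weights of the mean-intensity and gradient terms
    n_samples          Np; realized as the nearest square grid
    phi1_range/phi2    rotation search half-extent about the x/y axes (deg)
    phi_step           rotation grid step (deg)
    hanning_window     odd window length for cost-profile smoothing (stations)
    plane_halfwidth    in-plane sampling half-extent (mm)
    """

    alpha: float = 1.0
    beta: float = 1.0
    n_samples: int = 1024
    phi1_range: float = 20.0
    phi2_range: float = 20.0
    phi_step: float = 2.0
    hanning_window: int = 11
    plane_halfwidth: float = 8.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.hanning_window < 1 or self.hanning_window % 2 == 0:
            raise ValueError("hanning_window must be odd and >= 1")
        if self.plane_halfwidth <= 0 or self.phi_step <= 0:
            raise ValueError("plane_halfwidth and phi_step must be positive")

    @property
    def grid_side(self):
        return max(2, int(round(np.sqrt(self.n_samples))))


@dataclass(eq=False)
class CostProfile:
    """Plane costs at increasing arc-length stations along the arch curve."""

    positions: np.ndarray
    costs: np.ndarray          # Hanning-smoothed
    raw_costs: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.costs = np.asarray(self.costs, float)
        if self.positions.ndim != 1 or self.positions.shape != self.costs.shape:
            raise ValueError("positions and costs must be equal-length 1D arrays")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.raw_costs is not None:
            self.raw_costs = np.asarray(self.raw_costs, float)


def _inplane_basis(normal):
    n = np.asarray(normal, float)
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(n, z)
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(n, np.array([1.0, 0.0, 0.0]))
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    e2 /= np.linalg.norm(e2)
    return e1, e2


def _plane_samples(plane, params):
    e1, e2 = _inplane_basis(plane.normal)
    m = params.grid_side
    offs = np.linspace(-params.plane_halfwidth, params.plane_halfwidth, m)
    a, b = np.meshgrid(offs, offs, indexing="ij")
    return plane.point + a.reshape(-1, 1) * e1 + b.reshape(-1, 1) * e2


def plane_cost(volume, plane, params=None, _samples=None):
    """Evaluate the candidate-plane cost on a regular in-plane sample grid.

    Samples falling outside the volume contribute zero to both terms; the
    gradient term's division by |I| is guarded so samples with |I| below
    1e-6 of the intensity range contribute zero.
    """
    params = params or PlaneCostParams()
    pts = _plane_samples(plane, params) if _samples is None else _samples
    vals, inside = volume.interpolate(pts)
    if not inside.any():
        raise DomainError("plane lies entirely outside the volume")
    n_p = len(pts)
    term1 = params.alpha * float(vals.sum()) / n_p
    if params.beta == 0.0:
        return term1
    grads, _ = volume.interpolate_gradient(pts)
    lo, hi = volume.intensity_range
    eps = max(1e-6 * (hi - lo), 1e-300)
    absv = np.abs(vals)
    ok = inside & (absv >= eps)
    cross = np.cross(grads[ok] / absv[ok, None], plane.normal)
    term2 = params.beta * float(np.sum(vals[ok] * np.linalg.norm(cross, axis=1)))
    return term1 + term2


def _hanning_smooth(costs, window):
    c = np.asarray(costs, float)
    if window <= 1 or c.size < 2:
        return c.copy()
    w = np.hanning(window)
    if w.sum() == 0:
        return c.copy()
    w = w / w.sum()
    half = window // 2
    pad = np.pad(c, half, mode="reflect") if c.size > half else np.pad(c, half, mode="edge")
    return np.convolve(pad, w, mode="valid")


def cost_profile(volume, curve, params=None, step=0.25, z_center=None):
    """Plane cost at arc-length stations along the curve, Hanning-smoothed.

    At each station the plane passes through the curve point at height
    ``z_center`` (volume z mid-extent by default) with normal along the curve
    tangent (phi1 = phi2 = 0).
    """
    params = params or PlaneCostParams()
    if step <= 0:
        raise ValueError("step must be positive")
    if z_center is None:
        zc = volume.axis_coords(2)
        z_center = 0.5 * (zc[0] + zc[-1])
    stations = np.arange(0.0, curve.length + 1e-9, step)
    if stations.size == 0:
        stations = np.array([0.0])
    xy = curve.point_at(stations)
    x_lo, x_hi = volume.axis_coords(0)[[0, -1]]
    y_lo, y_hi = volume.axis_coords(1)[[0, -1]]
    if not np.any(
        (xy[:, 0] >= x_lo) & (xy[:, 0] <= x_hi) & (xy[:, 1] >= y_lo) & (xy[:, 1] <= y_hi)
    ):
        raise DomainError("arch curve lies outside the volume")
    tang = curve.tangent_at(stations)
    raw = np.empty(stations.size)
    for i, s in enumerate(stations):
        plane = SeparationPlane(
            np.array([xy[i, 0], xy[i, 1], z_center]),
            np.array([tang[i, 0], tang[i, 1], 0.0]),
        )
        raw[i] = plane_cost(volume, plane, params)
    return CostProfile(stations, _hanning_smooth(raw, params.hanning_window), raw)


def find_candidate_stations(profile, min_tooth_width=4.0):
    """Strict local minima of the smoothed cost, at least min_tooth_width apart.

    Among minima closer than ``min_tooth_width`` the lower-cost one is kept;
    exact cost ties keep the earlier station.
    """
    c = profile.costs
    pos = profile.positions
    if c.size < 3:
        return np.array([])
    interior = np.arange(1, c.size - 1)
    is_min = (c[interior] < c[interior - 1]) & (c[interior] < c[interior + 1])
    cand = interior[is_min]
    order = sorted(cand, key=lambda i: (c[i], pos[i]))
    accepted = []
    for i in order:
        if all(abs(pos[i] - pos[j]) >= min_tooth_width for j in accepted):
            accepted.append(i)
    return pos[np.sort(np.asarray(accepted, dtype=int))]


def _rot_x(deg):
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg):
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def plane_at_station(curve, station, z_center, phi1=0.0, phi2=0.0):
    """Plane through the curve point at a station, normal = tangent rotated by
    phi1 about the x axis then phi2 about the y axis."""
    x, y = np.atleast_2d(curve.point_at(station))[0]
    t = np.atleast_2d(curve.tangent_at(station))[0]
    n = np.array([t[0], t[1], 0.0])
    n = _rot_y(phi2) @ (_rot_x(phi1) @ n)
    return SeparationPlane(np.array([x, y, z_center]), n)


def refine_plane(volume, curve, station, params=None, z_center=None):
    """Exhaustive (phi1, phi2) rotation grid search minimizing the plane cost.

    Ties are broken toward smaller |phi1|, then smaller |phi2|.
    """
    params = params or PlaneCostParams()
    if z_center is None:
        zc = volume.axis_coords(2)
        z_center = 0.5 * (zc[0] + zc[-1])

    def angle_grid(extent):
        vals = np.arange(-extent, extent + params.phi_step / 2, params.phi_step)
        return sorted(vals, key=lambda v: (abs(v), v))

    best = None
    best_cost = np.inf
    for p1 in angle_grid(params.phi1_range):
        for p2 in angle_grid(params.phi2_range):
            plane = plane_at_station(curve, station, z_center, p1, p2)
            cost = plane_cost(volume, plane, params)
            if cost < best_cost:
                best_cost = cost
                best = plane
    return best


def extract_voi(volume, left, right, arch=None):
    """Carve the single-tooth VOI between two outward-facing planes.

    A voxel belongs to the slab when its signed value is <= 0 for both
    planes; the VOI box is the axis-aligned bounding box of those voxels and
    voxels violating either inequality are masked to the volume minimum in
    the returned copy.
    """
    nx, ny, nz = volume.shape
    cx = volume.axis_coords(0)[:, None, None]
    cy = volume.axis_coords(1)[None, :, None]
    cz = volume.axis_coords(2)[None, None, :]
    inside = np.ones(volume.shape, dtype=bool)
    for plane in (left, right):
        a, b, c, d = plane.constants
        inside &= (a * cx + b * cy + c * cz - d) <= 0
    if not inside.any():
        raise SeparationError("separation planes enclose no voxels (empty slab)")
    xs = np.flatnonzero(inside.any(axis=(1, 2)))
    ys = np.flatnonzero(inside.any(axis=(0, 2)))
    zs = np.flatnonzero(inside.any(axis=(0, 1)))
    bounds = (
        (int(xs[0]), int(xs[-1]) + 1),
        (int(ys[0]), int(ys[-1]) + 1),
        (int(zs[0]), int(zs[-1]) + 1),
    )
    crop = volume.crop(bounds)
    sub = inside[bounds[0][0] : bounds[0][1], bounds[1][0] : bounds[1][1], bounds[2][0] : bounds[2][1]]
    vmin = volume.values.min()
    crop.values[~sub] = vmin
    return VolumeOfInterest(parent=volume, bounds=bounds, side_planes=(left, right), volume=crop)
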