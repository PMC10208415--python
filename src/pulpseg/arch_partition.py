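"""Separation of the maxillary and mandibular dentitions and fitting of the
quadratic dental-arch curve.

When a CBCT scan is acquired in open-bite position the two dentitions do not
overlap on axial slices, so a threshold on the sagittal maximum intensity
projection (MIP) exposes two bright bands separated by a dark bite gap.  The
bands seed a k-nearest-neighbour classifier that labels every hard-tissue
voxel as maxillary or mandibular; each arch's axial intensity projection is
then fitted with a second-order polynomial y = a*x^2 + b*x + c that
parameterizes the tooth row for the separation-plane search.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .volume_core import PulpSegError

__all__ = [
    "ArchLabel",
    "ArchCurve",
    "CrownSeeds",
    "OpenBiteError",
    "FitError",
    "sagittal_mip",
    "extract_crown_seeds",
    "classify_arch_voxels",
    "fit_arch_curve",
]


class OpenBiteError(PulpSegError):
    """The scan does not show two z-separated dental arches."""


class FitError(PulpSegError):
    """Rank-deficient or under-determined curve fit."""


class ArchLabel(enum.Enum):
    MAXILLARY = "maxillary"
    MANDIBULAR = "mandibular"


# internal x-extension (mm) of the arc-length parameterization; lets the
# pipeline place end planes slightly beyond the outermost teeth
_CURVE_EXTENSION_MM = 15.0
_CURVE_SAMPLES = 4096


@dataclass(eq=False)
class ArchCurve:
    """Quadratic arch curve y = a*x^2 + b*x + c in the axial plane (mm).

    Arc length ``s`` is measured along the curve with ``s = 0`` at
    ``domain[0]``; the parameterization extends a little beyond the fitted
    domain so that planes can be placed just outside the outermost teeth.
    """

    coefficients: tuple
    domain: tuple
    arch: ArchLabel = None

    def __post_init__(self):
        a, b, c = (float(v) for v in self.coefficients)
        self.coefficients = (a, b, c)
        lo, hi = (float(v) for v in self.domain)
        if not lo < hi:
            raise FitError(f"invalid curve domain {self.domain}")
        self.domain = (lo, hi)
        xs = np.linspace(lo - _CURVE_EXTENSION_MM, hi + _CURVE_EXTENSION_MM, _CURVE_SAMPLES)
        ys = self.y(xs)
        seg = np.hypot(np.diff(xs), np.diff(ys))
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self._xs = xs
        self._s = s
        self._s0 = float(np.interp(lo, xs, s))
        self.length = float(np.interp(hi, xs, s)) - self._s0

    def y(self, x):
        a, b, c = self.coefficients
        return a * np.asarray(x, float) ** 2 + b * np.asarray(x, float) + c

    def x_at(self, s):
        """x coordinate at arc-length station(s) s (mm, s=0 at domain start)."""
        return np.interp(np.asarray(s, float) + self._s0, self._s, self._xs)

    def point_at(self, s):
        x = self.x_at(s)
        return np.stack([x, self.y(x)], axis=-1)

    def tangent_at(self, s):
        """Unit tangent (dx, dy) at arc-length station(s), pointing toward +s."""
        a, b, _ = self.coefficients
        x = np.asarray(self.x_at(s), float)
        t = np.stack([np.ones_like(x), 2 * a * x + b], axis=-1)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def station_of_x(self, x):
        return float(np.interp(x, self._xs, self._s) - self._s0)


@dataclass(eq=False)
class CrownSeeds:
    """Thresholded sagittal-MIP pixels split into the two arches.

    ``maxillary``/``mandibular`` are (N, 2) integer arrays of (y, z) MIP
    pixel indices; ``z_gap`` is the half-open index interval of the largest
    empty z band between them and ``threshold`` the intensity cut used.
    """

    maxillary: np.ndarray
    mandibular: np.ndarray
    threshold: float
    z_gap: tuple

    def as_dict(self):
        return {ArchLabel.MAXILLARY: self.maxillary, ArchLabel.MANDIBULAR: self.mandibular}


def sagittal_mip(volume):
    """Maximum intensity projection along x; output[y, z] = max_x I[x, y, z]."""
    return volume.values.max(axis=0)


def extract_crown_seeds(mip, threshold="auto"):
    """Split above-threshold MIP pixels into maxillary/mandibular seed sets.

    The split is made at the largest empty z gap between occupied z rows;
    pixels above the gap (superior) are maxillary, below mandibular.  With
    ``threshold="auto"`` Otsu's threshold of the MIP is used.
    """
    mip = np.asarray(mip, float)
    if threshold == "auto":
        from skimage.filters import threshold_otsu

        if np.unique(mip).size < 2:
            raise OpenBiteError("MIP is uniform; no crowns to threshold")
        threshold = float(threshold_otsu(mip))
    pts = np.argwhere(mip > threshold)
    if pts.size == 0:
        raise OpenBiteError("no above-threshold pixels in the MIP")
    occ = np.unique(pts[:, 1])
    gaps = np.diff(occ)
    if gaps.size == 0 or gaps.max() < 2:
        raise OpenBiteError(
            "above-threshold pixels form fewer than 2 z-separated clusters "
            "(closed-bite acquisition?)"
        )
    g = int(np.argmax(gaps))  # first largest gap
    z_lo, z_hi = int(occ[g]), int(occ[g + 1])  # empty rows are (z_lo, z_hi) exclusive
    mand = pts[pts[:, 1] <= z_lo]
    maxi = pts[pts[:, 1] >= z_hi]
    return CrownSeeds(
        maxillary=maxi, mandibular=mand, threshold=float(threshold), z_gap=(z_lo + 1, z_hi)
    )


def classify_arch_voxels(seeds, query_points, k=5):
    """Label query points by majority vote of their k nearest seeds.

    ``seeds`` maps each :class:`ArchLabel` to an (N, d) coordinate array; the
    query array must share the dimensionality d.  Distances are Euclidean in
    the coordinate units supplied (use mm for physical queries).  A vote tie
    is broken by the label of the single nearest seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = []
    coords = []
    for lab in (ArchLabel.MAXILLARY, ArchLabel.MANDIBULAR):
        arr = np.atleast_2d(np.asarray(seeds[lab], float))
        if arr.size == 0:
            raise ValueError(f"empty seed class {lab.value}")
        coords.append(arr)
        labels.append(np.full(len(arr), lab is ArchLabel.MAXILLARY))
    coords = np.vstack(coords)
    is_max = np.concatenate(labels)
    q = np.atleast_2d(np.asarray(query_points, float))
    if q.shape[1] != coords.shape[1]:
        raise ValueError("query dimensionality does not match seeds")
    kk = min(k, len(coords))
    _, idx = cKDTree(coords).query(q, k=kk)
    idx = np.atleast_2d(idx.reshape(len(q), kk))
    votes_max = is_max[idx].sum(axis=1)
    out = np.empty(len(q), dtype=object)
    maj = votes_max * 2 > kk
    tie = votes_max * 2 == kk
    out[:] = ArchLabel.MANDIBULAR
    out[maj] = ArchLabel.MAXILLARY
    if tie.any():  # even k: fall back to the nearest seed's label
        nearest_max = is_max[idx[:, 0]]
        out[tie & nearest_max] = ArchLabel.MAXILLARY
    return out


def fit_arch_curve(points, arch=None):
    """Weighted least-squares fit of y = a*x^2 + b*x + c.

    ``points`` is (N, 2) of (x, y) or (N, 3) of (x, y, weight); weights are
    typically summed axial-projection intensities.  Requires at least three
    distinct x values.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.ones(len(pts))])
    if pts.shape[1] != 3:
        raise ValueError("points must be (N, 2) or (N, 3)")
    x, y, w = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    keep = w > 0
    x, y, w = x[keep], y[keep], w[keep]
    if len(x) < 3 or np.unique(x).size < 3:
        raise FitError("need >= 3 points with >= 3 distinct x values")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient arch-curve design matrix")
    return ArchCurve(tuple(coef), (float(x.min()), float(x.max())), arch)
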