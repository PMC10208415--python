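"""Quantitative and qualitative comparison of automatic vs reference
segmentations.

Three metrics are computed per tooth: the Dice overlap coefficient, the
average symmetric surface distance (ASD, mm) between the two segmentation
surfaces, and the Mahalanobis distance (MHD, mm) between the surface point
clouds — a covariance-normalized between-mean distance that discounts local
differences in favour of global shape agreement.  Summaries are stratified
by tooth type and rootedness; qualitative review categories are tallied the
same way.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .pulp_segmentation import ToothClass, ToothKind
from .volume_core import BinaryMask, GeometryError

__all__ = [
    "SegmentationMetrics",
    "QualityCategory",
    "dice",
    "asd",
    "surface_voxels",
    "mahalanobis",
    "evaluate_pair",
    "summarize",
    "tally_categories",
]


@dataclass(frozen=True)
class SegmentationMetrics:
    """Dice in [0, 1], surface distances in mm (ideal: 1, 0, 0)."""

    dice: float
    asd_mm: float
    mhd_mm: float

    def __post_init__(self):
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError("dice must lie in [0, 1]")
        if self.asd_mm < 0 or self.mhd_mm < 0:
            raise ValueError("distances must be >= 0")


class QualityCategory(enum.Enum):
    GOOD = "good"
    APICAL_OVERFLOW = "apical_overflow"
    CROWN_OVERFLOW = "crown_overflow"
    MISSING_CANAL = "missing_canal"
    MISSING_CANAL_EXTREMITY = "missing_canal_extremity"
    SEGMENTATION_ERROR = "segmentation_error"
    OTHER = "other"


def _check_geometry(a, b):
    if not a.same_geometry(b):
        raise GeometryError("masks do not share grid geometry")


def dice(a, b):
    """Dice overlap 2|a n b| / (|a| + |b|); 1 when both masks are empty."""
    _check_geometry(a, b)
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


_SURF_STRUCT = ndi.generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask):
    """Mask voxels with at least one 6-connected complement neighbour.

    Out-of-grid neighbours count as complement, so border voxels are surface.
    """
    v = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    eroded = ndi.binary_erosion(v, structure=_SURF_STRUCT, border_value=0)
    return v & ~eroded


def _surface_points_mm(mask):
    surf = surface_voxels(mask)
    idx = np.argwhere(surf)
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing), surf


def asd(a, b):
    """Average symmetric surface distance in mm (pooled over both directions)."""
    _check_geometry(a, b)
    if a.count() == 0 or b.count() == 0:
        raise ValueError("asd requires non-empty masks")
    surf_a = surface_voxels(a)
    surf_b = surface_voxels(b)
    dt_to_b = ndi.distance_transform_edt(~surf_b, sampling=a.spacing)
    dt_to_a = ndi.distance_transform_edt(~surf_a, sampling=a.spacing)
    pooled = np.concatenate([dt_to_b[surf_a], dt_to_a[surf_b]])
    return float(pooled.mean())


def mahalanobis(a, b, ridge=1e-6):
    """Mahalanobis distance between two point clouds (or mask surfaces).

    sqrt((mu_a - mu_b)^T Sigma^-1 (mu_a - mu_b)) with Sigma the size-weighted
    pooled covariance of both clouds.  A singular covariance is ridge
    regularized (lambda = ridge * trace / dim) with a warning.
    """
    pts = []
    for cloud in (a, b):
        if isinstance(cloud, BinaryMask):
            p, _ = _surface_points_mm(cloud)
        else:
            p = np.atleast_2d(np.asarray(cloud, float))
        if len(p) < 4:
            raise ValueError("each cloud needs >= 4 points")
        pts.append(p)
    pa, pb = pts
    mu = pa.mean(axis=0) - pb.mean(axis=0)
    ca = np.cov(pa, rowvar=False, bias=True)
    cb = np.cov(pb, rowvar=False, bias=True)
    na, nb = len(pa), len(pb)
    sigma = (na * ca + nb * cb) / (na + nb)
    dim = sigma.shape[0]
    try:
        sol = np.linalg.solve(sigma, mu)
        if not np.all(np.isfinite(sol)) or np.linalg.cond(sigma) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        lam = ridge * np.trace(sigma) / dim
        if lam <= 0:
            lam = ridge
        warnings.warn("singular pooled covariance; ridge-regularizing", stacklevel=2)
        sol = np.linalg.solve(sigma + lam * np.eye(dim), mu)
    d2 = float(mu @ sol)
    return float(np.sqrt(max(d2, 0.0)))


def evaluate_pair(auto, reference):
    """All three metrics for one automatic/reference mask pair."""
    return SegmentationMetrics(
        dice=dice(auto, reference), asd_mm=asd(auto, reference), mhd_mm=mahalanobis(auto, reference)
    )


_STRATA = [
    ("single-rooted", "incisor"),
    ("single-rooted", "canine"),
    ("single-rooted", "premolar"),
    ("single-rooted", "all"),
    ("multi-rooted", "premolar"),
    ("multi-rooted", "molar"),
    ("multi-rooted", "all"),
    ("global", "all"),
]


def _in_stratum(tooth_class, stratum):
    root, kind = stratum
    if root == "global":
        return True
    multi = tooth_class.is_multi_rooted
    if (root == "multi-rooted") != multi:
        return False
    return kind == "all" or tooth_class.kind.value == kind


def summarize(records):
    """Min/max/mean/population-SD summary per metric, stratified by tooth class.

    ``records`` is a list of (ToothClass, SegmentationMetrics).  Dice is
    reported in percent, distances in mm; empty strata are omitted.
    """
    if not records:
        raise ValueError("no records to summarize")
    rows = {}
    for stratum in _STRATA:
        sel = [m for tc, m in records if _in_stratum(tc, stratum)]
        if not sel:
            continue
        row = {"n": len(sel)}
        for metric, scale in (("dice", 100.0), ("asd_mm", 1.0), ("mhd_mm", 1.0)):
            vals = np.array([getattr(m, metric) for m in sel]) * scale
            col = {"dice": "dice_pct", "asd_mm": "asd_mm", "mhd_mm": "mhd_mm"}[metric]
            row[f"{col}_min"] = vals.min()
            row[f"{col}_max"] = vals.max()
            row[f"{col}_mean"] = vals.mean()
            row[f"{col}_sd"] = vals.std(ddof=0)
        rows[" / ".join(stratum)] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def tally_categories(labels):
    """Count table of qualitative categories per tooth-class stratum.

    ``labels`` is a list of (ToothClass, QualityCategory); columns are the
    strata, rows the seven categories, and every record lands in exactly one
    rootedness stratum (plus the global column).
    """
    table = pd.DataFrame(
        0,
        index=[c.value for c in QualityCategory],
        columns=[" / ".join(s) for s in _STRATA],
        dtype=int,
    )
    for tc, cat in labels:
        for stratum in _STRATA:
            if _in_stratum(tc, stratum):
                table.loc[cat.value, " / ".join(stratum)] += 1
    return table
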