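"""Morphology-based pulp segmentation inside a single-tooth VOI.

On CBCT the tooth is a bright solid (dentine/enamel) and the pulp a dark
cavity inside it, so the pulp is exactly a grayscale "hole": a dark region
enclosed by brighter material.  The pipeline exploits this three ways:

* a **marker** from the difference between the image and its grayscale
  hole-filled version (large exactly inside enclosed dark cavities), reduced
  by an Otsu threshold and a radius limit around the strongest-difference
  voxel;
* a **valley mask** from a black top-hat of the Gaussian-blurred image
  followed by hole filling, binarized (valleys appear bright);
* a **morphological reconstruction** of the mask from the marker — the union
  of mask components touching the marker.

Two guards then trim overflow: a midpoint-intensity mask applied in the
crown region only (bright dentine wrongly captured there is removed) and a
slice-area-evolution model that cuts rapid shape changes in the apical fifth
of non-molar teeth.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .arch_partition import ArchLabel
from .volume_core import BinaryMask, ImageVolume, NoCavityError, PulpSegError, VolumeOfInterest

__all__ = [
    "PulpSegParams",
    "ToothKind",
    "ToothClass",
    "AreaEvolutionModel",
    "CrownExtent",
    "fill_holes",
    "build_marker",
    "build_valley_mask",
    "reconstruct",
    "find_crown_extent",
    "apply_crown_mask",
    "slice_area_vector",
    "fit_area_model",
    "apply_apical_cut",
    "segment_pulp",
    "models_to_json",
    "models_from_json",
]


@dataclass
class PulpSegParams:
    """Tunable parameters of the pulp segmentation.

    gaussian_sigma        mm, pre-smoothing before the black top-hat
    tophat_radius         mm, structuring-element radius of the black top-hat
    marker_radius         mm, kept region around the maximum-difference voxel
    mask_threshold        'otsu' or 'positive' binarization of the valley image
    uniform_filter_width  samples, smoothing of the candidate area gradient
    sd_margin             multiplier of the model SD for the apical-cut test
    """

    gaussian_sigma: float = 0.15
    tophat_radius: float = 2.0
    marker_radius: float = 2.0
    mask_threshold: str = "otsu"
    uniform_filter_width: int = 5
    sd_margin: float = 2.0

    def __post_init__(self):
        if self.gaussian_sigma < 0 or self.tophat_radius < 0 or self.marker_radius < 0:
            raise ValueError("radii and sigmas must be >= 0")
        if self.sd_margin <= 0:
            raise ValueError("sd_margin must be positive")
        if self.mask_threshold not in ("positive", "otsu"):
            raise ValueError("mask_threshold must be 'positive' or 'otsu'")


class ToothKind(enum.Enum):
    INCISOR = "incisor"
    CANINE = "canine"
    PREMOLAR = "premolar"
    MOLAR = "molar"


_FDI_KIND = {1: ToothKind.INCISOR, 2: ToothKind.INCISOR, 3: ToothKind.CANINE,
             4: ToothKind.PREMOLAR, 5: ToothKind.PREMOLAR,
             6: ToothKind.MOLAR, 7: ToothKind.MOLAR, 8: ToothKind.MOLAR}


@dataclass(frozen=True)
class ToothClass:
    """Tooth type + arch + FDI position code (e.g. 41 = lower right central incisor)."""

    kind: ToothKind
    arch: ArchLabel
    position: int
    multi_rooted: bool = None

    def __post_init__(self):
        q, d = divmod(self.position, 10)
        if q not in (1, 2, 3, 4) or d not in _FDI_KIND:
            raise ValueError(f"invalid FDI position {self.position}")
        if _FDI_KIND[d] is not self.kind:
            raise ValueError(f"FDI position {self.position} is not a {self.kind.value}")
        expected = ArchLabel.MAXILLARY if q in (1, 2) else ArchLabel.MANDIBULAR
        if expected is not self.arch:
            raise ValueError(f"FDI position {self.position} is not {self.arch.value}")

    @property
    def is_multi_rooted(self):
        if self.multi_rooted is not None:
            return self.multi_rooted
        return self.kind is ToothKind.MOLAR

    @property
    def key(self):
        return (self.kind.value, self.position)


@dataclass(eq=False)
class AreaEvolutionModel:
    """Per-class mean/SD gradient of normalized 100-sample axial-area profiles."""

    tooth_class: ToothClass
    mean_gradient: np.ndarray
    sd_gradient: np.ndarray

    def __post_init__(self):
        self.mean_gradient = np.asarray(self.mean_gradient, float)
        self.sd_gradient = np.asarray(self.sd_gradient, float)
        if self.mean_gradient.shape != (100,) or self.sd_gradient.shape != (100,):
            raise ValueError("model gradients must be length-100 vectors")
        if np.any(self.sd_gradient < 0):
            raise ValueError("sd_gradient must be non-negative")


def _full_struct(ndim):
    # 26-connectivity in 3D, 8-connectivity in 2D, everywhere
    return np.ones((3,) * ndim, dtype=bool)


def _footprint(radius_mm, spacing):
    """Boolean ball/disk footprint of a physical radius on an anisotropic grid."""
    spacing = tuple(float(s) for s in spacing)
    r = [max(0, int(np.ceil(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(*[np.arange(-ri, ri + 1) * si for ri, si in zip(r, spacing)],
                        indexing="ij")
    d2 = sum(g**2 for g in grids)
    fp = d2 <= radius_mm**2 + 1e-12
    fp[tuple(ri for ri in r)] = True  # always contains the centre
    return fp


def fill_holes(image):
    """Grayscale hole filling by reconstruction-by-erosion from the border.

    Every dark region not connected to the image border is raised to the
    minimum intensity of its enclosing rim.  Extensive (output >= input) and
    idempotent; border values are unchanged.  Works on 2D or 3D arrays.
    """
    from skimage.morphology import reconstruction

    img = np.asarray(image, float)
    if img.size == 0:
        return img.copy()
    seed = np.full_like(img, img.max())
    border = np.ones(img.shape, dtype=bool)
    border[tuple(slice(1, -1) for _ in img.shape)] = False
    seed[border] = img[border]
    if img.ndim == 1 or min(img.shape) <= 2:
        return np.maximum(img, seed.min())  # degenerate: everything is border
    return reconstruction(seed, img, method="erosion", footprint=_full_struct(img.ndim))


def build_marker(image, spacing, params=None, variant="improved"):
    """Marker for the morphological reconstruction, from the hole-fill difference.

    ``diff = fill_holes(image) - image`` is large inside enclosed dark
    cavities.  The ``initial`` variant binarizes diff > 0 and keeps the
    second-largest connected component (the largest is typically background
    overflow); the ``improved`` variant thresholds diff with Otsu's method,
    keeps the component containing the maximum-difference voxel and limits it
    to a ball of ``marker_radius`` around that voxel.
    """
    params = params or PulpSegParams()
    img = np.asarray(image, float)
    filled = fill_holes(img)
    diff = filled - img
    rng = max(float(img.max() - img.min()), 1.0)
    if diff.max() <= 1e-9 * rng:
        raise NoCavityError("image contains no enclosed dark cavity")
    struct = _full_struct(img.ndim)
    if variant == "initial":
        lbl, n = ndi.label(diff > 0, structure=struct)
        sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1]
        pick = order[1] + 1 if n >= 2 else order[0] + 1
        return lbl == pick
    if variant != "improved":
        raise ValueError(f"unknown marker variant {variant!r}")
    pos = diff[diff > 0]
    if np.unique(pos).size >= 2:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(pos))
    else:
        thr = float(pos.min())
    bw = diff >= thr
    peak = np.unravel_index(int(np.argmax(diff)), diff.shape)
    lbl, _ = ndi.label(bw, structure=struct)
    comp = lbl == lbl[peak]
    if params.marker_radius > 0:
        grids = np.meshgrid(*[(np.arange(nn) - p) * s
                              for nn, p, s in zip(img.shape, peak, spacing)], indexing="ij")
        ball = sum(g**2 for g in grids) <= params.marker_radius**2
        comp &= ball
    return comp


def cavity_component(image):
    """Full diff > 0 cavity component containing the maximum-difference voxel.

    This is the unreduced cavity region (the initial-marker support); its
    intensity statistics drive the crown midpoint threshold.
    """
    img = np.asarray(image, float)
    diff = fill_holes(img) - img
    rng = max(float(img.max() - img.min()), 1.0)
    if diff.max() <= 1e-9 * rng:
        raise NoCavityError("image contains no enclosed dark cavity")
    peak = np.unravel_index(int(np.argmax(diff)), diff.shape)
    lbl, _ = ndi.label(diff > 0, structure=_full_struct(img.ndim))
    return lbl == lbl[peak]


def build_valley_mask(image, spacing, params=None):
    """Valley mask: hole-filled black top-hat of the Gaussian-blurred image.

    Dark regions enclosed in brighter ones appear bright in the top-hat
    image; hole filling completes valleys wider than twice the structuring
    element.  Binarization follows ``params.mask_threshold``.
    """
    params = params or PulpSegParams()
    img = np.asarray(image, float)
    if params.gaussian_sigma > 0:
        img = ndi.gaussian_filter(img, [params.gaussian_sigma / s for s in spacing])
    fp = _footprint(params.tophat_radius, spacing)
    bth = ndi.grey_closing(img, footprint=fp) - img
    v = fill_holes(bth)
    if params.mask_threshold == "positive":
        return v > 0
    if np.unique(v).size < 2:
        return np.zeros_like(v, dtype=bool)
    from skimage.filters import threshold_otsu

    return v > float(threshold_otsu(v))


def reconstruct(marker, mask):
    """Binary morphological reconstruction by dilation.

    Equals the union of mask-connected components intersecting the marker
    (the fixed point of dilate-then-intersect); an empty marker yields an
    empty result.
    """
    marker = np.asarray(marker, bool)
    mask = np.asarray(mask, bool)
    if marker.shape != mask.shape:
        raise ValueError("marker and mask shapes differ")
    m = marker & mask
    out = np.zeros_like(mask)
    if not m.any():
        return out
    lbl, _ = ndi.label(mask, structure=_full_struct(mask.ndim))
    keep = np.unique(lbl[m])
    keep = keep[keep > 0]
    return np.isin(lbl, keep)


@dataclass(frozen=True)
class CrownExtent:
    orientation: str           # 'crown_at_low_z' or 'crown_at_high_z'
    chamber_slice: int
    crown_apical_limit: int


def _as_bool3(seg):
    if isinstance(seg, BinaryMask):
        return seg.values
    return np.asarray(seg, bool)


def _slice_region_stats(seg):
    """Per-axial-slice (largest single 2D region area, region count)."""
    struct = _full_struct(2)
    nz = seg.shape[2]
    largest = np.zeros(nz)
    counts = np.zeros(nz, dtype=int)
    for z in range(nz):
        sl = seg[:, :, z]
        if not sl.any():
            continue
        lbl, n = ndi.label(sl, structure=struct)
        sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        largest[z] = sizes.max()
        counts[z] = n
    return largest, counts


def find_crown_extent(seg):
    """Locate the pulp chamber and the apical limit of the crown region.

    The chamber slice has the largest single connected 2D region; the root
    side is the occupied extreme farther from the chamber, and the crown's
    apical limit is the last slice (moving chamber -> roots) whose
    segmentation is a single connected region.
    """
    seg = _as_bool3(seg)
    if not seg.any():
        raise ValueError("empty segmentation")
    largest, counts = _slice_region_stats(seg)
    occupied = np.flatnonzero(counts > 0)
    first, last = int(occupied[0]), int(occupied[-1])
    chamber = int(np.argmax(largest))
    orientation = "crown_at_low_z" if (last - chamber) >= (chamber - first) else "crown_at_high_z"
    step = 1 if orientation == "crown_at_low_z" else -1
    limit = chamber
    z = chamber
    while first <= z <= last and counts[z] == 1:
        limit = z
        z += step
    return CrownExtent(orientation, chamber, limit)


def apply_crown_mask(image, seg, marker, extent, params=None):
    """Remove bright (dentine-level) voxels from the crown-region segmentation.

    The threshold is the midpoint between the mean intensity over the marker
    and over a 1-voxel shell around it; segmented voxels brighter than the
    threshold inside the crown slices are dropped, root slices are untouched.
    """
    img = np.asarray(image, float)
    seg = _as_bool3(seg).copy()
    marker = np.asarray(marker, bool)
    if not marker.any():
        raise ValueError("empty marker")
    shell = ndi.binary_dilation(marker, structure=_full_struct(marker.ndim)) & ~marker
    if shell.any():
        t = 0.5 * (float(img[marker].mean()) + float(img[shell].mean()))
    else:
        vals = img[seg]
        if np.unique(vals).size >= 2:
            from skimage.filters import threshold_otsu

            t = float(threshold_otsu(vals))
        else:
            t = float(vals.max())
    if extent.orientation == "crown_at_low_z":
        crown = slice(0, extent.crown_apical_limit + 1)
    else:
        crown = slice(extent.crown_apical_limit, seg.shape[2])
    region = seg[:, :, crown] & (img[:, :, crown] > t)
    seg[:, :, crown] &= ~region
    return seg


def slice_area_vector(seg, orientation, spacing=(1.0, 1.0, 1.0)):
    """Normalized 100-sample axial-area profile in crown -> apex order.

    Per-slice areas (mm^2) over the occupied slice span are divided by their
    maximum and linearly resampled to 100 samples.
    """
    seg = _as_bool3(seg)
    if not seg.any():
        raise ValueError("empty segmentation")
    occ = np.flatnonzero(seg.any(axis=(0, 1)))
    first, last = int(occ[0]), int(occ[-1])
    pix = float(spacing[0]) * float(spacing[1])
    areas = seg[:, :, first : last + 1].sum(axis=(0, 1)).astype(float) * pix
    if orientation == "crown_at_high_z":
        areas = areas[::-1]
    areas = areas / areas.max()
    n = areas.size
    if n == 1:
        return np.ones(100)
    return np.interp(np.linspace(0, 1, 100), np.linspace(0, 1, n), areas)


def fit_area_model(references, uniform_filter_width=5):
    """Fit slice-area-evolution models from reference (mask, ToothClass) pairs.

    One model per (kind, position) class: elementwise mean and population SD
    of the central-difference gradients of the references' 100-sample area
    profiles.  Reference gradients receive the same uniform-filter smoothing
    later applied to candidates, so the deviation test compares like with
    like (pass width 1 for raw gradients).  Molars are excluded from modeling
    (their morphology is too variable); passing one raises.
    """
    groups = {}
    for seg, tooth_class in references:
        if tooth_class.kind is ToothKind.MOLAR:
            raise ValueError("molars are excluded from area-evolution modeling")
        extent = find_crown_extent(seg)
        spacing = seg.spacing if isinstance(seg, BinaryMask) else (1.0, 1.0, 1.0)
        v = slice_area_vector(seg, extent.orientation, spacing)
        g = ndi.uniform_filter1d(
            np.gradient(v), size=max(1, int(uniform_filter_width)), mode="nearest"
        )
        groups.setdefault(tooth_class.key, (tooth_class, []))[1].append(g)
    if not groups:
        raise ValueError("no references supplied")
    models = {}
    for key, (tooth_class, grads) in groups.items():
        g = np.vstack(grads)
        models[key] = AreaEvolutionModel(tooth_class, g.mean(axis=0), g.std(axis=0, ddof=0))
    return models


def apply_apical_cut(seg, model, tooth_class, params=None, spacing=(1.0, 1.0, 1.0)):
    """Cut apical overflow where the candidate area gradient leaves the model band.

    Only samples in the last fifth (apical) of the 100-sample profile are
    examined; if any smoothed-gradient sample deviates from the model mean by
    more than ``sd_margin`` SDs, all slices apical of the most coronal
    deviation are removed.  Molar inputs are always returned unchanged.
    """
    params = params or PulpSegParams()
    is_mask = isinstance(seg, BinaryMask)
    arr = _as_bool3(seg).copy()
    if tooth_class is not None and tooth_class.kind is ToothKind.MOLAR:
        return BinaryMask(arr, seg.spacing, seg.origin) if is_mask else arr
    if is_mask:
        spacing = seg.spacing
    extent = find_crown_extent(arr)
    v = slice_area_vector(arr, extent.orientation, spacing)
    g = ndi.uniform_filter1d(np.gradient(v), size=max(1, int(params.uniform_filter_width)),
                             mode="nearest")
    dev = np.abs(g - model.mean_gradient) > params.sd_margin * model.sd_gradient
    apical = np.flatnonzero(dev[80:])  # last fifth of the profile
    if apical.size == 0:
        return BinaryMask(arr, seg.spacing, seg.origin) if is_mask else arr
    i0 = int(apical[0]) + 80  # most coronal deviating sample
    occ = np.flatnonzero(arr.any(axis=(0, 1)))
    first, last = int(occ[0]), int(occ[-1])
    n = last - first + 1
    offset = int(np.floor(i0 / 99.0 * (n - 1)))  # proportional, rounded toward the crown
    if extent.orientation == "crown_at_low_z":
        arr[:, :, first + offset :] = False
    else:
        arr[:, :, : last - offset + 1] = False
    return BinaryMask(arr, seg.spacing, seg.origin) if is_mask else arr


def segment_pulp(voi, params=None, tooth_class=None, model=None, mode="volume"):
    """Full pulp segmentation of a single-tooth VOI.

    Composition: improved marker -> valley mask -> morphological
    reconstruction -> crown midpoint-threshold mask -> apical area-evolution
    cut (when a model is given and the tooth is not a molar).  ``mode``
    selects whole-volume 3D morphology (default) or the per-axial-slice
    variant (``"slice"``).
    """
    params = params or PulpSegParams()
    vol = voi.volume if isinstance(voi, VolumeOfInterest) else voi
    img = vol.values
    spacing = vol.spacing
    if mode == "volume":
        marker = build_marker(img, spacing, params)
        valley = build_valley_mask(img, spacing, params)
        seg = reconstruct(marker, valley)
        stats_marker = cavity_component(img)
    elif mode == "slice":
        seg = np.zeros(img.shape, dtype=bool)
        stats_marker = np.zeros(img.shape, dtype=bool)
        sp2 = spacing[:2]
        any_cavity = False
        for z in range(img.shape[2]):
            sl = img[:, :, z]
            try:
                mk = build_marker(sl, sp2, params)
            except NoCavityError:
                continue
            any_cavity = True
            vm = build_valley_mask(sl, sp2, params)
            seg[:, :, z] = reconstruct(mk, vm)
            stats_marker[:, :, z] = cavity_component(sl)
        if not any_cavity:
            raise NoCavityError("no axial slice contains an enclosed dark cavity")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not seg.any():
        raise NoCavityError("pulp reconstruction is empty")
    extent = find_crown_extent(seg)
    # the crown threshold uses the *unreduced* cavity region's statistics
    seg = apply_crown_mask(img, seg, stats_marker, extent, params)
    if not seg.any():
        raise NoCavityError("crown masking removed the entire segmentation")
    if model is not None and (tooth_class is None or tooth_class.kind is not ToothKind.MOLAR):
        seg = apply_apical_cut(seg, model, tooth_class, params, spacing)
    return BinaryMask(seg, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Model serialization (JSON keyed by tooth class)
# ---------------------------------------------------------------------------


def models_to_json(models, path=None):
    payload = {}
    for key, m in models.items():
        tc = m.tooth_class
        payload[f"{key[0]}:{key[1]}"] = {
            "kind": tc.kind.value,
            "arch": tc.arch.value,
            "position": tc.position,
            "mean_gradient": m.mean_gradient.tolist(),
            "sd_gradient": m.sd_gradient.tolist(),
        }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def models_from_json(source):
    if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    models = {}
    for entry in payload.values():
        tc = ToothClass(ToothKind(entry["kind"]), ArchLabel(entry["arch"]), int(entry["position"]))
        models[tc.key] = AreaEvolutionModel(
            tc, np.asarray(entry["mean_gradient"]), np.asarray(entry["sd_gradient"])
        )
    return models
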