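"""Synthetic CBCT-like dental phantoms with voxel-perfect ground truth.

Every pipeline stage is testable without clinical data: the generator builds
bright tooth solids (a barrel-profile crown over one to three tapered-cone
roots) containing darker pulp cavities (a chamber plus one canal per root
reaching near the apex), embeds the roots in a bone collar, arranges two
dentitions along quadratic arch curves separated by a dark open-bite gap,
and renders the scene by solid membership at voxel centres followed by
partial-volume Gaussian blur and additive Gaussian noise.  Ground-truth
masks are rendered before blurring; true separation planes sit mid-gap,
orthogonal to the arch curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .arch_partition import ArchCurve, ArchLabel
from .pulp_segmentation import ToothClass, ToothKind
from .tooth_separation import SeparationPlane
from .volume_core import BinaryMask, ImageVolume, PulpSegError

__all__ = [
    "PhantomIntensities",
    "PhantomSpec",
    "PhantomCase",
    "PhantomSpecError",
    "PlacementError",
    "generate_tooth",
    "generate_arch_scene",
    "default_scene",
]


class PhantomSpecError(PulpSegError):
    """Geometrically impossible phantom specification."""


class PlacementError(PulpSegError):
    """Teeth overlap at the requested arch spacing."""


@dataclass(frozen=True)
class PhantomIntensities:
    """Abstract CBCT-like intensity levels (not calibrated HU)."""

    background: float = 50.0
    bone: float = 400.0
    dentine: float = 1000.0
    enamel: float = 1400.0
    pulp: float = 120.0

    def validate(self):
        if not (self.pulp < self.bone < self.dentine <= self.enamel):
            raise PhantomSpecError("intensities must satisfy pulp < bone < dentine <= enamel")
        if not self.background < self.bone:
            raise PhantomSpecError("background must be darker than bone")


_DEFAULT_CLASS = ToothClass(ToothKind.INCISOR, ArchLabel.MANDIBULAR, 41)

_N_ROOTS_ALLOWED = {
    ToothKind.INCISOR: (1,),
    ToothKind.CANINE: (1,),
    ToothKind.PREMOLAR: (1, 2),
    ToothKind.MOLAR: (2, 3),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and degradation of one synthetic tooth.

    Lengths in mm.  ``pulp_scale`` is the fraction of the tooth cross-section
    occupied by pulp; ``noise_sd`` defaults to 2% of the dentine level (the
    reference noise condition of the synthetic study scenes).
    """

    tooth_class: ToothClass = _DEFAULT_CLASS
    n_roots: int = 1
    crown_height: float = 4.0
    crown_radius: float = 2.6
    root_length: float = 8.0
    root_radius: float = 1.8
    pulp_scale: float = 0.45
    intensities: PhantomIntensities = field(default_factory=PhantomIntensities)
    blur_sigma: float = 0.2
    noise_sd: float = 20.0
    voxel_size: float = 0.25
    bone_thickness: float = 1.2
    open_apex: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pulp_scale < 1:
            raise PhantomSpecError("pulp_scale must lie in (0, 1)")
        if self.n_roots not in _N_ROOTS_ALLOWED[self.tooth_class.kind]:
            raise PhantomSpecError(
                f"{self.tooth_class.kind.value} cannot have {self.n_roots} root(s)"
            )
        for name in ("crown_height", "crown_radius", "root_length", "root_radius", "voxel_size"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be positive")
        self.intensities.validate()
        if self.n_roots > 1:
            d = 0.40 * self.crown_radius
            if d + self.root_radius > 0.75 * self.crown_radius + 1e-9:
                raise PhantomSpecError("roots do not fit under the crown")

    @property
    def footprint_radius(self):
        return self.crown_radius + self.bone_thickness

    @property
    def total_height(self):
        return self.crown_height + self.root_length


@dataclass(eq=False)
class PhantomCase:
    """A rendered phantom with its ground truth."""

    volume: ImageVolume
    tooth_masks: list
    pulp_masks: list
    true_planes: dict            # ArchLabel -> [SeparationPlane] (may be empty)
    arch_labels: list
    specs: list
    true_curves: dict = field(default_factory=dict)   # ArchLabel -> ArchCurve
    bite_gap_z: tuple = None     # (z_lo, z_hi) mm of the open-bite gap

    def __post_init__(self):
        for tooth, pulp in zip(self.tooth_masks, self.pulp_masks):
            if np.any(pulp.values & ~tooth.values):
                raise PhantomSpecError("pulp mask must be contained in its tooth mask")
        for i in range(len(self.tooth_masks)):
            for j in range(i + 1, len(self.tooth_masks)):
                if np.any(self.tooth_masks[i].values & self.tooth_masks[j].values):
                    raise PlacementError("tooth masks overlap")


def _root_offsets(spec):
    if spec.n_roots == 1:
        return np.array([[0.0, 0.0]])
    d = 0.40 * spec.crown_radius
    if spec.n_roots == 2:
        return np.array([[-d, 0.0], [d, 0.0]])
    ang = np.deg2rad([90.0, 210.0, 330.0])
    return np.stack([d * np.cos(ang), d * np.sin(ang)], axis=1)


def _tooth_solids(spec, lx, ly, lz):
    """Boolean membership of tooth / pulp / enamel in the tooth's local frame.

    Local frame: origin at the cervical line on the tooth axis, +z toward the
    crown tip; the crown occupies z in [0, h], roots z in [-root_length, 0].
    """
    h = spec.crown_height
    rl = spec.root_length

    # crown: barrel profile, widest at mid-height, 75% radius at both ends
    zeta = np.clip((lz - h / 2) / (h / 2), -1.0, 1.0)
    crown_r = spec.crown_radius * (1.0 - 0.25 * zeta**6)
    r2 = lx**2 + ly**2
    in_crown = (lz >= 0) & (lz <= h) & (r2 <= crown_r**2)

    # roots: tapered cones, radius falling to 20% at the apex; multi-rooted
    # teeth keep a united root trunk for the coronal 30% of the root length
    # (the chamber floor sits on trunk dentine, above the furcation)
    offsets = _root_offsets(spec)
    t = np.clip(-lz / rl, 0.0, 1.0)
    root_r = spec.root_radius * (1.0 - 0.8 * t)
    in_roots = np.zeros_like(in_crown)
    root_zone = (lz <= 0) & (lz >= -rl)
    for ox, oy in offsets:
        in_roots |= root_zone & ((lx - ox) ** 2 + (ly - oy) ** 2 <= root_r**2)
    if spec.n_roots > 1:
        trunk_len = 0.3 * rl
        trunk_r = np.abs(offsets).max() + root_r
        in_roots |= (lz <= 0) & (lz >= -trunk_len) & (r2 <= trunk_r**2)

    tooth = in_crown | in_roots

    # enamel: outer 0.7 mm shell of the crown (and the incisal/occlusal cap)
    shell = 0.7
    in_enamel = in_crown & ((r2 >= np.maximum(crown_r - shell, 0.0) ** 2) | (lz >= h - shell))

    # pulp chamber: scaled crown cross-section over the lower 60% of the crown;
    # for multi-rooted teeth the chamber floor widens to cover the canal mouths
    ch_top = 0.6 * h
    ch_r = spec.pulp_scale * crown_r
    if spec.n_roots > 1:
        cover = np.abs(offsets).max() + spec.pulp_scale * spec.root_radius + 0.15
        floor_r = cover * np.clip(1.0 - (np.maximum(lz, 0.0) / ch_top) ** 2, 0.0, 1.0)
        ch_r = np.maximum(ch_r, floor_r)
    in_chamber = (lz >= 0) & (lz <= ch_top) & (r2 <= ch_r**2)

    # canals: one tapered cone per root, stopping short of the closed apex
    canal_len = rl if spec.open_apex else max(rl - 0.6, 0.5 * rl)
    tc = np.clip(-lz / canal_len, 0.0, 1.0)
    canal_r = spec.pulp_scale * spec.root_radius * (1.0 - 0.7 * tc)
    in_canals = np.zeros_like(in_chamber)
    canal_zone = (lz <= 0) & (lz >= -canal_len)
    for ox, oy in offsets:
        in_canals |= canal_zone & ((lx - ox) ** 2 + (ly - oy) ** 2 <= canal_r**2)

    pulp = in_chamber | in_canals
    if spec.open_apex:
        # carve a small apical opening connecting the canal to the exterior
        for ox, oy in offsets:
            near_apex = (lx - ox) ** 2 + (ly - oy) ** 2 + (lz + rl) ** 2 <= 0.5**2
            tooth &= ~near_apex
            pulp &= ~near_apex
    pulp &= tooth
    return tooth, pulp, in_enamel & ~pulp


def _render(shape, spacing, origin, paint_jobs, intensities, blur_sigma, noise_sd, seed):
    """Compose intensity volume from boolean paint layers, blur, add noise."""
    vol = np.full(shape, intensities.background, dtype=float)
    for mask, level in paint_jobs:
        vol[mask] = level
    if blur_sigma > 0:
        vol = ndi.gaussian_filter(vol, blur_sigma / np.asarray(spacing))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=shape)
    return ImageVolume(vol, spacing, origin)


def _grid(bounds_mm, voxel):
    """Regular grid covering an mm bounding box; returns origin, shape, coords."""
    lo = np.asarray([b[0] for b in bounds_mm], float)
    hi = np.asarray([b[1] for b in bounds_mm], float)
    shape = tuple(int(np.ceil((h - l) / voxel)) + 1 for l, h in zip(lo, hi))
    coords = [lo[a] + voxel * np.arange(shape[a]) for a in range(3)]
    return tuple(lo), shape, coords


def generate_tooth(spec=None):
    """Render a single tooth (crown up for mandibular classes, down for maxillary)."""
    spec = spec or PhantomSpec()
    m = 2.0
    r = spec.footprint_radius + m
    flip = spec.tooth_class.arch is ArchLabel.MAXILLARY
    z_lo, z_hi = -spec.root_length - m, spec.crown_height + m
    if flip:
        z_lo, z_hi = -z_hi, -z_lo
    origin, shape, (cx, cy, cz) = _grid(((-r, r), (-r, r), (z_lo, z_hi)), spec.voxel_size)
    lx = cx[:, None, None]
    ly = cy[None, :, None]
    lz = cz[None, None, :] * (-1.0 if flip else 1.0)
    tooth, pulp, enamel = _tooth_solids(spec, lx, ly, np.broadcast_to(lz, shape))

    roots = tooth & (np.broadcast_to(lz, shape) <= 0)
    bone = _bone_collar(roots, tooth, spec)
    inten = spec.intensities
    volume = _render(
        shape,
        (spec.voxel_size,) * 3,
        origin,
        [(bone, inten.bone), (tooth, inten.dentine), (enamel, inten.enamel), (pulp, inten.pulp)],
        inten,
        spec.blur_sigma,
        spec.noise_sd,
        spec.seed,
    )
    geom = dict(spacing=volume.spacing, origin=volume.origin)
    return PhantomCase(
        volume=volume,
        tooth_masks=[BinaryMask(tooth, **geom)],
        pulp_masks=[BinaryMask(pulp, **geom)],
        true_planes={},
        arch_labels=[spec.tooth_class.arch],
        specs=[spec],
    )


def _bone_collar(roots, teeth, spec):
    if spec.bone_thickness <= 0 or not roots.any():
        return np.zeros_like(roots)
    dist = ndi.distance_transform_edt(~roots, sampling=(spec.voxel_size,) * 3)
    return (dist <= spec.bone_thickness) & ~teeth


def generate_arch_scene(
    specs=None,
    arch_curve=(0.035, 0.3, 0.0),
    gap_mm=2.0,
    bite_gap_mm=3.0,
    seed=0,
    margin=2.0,
):
    """Render a two-arch open-bite scene with teeth along quadratic arch curves.

    ``specs`` maps each :class:`ArchLabel` to the list of tooth specs placed
    at equal crown-gap spacing along the arch; the maxillary arch sits above
    the mandibular one, separated by ``bite_gap_mm`` of background.  True
    separation planes are placed mid-gap, orthogonal to the curve.
    """
    if specs is None:
        specs = _default_scene_specs()
    if gap_mm <= 0 or bite_gap_mm <= 0:
        raise PlacementError("gap_mm and bite_gap_mm must be positive")
    a, b, c = (float(v) for v in arch_curve)
    voxel = specs[ArchLabel.MANDIBULAR][0].voxel_size

    # arc-length parameterization of the generating curve around x = 0
    xs = np.linspace(-80.0, 80.0, 8192)
    ys = a * xs**2 + b * xs + c
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xs), np.diff(ys)))])
    s -= np.interp(0.0, xs, s)

    def x_of_s(sv):
        return np.interp(sv, s, xs)

    placements = {}   # arch -> list of (spec, centre_xy, station)
    all_extents = []
    arch_z = {}
    mand = specs.get(ArchLabel.MANDIBULAR, [])
    maxi = specs.get(ArchLabel.MAXILLARY, [])
    mand_h = max((sp.total_height for sp in mand), default=0.0)
    z_bite_lo = margin + mand_h       # top of mandibular crowns
    z_bite_hi = z_bite_lo + bite_gap_mm
    for arch, arch_specs in ((ArchLabel.MANDIBULAR, mand), (ArchLabel.MAXILLARY, maxi)):
        if not arch_specs:
            continue
        radii = [sp.crown_radius for sp in arch_specs]
        stations = [0.0]
        for i in range(1, len(arch_specs)):
            stations.append(stations[-1] + radii[i - 1] + gap_mm + radii[i])
        stations = np.asarray(stations) - 0.5 * stations[-1]  # centre on x ~ 0
        xsc = x_of_s(stations)
        ysc = a * xsc**2 + b * xsc + c
        placements[arch] = list(zip(arch_specs, np.stack([xsc, ysc], axis=1), stations))
        if arch is ArchLabel.MANDIBULAR:
            cerv = z_bite_lo - max(sp.crown_height for sp in arch_specs)
            arch_z[arch] = cerv
        else:
            cerv = z_bite_hi + max(sp.crown_height for sp in arch_specs)
            arch_z[arch] = cerv
        for sp, (xc, yc), _ in placements[arch]:
            r = sp.footprint_radius
            if arch is ArchLabel.MANDIBULAR:
                zr = (cerv - sp.root_length, cerv + sp.crown_height)
            else:
                zr = (cerv - sp.crown_height, cerv + sp.root_length)
            all_extents.append(((xc - r, xc + r), (yc - r, yc + r), zr))

    if not all_extents:
        raise PlacementError("no teeth to place")
    bounds = tuple(
        (min(e[axis][0] for e in all_extents) - margin, max(e[axis][1] for e in all_extents) + margin)
        for axis in range(3)
    )
    origin, shape, (cx, cy, cz) = _grid(bounds, voxel)
    gx = cx[:, None, None]
    gy = cy[None, :, None]
    gz = cz[None, None, :]

    tooth_masks, pulp_masks, arch_labels, flat_specs = [], [], [], []
    paint_teeth = np.zeros(shape, bool)
    paint_enamel = np.zeros(shape, bool)
    paint_pulp = np.zeros(shape, bool)
    roots_all = np.zeros(shape, bool)
    geom = dict(spacing=(voxel,) * 3, origin=origin)
    for arch, placed in placements.items():
        cerv = arch_z[arch]
        sign = -1.0 if arch is ArchLabel.MAXILLARY else 1.0
        for sp, (xc, yc), _ in placed:
            lx = gx - xc
            ly = gy - yc
            lz = np.broadcast_to(sign * (gz - cerv), shape)
            tooth, pulp, enamel = _tooth_solids(sp, lx, ly, lz)
            tooth_masks.append(BinaryMask(tooth, **geom))
            pulp_masks.append(BinaryMask(pulp, **geom))
            arch_labels.append(arch)
            flat_specs.append(sp)
            paint_teeth |= tooth
            paint_enamel |= enamel
            paint_pulp |= pulp
            roots_all |= tooth & (lz <= 0)

    bone_spec = flat_specs[0]
    bone = _bone_collar(roots_all, paint_teeth, replace(bone_spec, seed=seed))
    inten = bone_spec.intensities
    noise_sd = bone_spec.noise_sd
    volume = _render(
        shape,
        (voxel,) * 3,
        origin,
        [
            (bone, inten.bone),
            (paint_teeth, inten.dentine),
            (paint_enamel, inten.enamel),
            (paint_pulp, inten.pulp),
        ],
        inten,
        bone_spec.blur_sigma,
        noise_sd,
        seed,
    )

    true_planes = {}
    true_curves = {}
    for arch, placed in placements.items():
        cerv = arch_z[arch]
        sign = -1.0 if arch is ArchLabel.MAXILLARY else 1.0
        zs = [cerv + sign * 0.5 * (sp.crown_height - sp.root_length) for sp, _, _ in placed]
        z_mid = float(np.mean(zs))
        planes = []
        for i in range(len(placed) - 1):
            sp_l, _, s_l = placed[i]
            sp_r, _, s_r = placed[i + 1]
            s_mid = 0.5 * ((s_l + sp_l.crown_radius) + (s_r - sp_r.crown_radius))
            xm = float(x_of_s(s_mid))
            ym = a * xm**2 + b * xm + c
            tx, ty = 1.0, 2 * a * xm + b
            nrm = np.hypot(tx, ty)
            planes.append(
                SeparationPlane(np.array([xm, ym, z_mid]), np.array([tx / nrm, ty / nrm, 0.0]))
            )
        true_planes[arch] = planes
        x_lo = float(min(p[1][0] for p in placed)) - placed[0][0].crown_radius
        x_hi = float(max(p[1][0] for p in placed)) + placed[-1][0].crown_radius
        true_curves[arch] = ArchCurve((a, b, c), (x_lo, x_hi), arch)

    return PhantomCase(
        volume=volume,
        tooth_masks=tooth_masks,
        pulp_masks=pulp_masks,
        true_planes=true_planes,
        arch_labels=arch_labels,
        specs=flat_specs,
        true_curves=true_curves,
        bite_gap_z=(z_bite_lo, z_bite_hi),
    )


def _default_scene_specs(noise_sd=20.0, voxel_size=0.25, seed=0):
    """4 + 4 single-rooted teeth: premolar, canine, incisor, incisor per arch."""

    def tooth(kind, arch, position):
        return PhantomSpec(
            tooth_class=ToothClass(kind, arch, position),
            crown_radius=2.5,
            noise_sd=noise_sd,
            voxel_size=voxel_size,
            seed=seed,
        )

    mand = [
        tooth(ToothKind.PREMOLAR, ArchLabel.MANDIBULAR, 44),
        tooth(ToothKind.CANINE, ArchLabel.MANDIBULAR, 43),
        tooth(ToothKind.INCISOR, ArchLabel.MANDIBULAR, 42),
        tooth(ToothKind.INCISOR, ArchLabel.MANDIBULAR, 41),
    ]
    maxi = [
        tooth(ToothKind.PREMOLAR, ArchLabel.MAXILLARY, 14),
        tooth(ToothKind.CANINE, ArchLabel.MAXILLARY, 13),
        tooth(ToothKind.INCISOR, ArchLabel.MAXILLARY, 12),
        tooth(ToothKind.INCISOR, ArchLabel.MAXILLARY, 11),
    ]
    return {ArchLabel.MANDIBULAR: mand, ArchLabel.MAXILLARY: maxi}


def default_scene(seed=0, noise_sd=20.0, voxel_size=0.25):
    """The reference 4+4-tooth open-bite study scene (0.25 mm voxels, 2% noise)."""
    return generate_arch_scene(
        specs=_default_scene_specs(noise_sd=noise_sd, voxel_size=voxel_size, seed=seed),
        seed=seed,
    )
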