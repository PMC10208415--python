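"""Full per-case orchestration: arches -> separation planes -> per-tooth pulp
-> tooth surface -> metrics.

Per-tooth failures (no pulp cavity, empty separation slab) are reported as
rejections, never abort the case; a closed-bite acquisition (no z-separated
arches) is a case-level error.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields

import numpy as np

from . import evaluation
from .arch_partition import (
    ArchLabel,
    OpenBiteError,
    classify_arch_voxels,
    extract_crown_seeds,
    fit_arch_curve,
    sagittal_mip,
)
from .pulp_segmentation import PulpSegParams, ToothClass, segment_pulp
from .tooth_segmentation import DeformationParams, deform, init_mesh, mesh_to_mask
from .tooth_separation import (
    PlaneCostParams,
    SeparationError,
    cost_profile,
    extract_voi,
    find_candidate_stations,
    plane_at_station,
    refine_plane,
)
from .volume_core import BinaryMask, NoCavityError, PulpSegError

logger = logging.getLogger("pulpseg")

__all__ = ["PipelineConfig", "ToothReport", "CaseReport", "segment_case"]


@dataclass
class PipelineConfig:
    """Configuration of the full segmentation pipeline.

    The pulp morphology defaults to whole-volume (3D) operation with an Otsu
    valley threshold, which is robust to acquisition noise; the per-slice
    variant remains available via ``pulp_mode="slice"``.
    """

    plane_params: PlaneCostParams = field(default_factory=PlaneCostParams)
    pulp_params: PulpSegParams = field(default_factory=PulpSegParams)
    deform_params: DeformationParams = field(default_factory=DeformationParams)
    mip_threshold: object = "auto"
    knn_k: int = 5
    profile_step: float = 0.25
    min_tooth_width: float = 4.0
    pulp_mode: str = "volume"
    tooth_classes: dict = field(default_factory=dict)  # (arch, voi index) -> ToothClass
    area_models: dict = field(default_factory=dict)    # ToothClass.key -> AreaEvolutionModel
    refine_planes: bool = True
    debug: bool = False

    _PARAM_TYPES = {"plane_params": PlaneCostParams, "pulp_params": PulpSegParams,
                    "deform_params": DeformationParams}

    @classmethod
    def from_dict(cls, data):
        """Build a config from a plain dict; unknown keys are rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            if key in cls._PARAM_TYPES and isinstance(value, dict):
                sub_cls = cls._PARAM_TYPES[key]
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(eq=False)
class ToothReport:
    arch: ArchLabel
    index: int
    status: str                   # 'ok' or 'rejected'
    reason: str = ""
    tooth_class: ToothClass = None
    planes: tuple = ()
    pulp_mask: BinaryMask = None  # full-grid geometry
    tooth_mask: BinaryMask = None
    mesh: object = None
    pulp_metrics: object = None
    tooth_metrics: object = None
    matched_reference: int = None

    def to_dict(self):
        out = {
            "arch": self.arch.value,
            "index": self.index,
            "status": self.status,
            "reason": self.reason,
        }
        if self.tooth_class is not None:
            out["tooth_class"] = {
                "kind": self.tooth_class.kind.value,
                "position": self.tooth_class.position,
            }
        for name in ("pulp_metrics", "tooth_metrics"):
            m = getattr(self, name)
            if m is not None:
                out[name] = {"dice": m.dice, "asd_mm": m.asd_mm, "mhd_mm": m.mhd_mm}
        if self.matched_reference is not None:
            out["matched_reference"] = self.matched_reference
        return out


@dataclass(eq=False)
class CaseReport:
    teeth: list
    arch_curves: dict
    planes: dict                  # ArchLabel -> [SeparationPlane] (interior, refined)
    seeds: object = None
    arch_voxel_labels: object = None

    @property
    def n_ok(self):
        return sum(1 for t in self.teeth if t.status == "ok")

    @property
    def n_rejected(self):
        return sum(1 for t in self.teeth if t.status == "rejected")

    def to_dict(self):
        return {
            "n_teeth": len(self.teeth),
            "n_ok": self.n_ok,
            "n_rejected": self.n_rejected,
            "planes_per_arch": {a.value: len(p) for a, p in self.planes.items()},
            "teeth": [t.to_dict() for t in self.teeth],
        }


def _embed_mask(sub, full_geometry, offset_idx):
    """Paste a sub-grid mask into an empty full-grid mask at an index offset."""
    out = np.zeros(full_geometry.shape, dtype=bool)
    x0, y0, z0 = offset_idx
    sx, sy, sz = sub.shape
    out[x0 : x0 + sx, y0 : y0 + sy, z0 : z0 + sz] = sub.values
    return BinaryMask(out, full_geometry.spacing, full_geometry.origin)


def segment_case(volume, config=None, references=None):
    """Run the full pipeline on a CBCT volume.

    ``references`` is an optional list of (tooth_mask, pulp_mask, ToothClass)
    ground-truth triples on the same grid; when given, each segmented tooth
    is matched to the reference whose tooth-mask centroid falls inside the
    tooth's VOI slab and Dice/ASD/MHD metrics are attached to the report.
    """
    config = config or PipelineConfig()
    t0 = time.time()

    mip = sagittal_mip(volume)
    seeds = extract_crown_seeds(mip, config.mip_threshold)
    logger.info("crown seeds: threshold=%.1f z-gap=%s", seeds.threshold, seeds.z_gap)

    sy, sz = volume.spacing[1], volume.spacing[2]
    oy, oz = volume.origin[1], volume.origin[2]
    seeds_mm = {
        lab: np.column_stack([oy + pts[:, 0] * sy, oz + pts[:, 1] * sz])
        for lab, pts in seeds.as_dict().items()
    }

    hard = volume.values > seeds.threshold
    hard_idx = np.argwhere(hard)
    q_mm = np.column_stack([oy + hard_idx[:, 1] * sy, oz + hard_idx[:, 2] * sz])
    labels = classify_arch_voxels(seeds_mm, q_mm, k=config.knn_k)

    ref_centroids = None
    if references:
        ref_centroids = []
        for tooth_mask, _, _ in references:
            idx = np.argwhere(tooth_mask.values)
            ref_centroids.append(np.asarray(tooth_mask.origin) + idx.mean(axis=0) * np.asarray(tooth_mask.spacing))

    teeth = []
    curves = {}
    planes_out = {}
    for arch in (ArchLabel.MANDIBULAR, ArchLabel.MAXILLARY):
        sel = labels == arch
        if not sel.any():
            continue
        vox = hard_idx[sel]
        z_lo = max(0, int(vox[:, 2].min()) - int(np.ceil(1.0 / volume.spacing[2])))
        z_hi = min(volume.shape[2], int(vox[:, 2].max()) + 1 + int(np.ceil(1.0 / volume.spacing[2])))
        arch_vol = volume.crop(((0, volume.shape[0]), (0, volume.shape[1]), (z_lo, z_hi)))

        # weighted axial projection of this arch's hard-tissue voxels
        w2d = np.zeros(volume.shape[:2])
        np.add.at(w2d, (vox[:, 0], vox[:, 1]), volume.values[vox[:, 0], vox[:, 1], vox[:, 2]])
        xi, yi = np.nonzero(w2d)
        pts = np.column_stack(
            [
                volume.origin[0] + xi * volume.spacing[0],
                oy + yi * sy,
                w2d[xi, yi],
            ]
        )
        curve = fit_arch_curve(pts, arch)
        curves[arch] = curve

        z_center = float(oz + 0.5 * (vox[:, 2].min() + vox[:, 2].max()) * sz)
        profile = cost_profile(arch_vol, curve, config.plane_params, config.profile_step, z_center)
        stations = find_candidate_stations(profile, config.min_tooth_width)
        logger.info("%s: %d candidate separation stations", arch.value, len(stations))
        refined = []
        for s in stations:
            if config.refine_planes:
                refined.append(refine_plane(arch_vol, curve, s, config.plane_params, z_center))
            else:
                refined.append(plane_at_station(curve, s, z_center))
        planes_out[arch] = refined

        if len(stations) >= 2:
            pitch = float(np.median(np.diff(stations)))
        else:
            pitch = 1.5 * config.min_tooth_width
        s_first = (stations[0] if len(stations) else 0.5 * curve.length) - pitch
        s_last = (stations[-1] if len(stations) else 0.5 * curve.length) + pitch
        boundaries = [plane_at_station(curve, s_first, z_center)] + refined + [
            plane_at_station(curve, s_last, z_center)
        ]

        for i in range(len(boundaries) - 1):
            left = boundaries[i].flipped()   # normals point away from the tooth
            right = boundaries[i + 1]
            report = ToothReport(arch=arch, index=i, status="ok", planes=(left, right))
            report.tooth_class = config.tooth_classes.get((arch, i))
            try:
                voi = extract_voi(arch_vol, left, right, arch)
            except SeparationError as exc:
                report.status, report.reason = "rejected", f"empty-slab: {exc}"
                teeth.append(report)
                continue
            model = None
            if report.tooth_class is not None:
                model = config.area_models.get(report.tooth_class.key)
            try:
                pulp = segment_pulp(
                    voi, config.pulp_params, report.tooth_class, model, mode=config.pulp_mode
                )
            except NoCavityError as exc:
                report.status, report.reason = "rejected", f"no-cavity: {exc}"
                teeth.append(report)
                continue
            try:
                mesh0 = init_mesh(pulp)
                mesh = deform(arch_vol, mesh0, (left, right), config.deform_params)
                tooth_sub = mesh_to_mask(mesh, voi.volume)
            except PulpSegError as exc:
                report.status, report.reason = "rejected", f"deformation: {exc}"
                teeth.append(report)
                continue
            off = (voi.bounds[0][0], voi.bounds[1][0], voi.bounds[2][0] + z_lo)
            pulp_sub_vals = BinaryMask(pulp.values, pulp.spacing, pulp.origin)
            report.pulp_mask = _embed_mask(pulp_sub_vals, volume, off)
            report.tooth_mask = _embed_mask(tooth_sub, volume, off)
            report.mesh = mesh
            if references:
                report.matched_reference = _match_reference(
                    ref_centroids, references, arch, left, right
                )
                if report.matched_reference is not None:
                    ref_tooth, ref_pulp, ref_class = references[report.matched_reference]
                    if report.tooth_class is None:
                        report.tooth_class = ref_class
                    try:
                        report.pulp_metrics = evaluation.evaluate_pair(report.pulp_mask, ref_pulp)
                        report.tooth_metrics = evaluation.evaluate_pair(report.tooth_mask, ref_tooth)
                    except ValueError as exc:
                        report.status, report.reason = "rejected", f"evaluation: {exc}"
            teeth.append(report)

    logger.info(
        "case done in %.1fs: %d ok, %d rejected",
        time.time() - t0,
        sum(t.status == "ok" for t in teeth),
        sum(t.status == "rejected" for t in teeth),
    )
    return CaseReport(teeth=teeth, arch_curves=curves, planes=planes_out, seeds=seeds,
                      arch_voxel_labels=(hard_idx, labels))


def _match_reference(ref_centroids, references, arch, left, right):
    best = None
    for j, cen in enumerate(ref_centroids):
        ref_class = references[j][2]
        if ref_class is not None and ref_class.arch is not arch:
            continue
        if left.signed(cen[None, :])[0] <= 0 and right.signed(cen[None, :])[0] <= 0:
            if best is None:
                best = j
            else:  # ambiguous: prefer the centroid deepest inside the slab
                depth_j = -max(left.signed(cen[None, :])[0], right.signed(cen[None, :])[0])
                cb = ref_centroids[best]
                depth_b = -max(left.signed(cb[None, :])[0], right.signed(cb[None, :])[0])
                if depth_j > depth_b:
                    best = j
    return best
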