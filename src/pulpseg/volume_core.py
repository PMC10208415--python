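"""Core raster and mesh containers plus readers/writers for the formats the
pipeline touches.

The package works on 3D grayscale volumes (CBCT-like scans) stored as an
``ImageVolume``: a scalar grid with physical voxel spacing and an origin, all
in millimetres.  Axis convention throughout: x = left-right, y =
anterior-posterior, z = inferior-superior; an "axial slice" is a constant-z
plane and a "sagittal projection" collapses the x axis.  Segmentations are
``BinaryMask`` grids sharing a volume's geometry, and deformable tooth models
are triangulated ``SurfaceMesh`` objects in physical coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

logger = logging.getLogger("pulpseg")

__all__ = [
    "PulpSegError",
    "FormatError",
    "GeometryError",
    "DomainError",
    "MeshError",
    "NoCavityError",
    "ImageVolume",
    "BinaryMask",
    "SurfaceMesh",
    "VolumeOfInterest",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "write_mesh",
    "read_mesh",
]


class PulpSegError(Exception):
    """Base class for all pulpseg errors."""


class FormatError(PulpSegError):
    """A file could not be parsed as the named format."""


class GeometryError(PulpSegError):
    """Inconsistent or invalid grid geometry."""


class DomainError(PulpSegError):
    """A geometric query falls entirely outside the volume."""


class MeshError(PulpSegError):
    """Invalid or degenerate surface mesh."""


class NoCavityError(PulpSegError):
    """The image contains no enclosed dark cavity (no pulp evidence)."""


def _as_tuple3(x, name):
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise GeometryError(f"{name} must have 3 components, got {len(t)}")
    return t


@dataclass(eq=False)
class ImageVolume:
    """3D scalar grid with physical spacing and origin (mm).

    ``values[ix, iy, iz]`` is the intensity at physical position
    ``origin + (ix, iy, iz) * spacing``.  Voxel indices are 0-based.
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise GeometryError(f"volume must be 3D, got shape {v.shape}")
        if v.size == 0:
            raise GeometryError("volume must be non-empty")
        if not np.all(np.isfinite(v)):
            raise GeometryError("volume values must all be finite")
        self.values = v
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin, "origin")
        self._gradient = None
        self._range = None

    @property
    def shape(self):
        return self.values.shape

    @property
    def intensity_range(self):
        if self._range is None:
            self._range = (float(self.values.min()), float(self.values.max()))
        return self._range

    def axis_coords(self, axis):
        """Physical coordinates of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def mm_to_index(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_mm(self, idx):
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def interpolate(self, points):
        """Trilinear interpolation at physical points.

        Returns ``(values, inside)``; samples outside the voxel-centre hull
        are flagged and contribute zero.
        """
        idx = self.mm_to_index(points)
        upper = np.asarray(self.shape, dtype=float) - 1.0
        inside = np.all((idx >= 0.0) & (idx <= upper), axis=1)
        vals = map_coordinates(self.values, idx.T, order=1, mode="constant", cval=0.0)
        vals = np.where(inside, vals, 0.0)
        return vals, inside

    @property
    def gradient(self):
        """Central-difference gradient field in intensity per mm, shape (3, nx, ny, nz).

        One-sided differences are used at grid borders.
        """
        if self._gradient is None:
            axes_ok = [a for a in range(3) if self.shape[a] > 1]
            g = [np.zeros_like(self.values) for _ in range(3)]
            if axes_ok:
                grads = np.gradient(
                    self.values, *[self.spacing[a] for a in axes_ok], axis=tuple(axes_ok)
                )
                if len(axes_ok) == 1:
                    grads = [grads]
                for a, ga in zip(axes_ok, grads):
                    g[a] = ga
            self._gradient = np.stack(g)
        return self._gradient

    def interpolate_gradient(self, points):
        """Trilinear interpolation of the gradient field; zero outside."""
        idx = self.mm_to_index(points)
        upper = np.asarray(self.shape, dtype=float) - 1.0
        inside = np.all((idx >= 0.0) & (idx <= upper), axis=1)
        g = self.gradient
        out = np.stack(
            [
                map_coordinates(g[a], idx.T, order=1, mode="constant", cval=0.0)
                for a in range(3)
            ],
            axis=1,
        )
        out[~inside] = 0.0
        return out, inside

    def crop(self, bounds):
        """Sub-volume over a half-open 0-based index box ((x0,x1),(y0,y1),(z0,z1))."""
        (x0, x1), (y0, y1), (z0, z1) = bounds
        if not (0 <= x0 < x1 <= self.shape[0] and 0 <= y0 < y1 <= self.shape[1] and 0 <= z0 < z1 <= self.shape[2]):
            raise GeometryError(f"crop bounds {bounds} outside grid {self.shape}")
        new_origin = (
            self.origin[0] + x0 * self.spacing[0],
            self.origin[1] + y0 * self.spacing[1],
            self.origin[2] + z0 * self.spacing[2],
        )
        return ImageVolume(self.values[x0:x1, y0:y1, z0:z1].copy(), self.spacing, new_origin)


@dataclass(eq=False)
class BinaryMask:
    """Boolean grid sharing an :class:`ImageVolume`'s geometry."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.dtype != bool:
            v = v.astype(bool)
        if v.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {v.shape}")
        self.values = v
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin, "origin")

    @property
    def shape(self):
        return self.values.shape

    @classmethod
    def like(cls, geometry, values=None):
        """Empty (or given) mask with the geometry of a volume or mask."""
        if values is None:
            values = np.zeros(geometry.shape, dtype=bool)
        return cls(values, geometry.spacing, geometry.origin)

    def same_geometry(self, other, tol=1e-9):
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def voxel_volume(self):
        return float(np.prod(self.spacing))

    def count(self):
        return int(self.values.sum())


def _vertex_normals(vertices, faces):
    """Area-weighted per-vertex normals, unit length."""
    v = vertices
    f = faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[:, k], fn)
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    return normals / norms[:, None]


@dataclass(eq=False)
class SurfaceMesh:
    """Triangulated surface in physical (mm) coordinates with outward normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face indices out of range")
        self.vertices = v
        self.faces = f
        if self.normals is None:
            self.normals = _vertex_normals(v, f) if len(v) else np.zeros((0, 3))
        else:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != len(v):
                raise MeshError("one normal per vertex required")

    def __len__(self):
        return len(self.vertices)

    def recompute_normals(self):
        self.normals = _vertex_normals(self.vertices, self.faces)
        return self.normals

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm):
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))

    def is_closed(self):
        """True when every edge is shared by exactly two faces."""
        if len(self.faces) == 0:
            return False
        return bool(self.to_trimesh().is_watertight)

    def area(self):
        v, f = self.vertices, self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return float(0.5 * np.linalg.norm(cr, axis=1).sum())

    def copy(self):
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.normals.copy())


@dataclass(eq=False)
class VolumeOfInterest:
    """Single-tooth sub-volume bounded by two separation planes.

    ``bounds`` is a half-open 0-based index box in the parent grid; ``volume``
    is the cropped copy in which voxels outside either side plane are masked
    to the parent's minimum intensity.
    """

    parent: ImageVolume
    bounds: tuple
    side_planes: tuple
    volume: ImageVolume

    def __post_init__(self):
        (x0, x1), (y0, y1), (z0, z1) = self.bounds
        px, py, pz = self.parent.shape
        if not (0 <= x0 < x1 <= px and 0 <= y0 < y1 <= py and 0 <= z0 < z1 <= pz):
            raise GeometryError(f"VOI bounds {self.bounds} outside parent grid")


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_RASTER_FORMATS = ("dicom-series", "nifti", "nrrd")


def _infer_raster_format(path):
    p = Path(path)
    if p.is_dir():
        return "dicom-series"
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise FormatError(f"cannot infer raster format of {path}")


def _read_dicom_series(path):
    import pydicom

    p = Path(path)
    files = sorted(f for f in p.iterdir() if f.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM slices under {path}")
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
        px = [float(v) for v in slices[0].PixelSpacing]
    except Exception as exc:  # missing geometry tags
        raise FormatError(f"DICOM series lacks geometry tags: {exc}") from exc
    if len(slices) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise GeometryError("duplicate DICOM slice positions")
        if (dz.max() - dz.min()) > 1e-3 * dz.mean() + 1e-6:
            raise GeometryError("inconsistent DICOM slice spacing beyond tolerance")
        step = float(dz.mean())
    else:
        step = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        inter = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(arr * slope + inter)
    # pixel_array is (rows=y, cols=x); volume axes are (x, y, z)
    vol = np.stack([pl.T for pl in planes], axis=-1)
    ipp = [float(v) for v in slices[0].ImagePositionPatient]
    spacing = (px[1], px[0], step)
    return ImageVolume(vol, spacing, (ipp[0], ipp[1], zs[0]))


def _read_nifti(path):
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise GeometryError(f"expected 3D NIfTI, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data, zooms, origin)


def _read_nrrd(path):
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NRRD {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise GeometryError(f"expected 3D NRRD, got shape {arr.shape}")
    return ImageVolume(
        arr.astype(float).transpose(2, 1, 0),
        tuple(float(s) for s in img.GetSpacing()),
        tuple(float(o) for o in img.GetOrigin()),
    )


def read_volume(path, format=None):
    """Read a 3D grayscale volume from a DICOM series directory, NIfTI or NRRD."""
    fmt = format or _infer_raster_format(path)
    if fmt not in _RASTER_FORMATS:
        raise FormatError(f"unsupported raster format {fmt!r}")
    if not Path(path).exists():
        raise FormatError(f"no such path: {path}")
    if fmt == "dicom-series":
        return _read_dicom_series(path)
    if fmt == "nifti":
        return _read_nifti(path)
    return _read_nrrd(path)


def write_volume(volume, path, format=None):
    """Write an :class:`ImageVolume` to NIfTI or NRRD."""
    fmt = format or _infer_raster_format_for_write(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.values.transpose(2, 1, 0))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported write format {fmt!r}")


def _infer_raster_format_for_write(path):
    name = Path(path).name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise FormatError(f"cannot infer raster format of {path}")


def write_mask(mask, path, format=None):
    """Write a :class:`BinaryMask` as a 0/1 integer raster (NIfTI or NRRD)."""
    fmt = format or _infer_raster_format_for_write(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(mask.spacing) + [1.0])
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(mask.values.astype(np.uint8).transpose(2, 1, 0))
        img.SetSpacing(mask.spacing)
        img.SetOrigin(mask.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported write format {fmt!r}")


def read_mask(path, format=None):
    vol = read_volume(path, format)
    return BinaryMask(vol.values > 0.5, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------


def write_mesh(mesh, path, format=None):
    """Write a :class:`SurfaceMesh` as binary STL or ascii PLY.

    An open (non-watertight) mesh is written with a warning; an empty mesh is
    an error.
    """
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise MeshError("cannot write an empty mesh")
    fmt = format
    if fmt is None:
        suffix = Path(path).suffix.lower().lstrip(".")
        fmt = suffix or "stl"
    if fmt not in ("stl", "ply"):
        raise FormatError(f"unsupported mesh format {fmt!r}")
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        warnings.warn("writing an open (non-watertight) mesh", stacklevel=2)
    if fmt == "stl":
        tm.export(str(path), file_type="stl")
    else:
        data = tm.export(file_type="ply", encoding="ascii")
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)


def read_mesh(path):
    import trimesh

    tm = trimesh.load(str(path), force="mesh")
    return SurfaceMesh.from_trimesh(tm)
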