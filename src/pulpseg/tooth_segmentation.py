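"""Tooth segmentation by pulp-initialized hierarchical surface deformation.

The pulp shares the morphological outline of its tooth, so its segmentation
is a natural pre-personalized initialization: a closed triangle mesh of the
pulp surface is deformed outward, each vertex searching an intensity profile
along its normal for the bright-to-dark transition marking the tooth
boundary.  The search half-length L shrinks geometrically per iteration
(coarse-to-fine), profile points crossing a tooth separation plane are
excluded so crowded neighbours cannot capture vertices, and a Laplacian
smoothing step keeps the surface coherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix

from .volume_core import BinaryMask, MeshError, PulpSegError, SurfaceMesh

__all__ = [
    "DeformationParams",
    "IntensityProfile",
    "DeformationError",
    "init_mesh",
    "sample_profile",
    "filter_plane_crossing",
    "find_boundary",
    "deform",
    "mesh_to_mask",
]


class DeformationError(PulpSegError):
    """Surface deformation failed (degenerate mesh)."""


@dataclass
class DeformationParams:
    """Parameters of the iterative surface deformation.

    initial_profile_halflength  L0 in mm
    shrink_factor               multiplicative reduction of L per iteration
    n_iterations                maximum iteration count
    samples_per_profile         odd sample count along [-L, +L]
    gaussian_sigma              mm, width of the distance prior in the boundary cost
    step_fraction               fraction of the target offset applied per iteration
    smooth_lambda               per-iteration Laplacian smoothing weight
    convergence_tol             mm, stop when mean displacement falls below
    """

    initial_profile_halflength: float = 4.0
    shrink_factor: float = 0.8
    n_iterations: int = 15
    samples_per_profile: int = 41
    gaussian_sigma: float = 1.0
    step_fraction: float = 0.5
    smooth_lambda: float = 0.3
    convergence_tol: float = 0.01

    def __post_init__(self):
        if not 0 < self.shrink_factor < 1:
            raise ValueError("shrink_factor must be in (0, 1)")
        if self.initial_profile_halflength <= 0:
            raise ValueError("initial_profile_halflength must be positive")
        if self.samples_per_profile < 3 or self.samples_per_profile % 2 == 0:
            raise ValueError("samples_per_profile must be odd and >= 3")


@dataclass(eq=False)
class IntensityProfile:
    """Intensities sampled along a vertex normal over offsets u in [-L, +L]."""

    offsets: np.ndarray
    values: np.ndarray
    points: np.ndarray
    admissible: np.ndarray

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, float)
        self.values = np.asarray(self.values, float)
        self.points = np.asarray(self.points, float)
        self.admissible = np.asarray(self.admissible, bool)
        n = self.offsets.size
        if not (self.values.size == n and len(self.points) == n and self.admissible.size == n):
            raise ValueError("profile arrays must have equal length")


def init_mesh(pulp):
    """Closed triangulated isosurface of the pulp mask (the deformable model).

    The mask is dilated by one voxel (clearing the cavity wall) and meshed at
    iso-level 0.5 with marching cubes; normals are oriented outward.
    """
    if isinstance(pulp, BinaryMask):
        values, spacing, origin = pulp.values, pulp.spacing, pulp.origin
    else:
        values = np.asarray(pulp, bool)
        spacing, origin = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
    if not values.any():
        raise MeshError("cannot mesh an empty mask")
    grown = ndi.binary_dilation(values, structure=np.ones((3, 3, 3), bool))
    padded = np.pad(grown, 1).astype(float)
    from skimage.measure import marching_cubes

    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts + np.asarray(origin) - np.asarray(spacing)  # undo the 1-voxel pad
    import trimesh

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.fix_normals()
    mesh = SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    # marching cubes of a padded binary volume is watertight by construction;
    # orient normals outward (positive mean signed offset from the centroid)
    centroid = mesh.vertices.mean(axis=0)
    if np.mean(np.einsum("ij,ij->i", mesh.normals, mesh.vertices - centroid)) < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1].copy())
    return mesh


def sample_profile(volume, vertex, normal, L, n):
    """Sample n equispaced intensities along vertex + u * normal, u in [-L, L].

    Values are trilinearly interpolated; samples outside the grid are marked
    inadmissible (and read as zero).
    """
    normal = np.asarray(normal, float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise ValueError("normal must have unit length")
    u = np.linspace(-L, L, n)
    pts = np.asarray(vertex, float) + u[:, None] * normal
    vals, inside = volume.interpolate(pts)
    return IntensityProfile(u, vals, pts, inside)


def filter_plane_crossing(profile, planes):
    """Mark samples on the excluded side of any separation plane inadmissible.

    A sample point M is excluded when a'*Mx + b'*My + c'*Mz - d' > 0 for any
    plane; all other samples are untouched.
    """
    adm = profile.admissible.copy()
    for plane in planes:
        adm &= plane.signed(profile.points) <= 0
    return IntensityProfile(profile.offsets, profile.values, profile.points, adm)


def find_boundary(profile, params=None):
    """Target offset g_i: argmax of the gradient-and-Gaussian boundary cost.

    The score is D(u) * exp(-u^2 / (2 sigma^2)) with D(u) = -dI/du, so an
    outward bright-to-dark transition scores positive and nearer transitions
    are preferred.  Returns ``None`` when fewer than 3 samples are admissible
    or no admissible sample scores positive (the vertex holds position).
    """
    params = params or DeformationParams()
    adm = profile.admissible
    if adm.sum() < 3:
        return None
    d = -np.gradient(profile.values, profile.offsets)
    # a sample whose gradient stencil touches an inadmissible neighbour would
    # carry a spurious transition (e.g. the zero padding outside the volume)
    core = adm.copy()
    core[1:] &= adm[:-1]
    core[:-1] &= adm[1:]
    score = d * np.exp(-(profile.offsets**2) / (2.0 * params.gaussian_sigma**2))
    score = np.where(core, score, -np.inf)
    i = int(np.argmax(score))
    # positivity up to interpolation round-off on the intensity scale
    du = profile.offsets[1] - profile.offsets[0] if profile.offsets.size > 1 else 1.0
    tol = 1e-9 * np.abs(profile.values).max() / max(du, 1e-12)
    if score[i] <= tol:
        return None
    return float(profile.offsets[i])


def _adjacency(n_vertices, faces):
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.concatenate([edges, edges[:, ::-1]])
    a = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n_vertices, n_vertices)
    ).tocsr()
    a.data[:] = 1.0  # collapse duplicates
    deg = np.asarray(a.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return a, deg


def deform(volume, mesh, planes=(), params=None):
    """Iteratively deform the pulp-initialized mesh to the tooth boundary.

    Per iteration: recompute vertex normals; sample a profile of half-length
    L per vertex; exclude plane-crossing samples; move each vertex by
    ``step_fraction * g_i`` along its normal (vertices without boundary
    evidence hold position); Laplacian-smooth; shrink L.  Stops after
    ``n_iterations`` or when the mean displacement falls below
    ``convergence_tol``.  The returned mesh has no vertex on the excluded
    side of any supplied plane.
    """
    params = params or DeformationParams()
    verts = mesh.vertices.copy()
    faces = mesh.faces
    adj, deg = _adjacency(len(verts), faces)
    L = params.initial_profile_halflength
    n = params.samples_per_profile
    gauss_sigma2 = 2.0 * params.gaussian_sigma**2
    plane_list = list(planes)
    for _ in range(params.n_iterations):
        normals = SurfaceMesh(verts, faces).normals
        u = np.linspace(-L, L, n)
        pts = verts[:, None, :] + u[None, :, None] * normals[:, None, :]
        flat = pts.reshape(-1, 3)
        vals, inside = volume.interpolate(flat)
        vals = vals.reshape(len(verts), n)
        adm = inside.reshape(len(verts), n)
        for plane in plane_list:
            adm &= (plane.signed(flat) <= 0).reshape(len(verts), n)
        d = -np.gradient(vals, u, axis=1)
        core = adm.copy()  # exclude samples with inadmissible gradient stencils
        core[:, 1:] &= adm[:, :-1]
        core[:, :-1] &= adm[:, 1:]
        score = d * np.exp(-(u**2) / gauss_sigma2)[None, :]
        score = np.where(core, score, -np.inf)
        best = np.argmax(score, axis=1)
        best_score = score[np.arange(len(verts)), best]
        du = u[1] - u[0] if n > 1 else 1.0
        tol = 1e-9 * np.abs(vals).max() / max(du, 1e-12)
        ok = (adm.sum(axis=1) >= 3) & (best_score > tol)
        g = np.where(ok, u[best], 0.0)
        disp = params.step_fraction * g
        verts = verts + disp[:, None] * normals
        if not np.all(np.isfinite(verts)):
            raise DeformationError("deformation produced non-finite vertices")
        if float(np.mean(np.abs(disp))) < params.convergence_tol:
            break
        if params.smooth_lambda > 0:
            mean_nb = adj.dot(verts) / deg[:, None]
            verts = verts + params.smooth_lambda * (mean_nb - verts)
        L *= params.shrink_factor
    for plane in plane_list:  # hard constraint: project violators onto the plane
        s = plane.signed(verts)
        bad = s > 0
        if bad.any():
            verts[bad] -= s[bad, None] * plane.normal
    return SurfaceMesh(verts, faces)


def mesh_to_mask(mesh, geometry):
    """Voxelize a closed mesh on a volume's grid by z-ray parity counting.

    A voxel is set when its centre lies inside the mesh (odd number of
    surface crossings below it along z).
    """
    if not mesh.is_closed():
        raise MeshError("mesh_to_mask requires a closed mesh")
    nx, ny, nz = geometry.shape
    sp = np.asarray(geometry.spacing)
    org = np.asarray(geometry.origin)
    v = (mesh.vertices - org) / sp  # continuous voxel-index coordinates
    f = mesh.faces
    # deterministic sub-voxel offset avoids rays hitting edges/vertices exactly
    eps = 1e-6
    tri = v[f]  # (F, 3, 3)
    toggles_col = []
    toggles_k = []
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        ix_lo = max(0, int(np.ceil(min(x0, x1, x2) - eps)))
        ix_hi = min(nx - 1, int(np.floor(max(x0, x1, x2) + eps)))
        iy_lo = max(0, int(np.ceil(min(y0, y1, y2) - eps)))
        iy_hi = min(ny - 1, int(np.floor(max(y0, y1, y2) + eps)))
        if ix_hi < ix_lo or iy_hi < iy_lo:
            continue
        gx = np.arange(ix_lo, ix_hi + 1) + eps
        gy = np.arange(iy_lo, iy_hi + 1) + eps * 0.5
        px, py = np.meshgrid(gx, gy, indexing="ij")
        d = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(d) < 1e-12:
            continue  # triangle vertical in z: no z-ray crossing area
        w1 = ((px - x0) * (y2 - y0) - (x2 - x0) * (py - y0)) / d
        w2 = ((x1 - x0) * (py - y0) - (px - x0) * (y1 - y0)) / d
        w0 = 1.0 - w1 - w2
        hit = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not hit.any():
            continue
        zc = w0 * z0 + w1 * z1 + w2 * z2
        ii, jj = np.nonzero(hit)
        cols = (ii + ix_lo) * ny + (jj + iy_lo)
        ks = np.floor(zc[hit]).astype(int) + 1  # first voxel centre above the crossing
        keep = ks < nz
        ks = np.clip(ks[keep], 0, nz - 1)
        toggles_col.append(cols[keep])
        toggles_k.append(ks)
    out = np.zeros((nx * ny, nz), dtype=np.int64)
    if toggles_col:
        np.add.at(out, (np.concatenate(toggles_col), np.concatenate(toggles_k)), 1)
    inside = (np.cumsum(out, axis=1) % 2).astype(bool).reshape(nx, ny, nz)
    return BinaryMask(inside, geometry.spacing, geometry.origin)
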