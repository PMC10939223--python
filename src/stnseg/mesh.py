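"""Corresponded surface meshes of subcortical nuclei and their primitives.

Meshes are generated by shrinking a subdivided-icosahedron seed sphere onto a
binary label: each vertex marches from the sphere toward the label's centre of
mass until the trilinearly interpolated label value reaches 0.5, followed by
Laplacian smoothing.  Because every subject uses the same seed sphere, vertex
indices correspond across subjects, which is what makes vertex-wise statistics
and eigenshape models possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage

from . import geometry
from .volume import LabelVolume, VoxelVolume

DEFAULT_SUBDIVISIONS = 3
PROFILE_OFFSETS_MM = np.arange(-3.0, 3.5, 1.0)  # 7 samples over +-3 mm


@dataclass
class SurfaceMesh:
    """Triangle mesh in world mm with corresponded vertex indexing."""

    vertices: np.ndarray
    faces: np.ndarray
    structure: str | None = None
    subdivisions: int | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        return replace(self, vertices=np.asarray(vertices, dtype=float))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def is_closed(self) -> bool:
        return self.to_trimesh().is_watertight


@dataclass
class IntensityProfileSet:
    """Per-vertex intensity profiles along outward vertex normals."""

    values: np.ndarray  # (N, 7), structure-mean-subtracted
    offsets: np.ndarray  # (7,) signed mm


def seed_sphere(center: np.ndarray, radius_mm: float, subdivisions: int = DEFAULT_SUBDIVISIONS) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(
        vertices=np.asarray(ico.vertices) + np.asarray(center, dtype=float),
        faces=np.asarray(ico.faces),
        subdivisions=subdivisions,
    )


def center_of_mass(label: LabelVolume) -> np.ndarray:
    """Mean voxel index of the nonzero voxels, one value per axis."""
    idx = np.argwhere(label.data > 0)
    if len(idx) == 0:
        raise ValueError("empty label")
    return idx.mean(axis=0)


def laplacian_smooth(mesh: SurfaceMesh, iterations: int = 5) -> SurfaceMesh:
    """Replace each vertex by the mean of its 1-ring neighbours, repeatedly."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    n = mesh.n_vertices
    # adjacency as a row-normalized sparse averaging operator
    edges = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    from scipy.sparse import coo_matrix

    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    adj = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    verts = mesh.vertices.copy()
    for _ in range(iterations):
        verts = adj @ verts / deg[:, None]
    return mesh.with_vertices(verts)


def shrink_wrap(
    label: LabelVolume,
    subdivisions: int = DEFAULT_SUBDIVISIONS,
    radius_mm: float | None = None,
    step_mm: float = 0.1,
    smooth_iterations: int = 5,
    max_flagged_fraction: float = 0.01,
) -> SurfaceMesh:
    """Fit a corresponded mesh to a binary label by sphere shrinkage.

    Every seed vertex moves along its ray toward the label centre of mass to
    the first location where the trilinear label value reaches 0.5 (linearly
    refined at the crossing).  Each Laplacian smoothing pass that follows
    evens out the vertex distribution and is itself followed by reprojection
    onto the 0.5 level set along the vertex's centre ray, so smoothing acts
    tangentially without eroding the boundary.  Vertex count and connectivity
    depend only on ``subdivisions``, giving point correspondence across
    subjects.
    """
    com_vox = center_of_mass(label)
    center = label.voxel_to_world(com_vox)[0]
    if radius_mm is None:
        idx = np.argwhere(label.data > 0)
        pts = label.voxel_to_world(idx)
        radius_mm = float(np.linalg.norm(pts - center, axis=1).max()) + 2.0 * label.spacing.max()
    sphere = seed_sphere(center, radius_mm, subdivisions)

    dirs = sphere.vertices - center[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    r_cross, flagged = _project_to_boundary(label, center, dirs, radius_mm, step_mm)
    if flagged.mean() > max_flagged_fraction:
        raise ValueError(
            f"{int(flagged.sum())} of {len(flagged)} vertices never reached the 0.5 level set"
        )

    mesh = SurfaceMesh(
        vertices=center[None, :] + r_cross[:, None] * dirs,
        faces=sphere.faces,
        structure=label.structure,
        subdivisions=subdivisions,
    )
    for _ in range(smooth_iterations):
        mesh = laplacian_smooth(mesh, 1)
        dirs = mesh.vertices - center[None, :]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        r_cross, _ = _project_to_boundary(label, center, dirs, radius_mm, step_mm)
        mesh = mesh.with_vertices(center[None, :] + r_cross[:, None] * dirs)
    return mesh


def _project_to_boundary(
    label: LabelVolume,
    center: np.ndarray,
    directions: np.ndarray,
    radius_mm: float,
    step_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """March inward along unit rays from radius ``radius_mm`` toward ``center``
    to the first trilinear 0.5 crossing; returns radii and never-crossed flags."""
    n_steps = int(np.ceil(radius_mm / step_mm)) + 1
    radii = np.linspace(radius_mm, 0.0, n_steps)  # outside -> center
    pos = center[None, None, :] + radii[None, :, None] * directions[:, None, :]
    vals = label.interpolate(pos.reshape(-1, 3), order=1).reshape(len(directions), n_steps)

    reached = vals >= 0.5
    any_hit = reached.any(axis=1)
    first = np.where(any_hit, reached.argmax(axis=1), n_steps - 1)
    prev = np.clip(first - 1, 0, None)
    v0 = vals[np.arange(len(first)), prev]
    v1 = vals[np.arange(len(first)), first]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(v1 > v0, (0.5 - v0) / (v1 - v0), 0.0)
    r_cross = radii[prev] + frac * (radii[first] - radii[prev])
    r_cross = np.where(any_hit, r_cross, 0.0)  # collapsed vertices land on center
    return r_cross, ~any_hit


def dice_score(mask_a: LabelVolume | np.ndarray, mask_b: LabelVolume | np.ndarray) -> float:
    """Volume overlap 2|X n Y| / (|X| + |Y|) of two binary masks on one grid."""
    a = mask_a.data if isinstance(mask_a, VoxelVolume) else np.asarray(mask_a)
    b = mask_b.data if isinstance(mask_b, VoxelVolume) else np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    a = a > 0.5
    b = b > 0.5
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def mesh_to_mask(mesh: SurfaceMesh, grid: VoxelVolume) -> LabelVolume:
    """Voxelize a closed mesh: voxel centres strictly inside map to 1.

    Containment is decided by crossing parity of rays cast along grid columns,
    restricted to the mesh bounding box for speed.
    """
    if not mesh.is_closed():
        raise ValueError("mesh must be closed for voxelization")
    shape = grid.data.shape
    mask = np.zeros(shape, dtype=float)

    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    corners_vox = grid.world_to_voxel(
        np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    )
    imin = np.clip(np.floor(corners_vox.min(axis=0)).astype(int) - 1, 0, np.array(shape) - 1)
    imax = np.clip(np.ceil(corners_vox.max(axis=0)).astype(int) + 1, 0, np.array(shape) - 1)

    ks = np.arange(imin[2], imax[2] + 1)
    z_world = grid.voxel_to_world(np.stack([np.zeros_like(ks), np.zeros_like(ks), ks], axis=1))
    # column direction in world space: along increasing k
    dir_k = grid.affine[:3, 2]
    dir_k = dir_k / np.linalg.norm(dir_k)
    for i in range(imin[0], imax[0] + 1):
        for j in range(imin[1], imax[1] + 1):
            origin = grid.voxel_to_world([[i, j, imin[2]]])[0]
            t, _, _ = geometry.ray_mesh_intersections(origin, dir_k, mesh.vertices, mesh.faces)
            if len(t) < 2:
                continue
            # distance of each voxel centre along the column
            step = np.linalg.norm(grid.affine[:3, 2])
            centers_t = (ks - imin[2]) * step
            inside = np.zeros(len(ks), dtype=bool)
            for t0, t1 in zip(t[0::2], t[1::2]):
                inside |= (centers_t > t0) & (centers_t < t1)
            mask[i, j, ks[inside]] = 1.0
    if mask.sum() == 0:
        raise ValueError("voxelization produced an empty mask (grid too coarse?)")
    return LabelVolume(data=mask, affine=grid.affine.copy(), frame=grid.frame, structure=mesh.structure)


def _vertex_normals_raw(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals from face cross products (no validation)."""
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )  # |fn| = 2 * face area, so summing area-weights automatically
    idx = faces.ravel()
    vn = np.empty_like(vertices)
    for c in range(3):
        vn[:, c] = np.bincount(idx, weights=np.repeat(fn[:, c], 3), minlength=len(vertices))
    return vn / np.linalg.norm(vn, axis=1, keepdims=True)


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Outward unit vertex normals (area-weighted face-normal average)."""
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    if np.any(areas <= 0):
        raise ValueError("mesh contains degenerate faces")
    return _vertex_normals_raw(mesh.vertices, mesh.faces)


def sample_profiles(
    mesh: SurfaceMesh,
    vol: VoxelVolume,
    structure_mean: float,
    offsets: np.ndarray = PROFILE_OFFSETS_MM,
    prefiltered: np.ndarray | None = None,
) -> IntensityProfileSet:
    """Cubic-spline intensity profiles at 7 points over +-3 mm per vertex.

    Samples along the outward vertex normal and subtracts ``structure_mean``
    (the subject's mean intensity inside the structure), which removes
    per-subject brightness offsets and leaves the border pattern.
    """
    normals = vertex_normals(mesh)
    pts = mesh.vertices[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    flat = pts.reshape(-1, 3)
    vox = vol.world_to_voxel(flat)
    out_of_grid = np.any((vox < 0) | (vox > np.array(vol.data.shape) - 1), axis=1)
    if out_of_grid.any():
        warnings.warn(
            f"{int(out_of_grid.sum())} profile samples fall outside the volume; edge-clamped",
            stacklevel=2,
        )
    vals = vol.interpolate(flat, order=3, prefiltered=prefiltered)
    values = vals.reshape(mesh.n_vertices, len(offsets)) - structure_mean
    return IntensityProfileSet(values=values, offsets=np.asarray(offsets, dtype=float))


def interior_mean_intensity(
    mesh: SurfaceMesh, vol: VoxelVolume, fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
) -> float:
    """Mean volume intensity inside the mesh via a radial interior quadrature.

    Samples the volume at fixed fractions along each vertex->centroid ray
    (interior for star-shaped nucleus meshes) plus the centroid itself.
    """
    c = mesh.centroid
    pts = [c[None, :]]
    for f in fractions:
        pts.append(c[None, :] + (1.0 - f) * (mesh.vertices - c[None, :]))
    pts = np.vstack(pts)
    return float(vol.interpolate(pts, order=1).mean())


def signed_distance(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mesh surface, positive inside."""
    return geometry.signed_distance_points(points, mesh.vertices, mesh.faces)


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write PLY (binary) or legacy ASCII VTK PolyData, preserving vertex order."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        mesh.to_trimesh().export(str(path), file_type="ply")
    elif path.suffix.lower() == ".vtk":
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nstnseg surface\nASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {mesh.n_vertices} double\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def load_mesh(path: str | Path, structure: str | None = None) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        tm = trimesh.load(str(path), process=False)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), structure=structure)
    if path.suffix.lower() == ".vtk":
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = next(k for k, l in enumerate(lines) if l.startswith("POINTS"))
        n = int(lines[i].split()[1])
        verts = np.array([[float(x) for x in lines[i + 1 + k].split()] for k in range(n)])
        j = next(k for k, l in enumerate(lines) if l.startswith("POLYGONS"))
        m = int(lines[j].split()[1])
        faces = np.array([[int(x) for x in lines[j + 1 + k].split()[1:]] for k in range(m)])
        return SurfaceMesh(verts, faces, structure=structure)
    raise ValueError(f"unsupported mesh format: {path.suffix}")
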