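"""Correspondence-based surface statistics on the STN.

Because every subject's mesh shares the seed-sphere tessellation, vertex i
and face j address the same anatomical spot in all subjects.  This enables
(i) k-means clustering of border intensity profiles across the surface, which
localizes characteristic T2 patterns (e.g. the sharp medial intensity rise),
and (ii) a surface likelihood map of where chronic stimulation electrodes
enter and exit the nucleus, built by mapping per-subject electrode/mesh
intersections to a reference mesh and fitting a 3D Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from . import geometry
from .mesh import SurfaceMesh

__all__ = [
    "ProfileClustering",
    "SurfaceDistribution",
    "cluster_profiles",
    "ProfileClusterer",
    "electrode_intersections",
    "map_to_reference",
    "fit_surface_density",
    "SurfaceDensityModel",
    "mean_mesh",
]


@dataclass
class ProfileClustering:
    """Per-vertex cluster assignment and per-cluster mean profiles."""

    labels: np.ndarray  # (N,) cluster id per vertex
    centers: np.ndarray  # (k, 7) mean profile per cluster
    inertia: float


@dataclass
class SurfaceDistribution:
    """Entry/exit likelihood on a corresponded reference surface."""

    face_density: np.ndarray  # density at face centers
    vertex_density: np.ndarray  # density at vertices (used for initialization)
    mean: np.ndarray  # fitted 3D Gaussian
    covariance: np.ndarray
    regularized: bool = False


def mean_mesh(meshes: list[SurfaceMesh], center_at_origin: bool = True) -> SurfaceMesh:
    """Vertex-wise mean of corresponded meshes (the reference surface).

    Centred at the origin by default: the absolute position of a population
    mean shape is arbitrary.
    """
    verts = np.mean([m.vertices for m in meshes], axis=0)
    if center_at_origin:
        verts = verts - verts.mean(axis=0)
    return SurfaceMesh(verts, meshes[0].faces.copy(), structure=meshes[0].structure)


def cluster_profiles(
    profile_sets: list[np.ndarray], k: int = 4, seed: int = 0
) -> ProfileClustering:
    """K-means over per-vertex dataset-mean intensity profiles.

    ``profile_sets`` holds one (N, 7) profile matrix per subject on
    corresponded vertices; profiles are averaged across subjects per vertex
    and the vertices are partitioned into ``k`` profile archetypes
    (k=4 gives the most consistent cortical-surface parcellation of the STN
    border patterns).
    """
    stack = np.stack(profile_sets)  # (S, N, 7)
    mean_profiles = stack.mean(axis=0)
    distinct = np.unique(np.round(mean_profiles, 9), axis=0)
    if len(distinct) < k:
        raise ValueError(f"only {len(distinct)} distinct profiles for k={k} clusters")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(mean_profiles)
    counts = np.bincount(km.labels_, minlength=k)
    if (counts == 0).any():
        warnings.warn("empty cluster in profile k-means (degenerate profiles)", stacklevel=2)
    return ProfileClustering(labels=km.labels_, centers=km.cluster_centers_, inertia=float(km.inertia_))


class ProfileClusterer(BaseEstimator):
    """Estimator wrapper for profile clustering (fit/predict on (N,7) profiles)."""

    def __init__(self, k: int = 4, seed: int = 0):
        self.k = k
        self.seed = seed

    def fit(self, profile_sets: list[np.ndarray]) -> "ProfileClusterer":
        self.clustering_ = cluster_profiles(profile_sets, k=self.k, seed=self.seed)
        return self

    def predict(self, profiles: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(profiles[:, None, :] - self.clustering_.centers[None, :, :], axis=-1)
        return d.argmin(axis=1)


def electrode_intersections(
    mesh: SurfaceMesh, point: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Entry and exit points of an electrode line through a closed mesh.

    Returns (entry, exit, face_ids) with entry the first hit along the
    insertion direction, or None if the line misses the mesh.  Tangential
    grazing (odd hit count) is repaired by dropping the most tangential hit,
    with a warning.
    """
    t, pts, face_ids = geometry.ray_mesh_intersections(point, direction, mesh.vertices, mesh.faces)
    if len(t) == 0:
        return None
    # merge duplicate hits from shared triangle edges
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) > 1e-9
    t, pts, face_ids = t[keep], pts[keep], face_ids[keep]
    if len(t) % 2 == 1:
        warnings.warn("odd intersection count (tangential grazing); repairing", stacklevel=2)
        tm = mesh.to_trimesh()
        normals = np.asarray(tm.face_normals)[face_ids]
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        drop = int(np.abs(normals @ d).argmin())
        sel = np.ones(len(t), dtype=bool)
        sel[drop] = False
        t, pts, face_ids = t[sel], pts[sel], face_ids[sel]
    if len(t) == 0:
        return None
    return pts[0], pts[-1], face_ids[[0, -1]]


def map_to_reference(
    points: np.ndarray,
    face_ids: np.ndarray,
    individual: SurfaceMesh,
    reference: SurfaceMesh,
) -> np.ndarray:
    """Carry surface points to the same-index faces of the reference mesh.

    Point correspondence means face j covers the same anatomical patch on
    both meshes, so the barycentric coordinates within the individual face
    transfer directly.
    """
    face_ids = np.asarray(face_ids, dtype=int)
    if face_ids.max(initial=-1) >= len(individual.faces) or face_ids.min(initial=0) < 0:
        raise IndexError("face index out of range")
    tri_ind = individual.vertices[individual.faces[face_ids]]
    tri_ref = reference.vertices[reference.faces[face_ids]]
    bary = geometry.barycentric_coordinates(np.atleast_2d(points), tri_ind)
    return geometry.from_barycentric(bary, tri_ref)


def fit_surface_density(
    points: np.ndarray, reference: SurfaceMesh, ridge: float = 1e-6
) -> SurfaceDistribution:
    """Gaussian MLE over mapped entry/exit points, evaluated on the surface.

    The 3D normal is fitted to the mapped points; its density is evaluated at
    every face center (for visualization) and vertex (for initialization
    queries).  A near-singular covariance is ridge-regularized with a flag.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    mean = points.mean(axis=0)
    if len(points) < 4:
        cov = np.eye(3)
        regularized = True
    else:
        cov = np.cov(points.T, bias=True)
        regularized = False
    # regularize if singular or nearly so
    if np.linalg.cond(cov) > 1e8 or np.linalg.det(cov) <= 0:
        scale = max(np.trace(cov) / 3.0, 1.0)
        cov = cov + ridge * scale * np.eye(3)
        regularized = True
        warnings.warn("singular covariance in surface density fit; ridge-regularized", stacklevel=2)
    mvn = multivariate_normal(mean=mean, cov=cov, allow_singular=True)
    face_centers = reference.vertices[reference.faces].mean(axis=1)
    return SurfaceDistribution(
        face_density=mvn.pdf(face_centers),
        vertex_density=mvn.pdf(reference.vertices),
        mean=mean,
        covariance=cov,
        regularized=regularized,
    )


class SurfaceDensityModel(BaseEstimator):
    """Estimator facade: fit the entry/exit Gaussian from per-subject
    electrode intersections mapped to a reference mesh."""

    def __init__(self, pool_entry_exit: bool = True):
        self.pool_entry_exit = pool_entry_exit

    def fit(
        self,
        meshes: list[SurfaceMesh],
        trajectories: list[tuple[np.ndarray, np.ndarray]],
        reference: SurfaceMesh | None = None,
    ) -> "SurfaceDensityModel":
        """``trajectories[i]`` is the (point, direction) electrode line of subject i."""
        self.reference_ = reference if reference is not None else mean_mesh(meshes)
        entries, exits = [], []
        for mesh, (point, direction) in zip(meshes, trajectories):
            hit = electrode_intersections(mesh, point, direction)
            if hit is None:
                continue
            entry, exit_, fids = hit
            mapped = map_to_reference(
                np.vstack([entry, exit_]), fids, mesh, self.reference_
            )
            entries.append(mapped[0])
            exits.append(mapped[1])
        if not entries:
            raise ValueError("no electrode intersected any mesh")
        pts = np.vstack(entries + exits) if self.pool_entry_exit else np.vstack(entries)
        self.distribution_ = fit_surface_density(pts, self.reference_)
        return self
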