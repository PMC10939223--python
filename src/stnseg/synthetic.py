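"""Phantom populations with known ground truth.

The generator emulates the study conditions end to end: ellipsoidal nuclei
templates at realistic sizes (STN ~130 mm^3), smooth low-rank shape variation
in the corresponded-vertex space, T2-like hypointense structures with a
logistic intensity ramp across the border, clinical (1.25 x 1.25 x 1.5 mm) or
fine (0.5 mm) voxel grids, and Ben-gun MER trajectories whose NRMS values are
drawn from log-normal IN/OUT emissions blended by a sigmoid of the distance to
the (truly shifted) STN surface.  Every stage of the pipeline can therefore
be tested against exact ground truth, which no clinical dataset provides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import mer as mer_mod
from .mer import FitTransform, MerModelParams, MerTrajectorySet, apply_transform, sigmoid_transition
from .mesh import SurfaceMesh, mesh_to_mask, seed_sphere
from .volume import LabelVolume, VoxelVolume

__all__ = [
    "StructureTemplate",
    "MerSimConfig",
    "PhantomSpec",
    "PhantomPopulation",
    "generate_population",
    "generate_mer_subject",
    "make_grid",
]

CLINICAL_SPACING = (1.25, 1.25, 1.5)
FINE_SPACING = (0.5, 0.5, 0.5)


@dataclass
class StructureTemplate:
    """Ellipsoidal nucleus template: semi-axes and centre in mm, T2 level."""

    name: str
    semi_axes_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    level: float = 0.55  # hypointense vs white-matter-normalized background 1.0


def default_structures() -> list[StructureTemplate]:
    # STN volume ~130 mm^3; SN larger, more inferior; both hypointense on T2
    return [
        StructureTemplate("STN_R", (5.2, 3.0, 2.0), (0.0, 0.0, 0.0), 0.55),
        StructureTemplate("SN_R", (6.0, 3.5, 2.5), (1.0, 3.5, -6.0), 0.60),
    ]


@dataclass
class MerSimConfig:
    """Generative settings for synthetic microelectrode recordings."""

    n_trajectories: int = 5
    ben_gun_radius_mm: float = mer_mod.BEN_GUN_RADIUS_MM
    depths_mm: np.ndarray = field(default_factory=lambda: mer_mod.DEFAULT_DEPTHS_MM.copy())
    direction: np.ndarray = field(default_factory=lambda: mer_mod.DEFAULT_DIRECTION.copy())
    params: MerModelParams = field(
        default_factory=lambda: MerModelParams(
            beta0=0.0, beta1=2.0, mu_in=float(np.log(2.5)), sigma_in=0.35, mu_out=0.0, sigma_out=0.2
        )
    )
    translation_range_mm: float = 1.5  # |true shift| per axis
    scale_range: tuple[float, float] = (0.95, 1.15)


@dataclass
class PhantomSpec:
    """Population-level settings; the defaults are the study conditions."""

    n_subjects: int = 40
    spacing: tuple[float, float, float] = FINE_SPACING
    structures: list[StructureTemplate] = field(default_factory=lambda: default_structures()[:1])
    rank: int = 5
    mode_sds_mm: tuple[float, ...] = (0.8, 0.6, 0.45, 0.3, 0.2)
    cross_structure_corr: float = 0.8  # latent sharing between structures
    background: float = 1.0
    boundary_width_mm: float = 0.8
    noise_sd: float = 0.0
    margin_mm: float = 8.0
    subdivisions: int = 3
    mer: MerSimConfig = field(default_factory=MerSimConfig)
    seed: int = 0


@dataclass
class PhantomPopulation:
    """Generated phantoms plus their exact ground truth."""

    spec: PhantomSpec
    volumes: list[VoxelVolume]
    labels: dict[str, list[LabelVolume]]
    meshes: dict[str, list[SurfaceMesh]]  # true (generating) meshes
    coeffs: dict[str, np.ndarray]  # (n_subjects, rank) latent draws per structure
    modes: dict[str, np.ndarray]  # (rank, 3N) orthonormal deformation modes


def make_grid(
    structures: list[StructureTemplate], spacing: tuple[float, float, float], margin_mm: float
) -> VoxelVolume:
    """Empty volume whose grid covers all structures plus a margin."""
    spacing = np.asarray(spacing, dtype=float)
    lo = np.min([np.asarray(s.center_mm) - np.asarray(s.semi_axes_mm) for s in structures], axis=0) - margin_mm
    hi = np.max([np.asarray(s.center_mm) + np.asarray(s.semi_axes_mm) for s in structures], axis=0) + margin_mm
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = lo
    return VoxelVolume(data=np.zeros(tuple(n)), affine=affine)


def _deformation_modes(unit_vertices: np.ndarray, rank: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth orthonormal vector fields on the template sphere, (rank, 3N).

    Each mode is a random linear+quadratic polynomial field of the unit-sphere
    coordinates, so deformations are spatially smooth and small draws cannot
    self-intersect the surface.
    """
    u = unit_vertices
    basis_scalars = [np.ones(len(u)), u[:, 0], u[:, 1], u[:, 2],
                     u[:, 0] * u[:, 1], u[:, 1] * u[:, 2], u[:, 0] * u[:, 2],
                     u[:, 0] ** 2 - u[:, 2] ** 2, u[:, 1] ** 2 - u[:, 2] ** 2]
    fields = []
    for _ in range(rank):
        coef = rng.normal(size=(len(basis_scalars), 3))
        f = sum(c[None, :] * b[:, None] for c, b in zip(coef, basis_scalars))
        fields.append(f.reshape(-1))
    q, _ = np.linalg.qr(np.stack(fields, axis=1))
    modes = q.T  # orthonormal rows in R^{3N}
    return modes


def _signed_distance_grid(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed EDT of a binary mask (positive inside), in mm."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask.astype(bool), sampling=spacing)
    return inside - outside


def generate_population(spec: PhantomSpec, rasterize: bool = True) -> PhantomPopulation:
    """Draw a phantom population; deterministic for a fixed ``spec.seed``.

    With ``rasterize=False`` only meshes and latent coefficients are
    generated (no label/volume rasterization), for mesh-level statistics.
    """
    rng = np.random.default_rng(spec.seed)
    grid = make_grid(spec.structures, spec.spacing, spec.margin_mm)
    sds = np.asarray(spec.mode_sds_mm[: spec.rank], dtype=float)

    # per-structure mode bases on the shared seed sphere tessellation
    sphere = seed_sphere(np.zeros(3), 1.0, spec.subdivisions)
    unit = sphere.vertices
    modes = {s.name: _deformation_modes(unit, spec.rank, rng) for s in spec.structures}

    # latent draws: shared component induces cross-structure correlation
    rho = spec.cross_structure_corr
    z_shared = rng.normal(size=(spec.n_subjects, spec.rank))
    coeffs = {}
    for s in spec.structures:
        z_own = rng.normal(size=(spec.n_subjects, spec.rank))
        z = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_own if len(spec.structures) > 1 else z_own
        coeffs[s.name] = z * sds[None, :]

    meshes: dict[str, list[SurfaceMesh]] = {s.name: [] for s in spec.structures}
    labels: dict[str, list[LabelVolume]] = {s.name: [] for s in spec.structures}
    volumes: list[VoxelVolume] = []
    spacing = np.asarray(spec.spacing, dtype=float)

    for i in range(spec.n_subjects):
        intensity = np.full(grid.data.shape, spec.background)
        for s in spec.structures:
            template = unit * np.asarray(s.semi_axes_mm) + np.asarray(s.center_mm)
            for _attempt in range(10):
                disp = (coeffs[s.name][i] @ modes[s.name]).reshape(-1, 3)
                verts = template + disp
                radial = np.linalg.norm(verts - verts.mean(axis=0), axis=1)
                if radial.min() > 0.5:  # star-shape sanity: no collapsed vertices
                    break
                coeffs[s.name][i] = rng.normal(size=spec.rank) * sds
            mesh = SurfaceMesh(verts, sphere.faces.copy(), structure=s.name, subdivisions=spec.subdivisions)
            meshes[s.name].append(mesh)
            if not rasterize:
                continue
            label = mesh_to_mask(mesh, grid)
            labels[s.name].append(label)
            d = _signed_distance_grid(label.data > 0.5, spacing)
            ramp = 1.0 / (1.0 + np.exp(-d / spec.boundary_width_mm))
            intensity = intensity + (s.level - spec.background) * ramp
        if not rasterize:
            continue
        if spec.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
        volumes.append(VoxelVolume(data=intensity, affine=grid.affine.copy()))

    return PhantomPopulation(
        spec=spec, volumes=volumes, labels=labels, meshes=meshes, coeffs=coeffs, modes=modes
    )


def generate_mer_subject(
    mesh: SurfaceMesh,
    config: MerSimConfig,
    true_transform: FitTransform,
    seed: int,
    plan_target: np.ndarray | None = None,
) -> tuple[MerTrajectorySet, dict]:
    """Synthetic MER session for one subject.

    Sites are laid out from the surgical plan (Ben-gun around the pre-op
    target); the electrophysiology is generated by the *truly shifted* mesh:
    the IN state is Bernoulli in the sigmoid of the signed distance, and NRMS
    is drawn from the state's log-normal emission.  Expert labels equal the
    true state.
    """
    rng = np.random.default_rng(seed)
    target = mesh.centroid if plan_target is None else np.asarray(plan_target, dtype=float)
    sites = mer_mod.init_from_plan(
        target,
        direction=config.direction,
        n_trajectories=config.n_trajectories,
        ben_gun_radius=config.ben_gun_radius_mm,
        depths=config.depths_mm,
    )
    true_mesh = apply_transform(mesh, true_transform)
    from .mesh import signed_distance

    d = signed_distance(true_mesh, sites.positions)
    p_in = sigmoid_transition(d, config.params.beta0, config.params.beta1)
    state = rng.random(len(d)) < p_in
    if not state.any():
        import warnings

        warnings.warn("no site falls inside the STN; trajectory misses the structure", stacklevel=2)
    mu = np.where(state, config.params.mu_in, config.params.mu_out)
    sigma = np.where(state, config.params.sigma_in, config.params.sigma_out)
    nrms = np.exp(rng.normal(mu, sigma))
    df = sites.sites.copy()
    df["nrms"] = nrms
    df["label"] = np.where(state, "IN", "OUT")
    truth = {"state": state, "distance": d, "transform": true_transform}
    return MerTrajectorySet(df), truth


def draw_transform(config: MerSimConfig, rng: np.random.Generator) -> FitTransform:
    """Random true brain-shift transform within the configured ranges."""
    t = rng.uniform(-config.translation_range_mm, config.translation_range_mm, size=3)
    s = rng.uniform(config.scale_range[0], config.scale_range[1], size=3)
    return FitTransform(t=t, s=s)
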