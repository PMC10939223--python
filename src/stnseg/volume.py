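"""Voxel volume containers, NIfTI I/O and T2 intensity normalization.

Conventions: world coordinates are millimetres in a RAS+ frame, voxel indices
are 0-based, and all world<->voxel mapping goes through the 4x4 affine of the
volume.  Interpolation queries take world-mm points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

STRUCTURES = ("STN_L", "STN_R", "SN_L", "SN_R", "RN_L", "RN_R")


@dataclass
class VoxelVolume:
    """A 3D scalar grid with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    frame: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("volume must be 3D with at least 2 voxels per axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        self._affine_inv = np.linalg.inv(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = self._affine_inv
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def interpolate(self, xyz: np.ndarray, order: int = 1, prefiltered: np.ndarray | None = None) -> np.ndarray:
        """Sample the volume at world-mm points (spline order 1 or 3).

        ``prefiltered`` may hold ``scipy.ndimage.spline_filter`` output for
        repeated cubic sampling; out-of-grid points are edge-clamped.
        """
        ijk = self.world_to_voxel(xyz).T
        src = self.data if prefiltered is None else prefiltered
        return ndimage.map_coordinates(
            src, ijk, order=order, mode="nearest", prefilter=(order > 1 and prefiltered is None)
        )


@dataclass
class LabelVolume(VoxelVolume):
    """Binary structure label on a voxel grid."""

    structure: str | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("label volume must be binary")
        if self.data.sum() < 1:
            raise ValueError("label volume is empty")
        raw = self.data > 0
        closed = ndimage.binary_closing(raw) | raw
        _, n_comp = ndimage.label(closed)
        if n_comp > 1:
            warnings.warn(
                f"label {self.structure or ''} has {n_comp} connected components after closing",
                stacklevel=2,
            )


@dataclass
class WhiteMatterMask:
    """Fuzzy white-matter membership in [0, 1] on a volume grid."""

    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        if self.membership.min() < 0 or self.membership.max() > 1:
            raise ValueError("membership values must lie in [0, 1]")
        if self.membership.sum() <= 0:
            raise ValueError("membership has empty support")


def load_volume(path: str | Path, frame: str = "native") -> VoxelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    bad = np.argwhere(~np.isfinite(data))
    if len(bad):
        idx = tuple(int(v) for v in bad[0])
        raise ValueError(f"volume {path} contains non-finite voxel, first at index {idx}")
    return VoxelVolume(data=data, affine=np.asarray(img.affine), frame=frame)


def save_volume(vol: VoxelVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), vol.affine), str(path))


def load_label(path: str | Path, structure: str | None = None, frame: str = "native") -> LabelVolume:
    vol = load_volume(path, frame=frame)
    return LabelVolume(data=(vol.data > 0.5).astype(float), affine=vol.affine, frame=frame, structure=structure)


def normalize_intensity(vol: VoxelVolume, wm: WhiteMatterMask) -> VoxelVolume:
    """Divide intensities by the membership-weighted mean white-matter intensity.

    After normalization the weighted WM mean equals 1; the transform is a
    global positive scaling, hence monotone and idempotent.
    """
    if wm.membership.shape != vol.data.shape:
        raise ValueError("white-matter mask must share the volume grid")
    w = wm.membership
    wm_mean = float((w * vol.data).sum() / w.sum())
    if abs(wm_mean) < 1e-12:
        raise ValueError("weighted white-matter mean is zero; cannot normalize")
    return replace(vol, data=vol.data / wm_mean)


def estimate_wm_membership(vol: VoxelVolume, n_classes: int = 3, n_iter: int = 50, m: float = 2.0,
                           seed: int = 0) -> WhiteMatterMask:
    """Fuzzy c-means membership of the white-matter class on a T2 volume.

    Clusters voxel intensities into ``n_classes`` with fuzzifier ``m`` and
    returns the membership of the darkest class (white matter is hypointense
    on T2 relative to grey matter and CSF).
    """
    x = vol.data.ravel()
    rng = np.random.default_rng(seed)
    centers = np.quantile(x, np.linspace(0.15, 0.85, n_classes)) + rng.normal(0, 1e-6, n_classes)
    for _ in range(n_iter):
        d = np.abs(x[:, None] - centers[None, :]) + 1e-12
        u = 1.0 / (d ** (2.0 / (m - 1.0)))
        u /= u.sum(axis=1, keepdims=True)
        um = u ** m
        centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
    wm_class = int(np.argmin(centers))
    d = np.abs(x[:, None] - centers[None, :]) + 1e-12
    u = 1.0 / (d ** (2.0 / (m - 1.0)))
    u /= u.sum(axis=1, keepdims=True)
    return WhiteMatterMask(membership=u[:, wm_class].reshape(vol.data.shape))
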