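"""Shared fixtures: analytic labels, grids and small phantom populations."""

import numpy as np
import pytest

from stnseg.volume import LabelVolume, VoxelVolume


def make_ellipsoid_label(
    semi=(6.0, 4.0, 3.0), spacing=(0.5, 0.5, 0.5), margin=8.0, center=(0.0, 0.0, 0.0)
) -> LabelVolume:
    """Binary ellipsoid on a regular grid (analytic ground truth)."""
    semi = np.asarray(semi, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center, dtype=float)
    lo = center - semi - margin
    n = np.ceil((2 * (semi + margin)) / spacing).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in n], indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) @ np.diag(spacing) + lo
    inside = (((pts - center) / semi) ** 2).sum(axis=1) <= 1.0
    return LabelVolume(data=inside.reshape(tuple(n)).astype(float), affine=affine)


@pytest.fixture(scope="session")
def ellipsoid_label():
    return make_ellipsoid_label()


@pytest.fixture(scope="session")
def sphere_label():
    return make_ellipsoid_label(semi=(5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def small_population():
    """10-subject noiseless STN phantom population at the fine grid."""
    from stnseg.synthetic import PhantomSpec, generate_population

    return generate_population(PhantomSpec(n_subjects=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
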