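import numpy as np
import pytest

from trabscope.phantom import (PhantomSpec, TransmuralSampleSpec,
                               generate_phantom, generate_transmural_sample)
from trabscope.volume import Label, LabelVolume


@pytest.fixture(scope="session")
def small_phantom():
    """A small LV-only phantom with 12 ridges, generated once per session."""
    spec = PhantomSpec(
        lv_epicardial_radius=10.0, lv_length=20.0, compact_thickness=3.0,
        n_trabeculations=12, trabeculation_width=(0.9, 1.1),
        trabeculation_depth=1.2, recess_gap=0.4,
        papillary_radius=1.0, rv_present=False,
        generation_voxel=0.2, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def rv_phantom():
    """A small phantom with both ventricles."""
    spec = PhantomSpec(
        lv_epicardial_radius=10.0, lv_length=20.0, compact_thickness=3.0,
        n_trabeculations=10, trabeculation_width=(0.9, 1.1),
        trabeculation_depth=1.2, recess_gap=0.4,
        papillary_radius=1.0, rv_present=True, rv_bulge=5.0,
        generation_voxel=0.2, seed=2)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def slab_sample():
    """A transmural slab sample with known sheet structure."""
    spec = TransmuralSampleSpec(seed=3)
    return generate_transmural_sample(spec)


def make_annulus(r_inner=8.0, r_outer=12.0, voxel=0.25, nz=20,
                 extent=30.0, label=Label.LV_COMPACT):
    """Cylindrical shell volume: constant cross-section ring."""
    n = int(round(extent / voxel))
    xs = (np.arange(n) + 0.5) * voxel - extent / 2.0
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    rho = np.hypot(X, Y)
    ring = ((rho > r_inner) & (rho <= r_outer)).astype(np.uint8) * label
    lum = (rho <= r_inner).astype(np.uint8) * Label.LV_LUMEN
    grid = np.repeat((ring + lum)[:, :, None], nz, axis=2)
    return LabelVolume(grid=grid, spacing=(voxel, voxel, voxel))


def make_annulus_with_ridges(n_ridges=12, r_inner=8.0, r_outer=12.0,
                             gap=0.6, depth=1.5, width=1.2, voxel=0.1,
                             nz=6, extent=30.0):
    """Ring plus detached radial ridges, for classification oracles."""
    n = int(round(extent / voxel))
    xs = (np.arange(n) + 0.5) * voxel - extent / 2.0
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    rho = np.hypot(X, Y)
    theta = np.degrees(np.arctan2(Y, X)) % 360.0
    grid2 = np.zeros((n, n), dtype=np.uint8)
    grid2[rho <= r_inner] = Label.LV_LUMEN
    grid2[(rho > r_inner) & (rho <= r_outer)] = Label.LV_COMPACT
    pitch = 360.0 / n_ridges
    k = np.minimum((theta / pitch).astype(int), n_ridges - 1)
    delta = np.radians(theta - (k + 0.5) * pitch)
    band = (rho <= r_inner - gap) & (rho >= r_inner - gap - depth)
    ridge = band & (np.abs(delta) * rho <= width / 2.0)
    grid2[ridge] = Label.LV_TRABECULAR
    grid = np.repeat(grid2[:, :, None], nz, axis=2)
    return LabelVolume(grid=grid, spacing=(voxel, voxel, voxel))
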