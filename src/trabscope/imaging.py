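"""Resolution degradation with exact partial-volume averaging.

A truth label volume is degraded to a stated acquisition resolution by box
averaging: each output voxel carries the volume-weighted myocardium fraction
of the source voxels it covers.  Box averaging (rather than a windowed-sinc
kernel) is used deliberately: it has an exact mass-conservation contract,
which is what the partial-volume experiments rely on.

Three named resolutions cover the study conditions: histology-like
(handled by 2D section rendering), 0.5 mm isotropic high-resolution MRI,
and 1.5 x 1.5 x 8 mm clinical-like MRI, where the 8 mm axis is always the
base->apex (slice stacking) direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import IntensityVolume, LabelVolume

__all__ = ["ResolutionSpec", "RESOLUTIONS", "resample", "binarize",
           "add_noise", "acquire"]


@dataclass(frozen=True)
class ResolutionSpec:
    """Acquisition resolution and the rule turning intensity into tissue."""

    voxel: tuple[float, float, float]
    modality: str = "mri_high"
    noise_sd: float = 0.0
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel dimensions must be positive")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must lie strictly in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


RESOLUTIONS: dict[str, ResolutionSpec] = {
    "mri_high": ResolutionSpec(voxel=(0.5, 0.5, 0.5), modality="mri_high"),
    "mri_clinical": ResolutionSpec(voxel=(1.5, 1.5, 8.0),
                                   modality="mri_clinical"),
}


def _overlap_matrix(n_in: int, s_in: float, t_out: float) -> np.ndarray:
    """1D box-overlap weights W[j, i] = |[j t,(j+1)t) ∩ [i s,(i+1)s)| / t."""
    n_out = max(int(np.floor(n_in * s_in / t_out)), 1)
    i = np.arange(n_in)
    j = np.arange(n_out)
    lo = np.maximum.outer(j * t_out, i * s_in)
    hi = np.minimum.outer((j + 1) * t_out, (i + 1) * s_in)
    return np.maximum(hi - lo, 0.0) / t_out


def resample(vol: LabelVolume, res: ResolutionSpec) -> IntensityVolume:
    """Box-average a label volume down to the requested resolution.

    Each output voxel value is the myocardium volume fraction of the source
    voxels it covers; total tissue mass (sum of intensity x voxel volume) is
    conserved up to truncation of a partial voxel layer at the far edges.
    Upsampling requests are rejected.
    """
    eps = 1e-9
    for t, s in zip(res.voxel, vol.spacing):
        if t < s - eps:
            raise ValueError(
                "target resolution is finer than the source voxel "
                f"({res.voxel} < {vol.spacing}): upsampling not supported")
    myo = vol.myocardium_mask().astype(np.float32)
    out = myo
    for axis in range(3):
        w = _overlap_matrix(vol.grid.shape[axis], vol.spacing[axis],
                            res.voxel[axis]).astype(np.float32)
        out = np.moveaxis(np.tensordot(w, out, axes=([1], [axis])), 0, axis)
    out = np.clip(out, 0.0, 1.0)
    return IntensityVolume(grid=out, spacing=res.voxel)


def binarize(iv: IntensityVolume, threshold: float = 0.5) -> LabelVolume:
    """Threshold a fractional-intensity volume into myocardium/non-myocardium.

    A voxel is myocardium iff its intensity is >= threshold; the operation is
    idempotent (binarizing a 0/1 volume returns it unchanged for any
    threshold in (0, 1]).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly in (0, 1)")
    grid = (iv.grid >= threshold).astype(np.uint8)
    return LabelVolume(grid=grid, spacing=iv.spacing, binary=True)


def add_noise(iv: IntensityVolume, sd: float, seed: int) -> IntensityVolume:
    """Add seeded Gaussian intensity noise; sd = 0 is the identity."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return IntensityVolume(grid=iv.grid.copy(), spacing=iv.spacing)
    rng = np.random.default_rng(seed)
    noisy = iv.grid + rng.normal(0.0, sd, size=iv.grid.shape).astype(np.float32)
    return IntensityVolume(grid=noisy, spacing=iv.spacing)


def acquire(vol: LabelVolume, res: ResolutionSpec, seed: int = 0) -> LabelVolume:
    """Full acquisition chain: box-average, optional noise, binarize."""
    iv = resample(vol, res)
    if res.noise_sd > 0:
        iv = add_noise(iv, res.noise_sd, seed)
    return binarize(iv, res.binarize_threshold)
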