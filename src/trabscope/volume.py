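"""Label and intensity volumes: the common currency of the pipeline.

Conventions used throughout the package:

* axis 0 = x, axis 1 = y (in-plane), axis 2 = z = base -> apex (short-axis
  stacking direction);
* physical coordinates are in millimetres, with the centre of voxel
  ``(i, j, k)`` at ``((i + 0.5) * sx, (j + 0.5) * sy, (k + 0.5) * sz)``;
* indices are 0-based and slice spans are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Label",
    "TISSUE_LABELS",
    "LV_TISSUE_LABELS",
    "RV_TISSUE_LABELS",
    "LabelVolume",
    "IntensityVolume",
]


class Label:
    """Integer codes of the anatomical compartments."""

    BACKGROUND = 0
    LV_LUMEN = 1
    LV_COMPACT = 2
    LV_TRABECULAR = 3
    RV_LUMEN = 4
    RV_COMPACT = 5
    RV_TRABECULAR = 6

    NAMES = {
        BACKGROUND: "background",
        LV_LUMEN: "lv_lumen",
        LV_COMPACT: "lv_compact",
        LV_TRABECULAR: "lv_trabecular",
        RV_LUMEN: "rv_lumen",
        RV_COMPACT: "rv_compact",
        RV_TRABECULAR: "rv_trabecular",
    }


LV_TISSUE_LABELS = (Label.LV_COMPACT, Label.LV_TRABECULAR)
RV_TISSUE_LABELS = (Label.RV_COMPACT, Label.RV_TRABECULAR)
TISSUE_LABELS = LV_TISSUE_LABELS + RV_TISSUE_LABELS


@dataclass
class LabelVolume:
    """3D voxel grid of anatomical labels with physical voxel spacing.

    ``binary=True`` marks a myocardium/non-myocardium volume (grid values
    0/1), e.g. the output of :func:`trabscope.imaging.binarize`.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    binary: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("LabelVolume grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid.shape, self.spacing))

    # -- masks & volumes ----------------------------------------------
    def myocardium_mask(self) -> np.ndarray:
        """Boolean mask of all myocardial tissue (any chamber, any layer)."""
        if self.binary:
            return self.grid > 0
        return np.isin(self.grid, TISSUE_LABELS)

    def label_mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.grid, labels)

    def volume_ml(self, *labels: int) -> float:
        """Volume occupied by the given labels, in ml."""
        return float(self.label_mask(*labels).sum()) * self.voxel_volume_ml

    def volumes_ml(self) -> dict[str, float]:
        """Per-compartment volumes in ml, keyed by label name."""
        counts = np.bincount(self.grid.ravel().astype(np.int64),
                             minlength=len(Label.NAMES))
        return {
            Label.NAMES[lab]: counts[lab] * self.voxel_volume_ml
            for lab in Label.NAMES
        }

    # -- physical <-> index -------------------------------------------
    def index_of(self, points_mm: np.ndarray) -> np.ndarray:
        """Voxel indices containing physical points (n, 3) in mm."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return np.floor(pts / np.asarray(self.spacing)).astype(np.int64)

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel label values at physical points; background outside."""
        idx = self.index_of(points_mm)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        out = np.zeros(len(idx), dtype=self.grid.dtype)
        ii = idx[inside]
        out[inside] = self.grid[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    # -- I/O ------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(self.grid.astype(np.uint8), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, binary: bool = False) -> "LabelVolume":
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj).astype(np.uint8)
        zooms = img.header.get_zooms()[:3]
        return cls(grid=grid, spacing=tuple(float(z) for z in zooms),
                   binary=binary)


@dataclass
class IntensityVolume:
    """Fractional myocardium intensity volume (values in [0, 1] pre-noise)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("IntensityVolume grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid.shape, self.spacing))

    def tissue_mass_ml(self) -> float:
        """Integrated myocardium content (sum of intensity x voxel volume)."""
        return float(self.grid.sum(dtype=np.float64)) * self.voxel_volume_ml

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(self.grid.astype(np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "IntensityVolume":
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj, dtype=np.float32)
        zooms = img.header.get_zooms()[:3]
        return cls(grid=grid, spacing=tuple(float(z) for z in zooms))
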