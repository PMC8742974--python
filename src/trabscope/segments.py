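"""17-segment partition of the left ventricle from landmark slices.

The LV long axis is divided into basal, mid-cavity and apical thirds from
four landmark slices — the basal-most LV slice, the tips of the papillary
muscles, the base of the papillary muscles, and the apex-most slice — with
the analysis image of each third taken midway between its flanking
landmarks.  Basal and mid rings carry six 60-degree sectors, the apical ring
four 90-degree sectors, and the apical cap (no remaining lumen) is segment
17.  Sector numbering starts at the reference angle (the RV insertion) and
follows the standard clinical ordering; the attitudinally correct name
'superior' replaces 'anterior' in the segment names, which is cosmetic only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume import Label, LabelVolume
from . import morphometry as mm

__all__ = ["Landmarks", "SegmentMap", "SegmentMetrics", "SEGMENT_NAMES",
           "find_landmarks", "assign_segments", "per_segment_metrics",
           "LandmarkError"]


class LandmarkError(ValueError):
    """Raised when the landmark structures cannot be located."""


SEGMENT_NAMES = {
    1: "basal superior", 2: "basal superoseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal superolateral",
    7: "mid superior", 8: "mid superoseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid superolateral",
    13: "apical superior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apex",
}


@dataclass(frozen=True)
class Landmarks:
    """Slice indices of the four axial landmarks, ordered base -> apex."""

    base_most: int
    papillary_tips: int
    papillary_base: int
    apex_most: int

    def __post_init__(self) -> None:
        seq = (self.base_most, self.papillary_tips,
               self.papillary_base, self.apex_most)
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise LandmarkError("landmarks must be ordered base -> apex")

    def analysis_slices(self) -> tuple[int, int, int]:
        """Basal/mid/apical analysis slices, midway between flanking
        landmarks (floor; ties break toward the base)."""
        return ((self.base_most + self.papillary_tips) // 2,
                (self.papillary_tips + self.papillary_base) // 2,
                (self.papillary_base + self.apex_most) // 2)


def find_landmarks(vol: LabelVolume,
                   papillary_slices: tuple[int, int] | None = None
                   ) -> Landmarks:
    """Locate the four landmark slices on a label volume.

    Base-most/apex-most are the first/last slices containing LV tissue.  The
    papillary extent is taken from ``papillary_slices`` when the generator's
    ground truth is available; otherwise papillary muscle is detected as
    trabecular-labelled components whose mean radius stays within half the
    local endocardial radius (papillaries sit deep in the cavity, mural
    trabeculations hug the compact wall).
    """
    lv = vol.label_mask(Label.LV_COMPACT, Label.LV_TRABECULAR)
    has = np.flatnonzero(lv.any(axis=(0, 1)))
    if has.size == 0:
        raise LandmarkError("volume contains no LV tissue")
    base_most, apex_most = int(has[0]), int(has[-1])

    if papillary_slices is None:
        papillary_slices = _detect_papillary_extent(vol)
    tips, pap_base = papillary_slices
    return Landmarks(base_most=base_most, papillary_tips=int(tips),
                     papillary_base=int(pap_base), apex_most=apex_most)


def _detect_papillary_extent(vol: LabelVolume) -> tuple[int, int]:
    from scipy import ndimage

    trab = vol.label_mask(Label.LV_TRABECULAR)
    if not trab.any():
        raise LandmarkError("no papillary structures found")
    lab, n = ndimage.label(trab)
    sx, sy, _ = vol.spacing
    nx, ny, _ = vol.grid.shape
    compact = vol.label_mask(Label.LV_COMPACT)
    zs = np.flatnonzero(compact.any(axis=(0, 1)))
    pap_z: list[int] = []
    objects = ndimage.find_objects(lab)
    for i, slc in enumerate(objects, start=1):
        m = lab == i
        ks = np.flatnonzero(m.any(axis=(0, 1)))
        k_mid = int(ks[len(ks) // 2])
        cxy = mm.slice_lumen_centroid(vol, (k_mid + 0.5) * vol.spacing[2])
        xs = (np.arange(nx) + 0.5) * sx - cxy[0]
        ys = (np.arange(ny) + 0.5) * sy - cxy[1]
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        rho = np.hypot(X, Y)
        comp_k = compact[:, :, k_mid]
        if not comp_k.any():
            continue
        r_endo = rho[comp_k].min()
        mean_r = rho[m[:, :, k_mid]].mean() if m[:, :, k_mid].any() else np.inf
        if mean_r < 0.5 * r_endo:
            pap_z.extend([int(ks[0]), int(ks[-1])])
    if not pap_z:
        raise LandmarkError("no papillary structures found")
    return min(pap_z), max(pap_z)


@dataclass
class SegmentMap:
    """Voxel -> segment assignment plus the landmark bookkeeping."""

    assignment: np.ndarray               # uint8; 0 = none, 1..17 = segment
    landmarks: Landmarks
    analysis_slices: tuple[int, int, int]
    reference_angle: float
    spacing: tuple[float, float, float]

    def segment_mask(self, seg: int) -> np.ndarray:
        return self.assignment == seg

    def ring_of(self, seg: int) -> str:
        if 1 <= seg <= 6:
            return "basal"
        if 7 <= seg <= 12:
            return "mid"
        if 13 <= seg <= 16:
            return "apical"
        return "apex"


def assign_segments(vol: LabelVolume, landmarks: Landmarks,
                    reference_angle: float = 0.0) -> SegmentMap:
    """Assign every LV wall voxel between the base-most and apex-most
    landmarks to exactly one of the 17 segments."""
    lv = vol.label_mask(Label.LV_COMPACT, Label.LV_TRABECULAR)
    lumen = vol.label_mask(Label.LV_LUMEN)
    nx, ny, nz = vol.grid.shape
    sx, sy, sz = vol.spacing

    lumen_z = np.flatnonzero(lumen.any(axis=(0, 1)))
    apex_cap_start = int(lumen_z[-1]) + 1 if lumen_z.size else landmarks.apex_most

    # angle relative to the volume's long axis (centroid of the lumen stack;
    # falls back to LV tissue when no lumen, e.g. fully binarized caps)
    ref_mask = lumen if lumen.any() else lv
    from scipy import ndimage
    com = ndimage.center_of_mass(ref_mask.any(axis=2))
    cx, cy = (com[0] + 0.5) * sx, (com[1] + 0.5) * sy
    xs = (np.arange(nx) + 0.5) * sx - cx
    ys = (np.arange(ny) + 0.5) * sy - cy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    theta = (np.degrees(np.arctan2(Y, X)) - reference_angle) % 360.0
    sector6 = np.minimum((theta / 60.0).astype(np.uint8), 5)
    sector4 = np.minimum((theta / 90.0).astype(np.uint8), 3)

    assignment = np.zeros((nx, ny, nz), dtype=np.uint8)
    for k in range(landmarks.base_most, landmarks.apex_most + 1):
        wall = lv[:, :, k]
        if not wall.any():
            continue
        if k >= apex_cap_start:
            assignment[:, :, k][wall] = 17
        elif k < landmarks.papillary_tips:
            assignment[:, :, k][wall] = (1 + sector6)[wall]
        elif k < landmarks.papillary_base:
            assignment[:, :, k][wall] = (7 + sector6)[wall]
        else:
            assignment[:, :, k][wall] = (13 + sector4)[wall]

    return SegmentMap(assignment=assignment, landmarks=landmarks,
                      analysis_slices=landmarks.analysis_slices(),
                      reference_angle=reference_angle,
                      spacing=vol.spacing)


@dataclass
class SegmentMetrics:
    """Per-segment T/C and trabecular fraction, with the 1-16 summaries."""

    tc: dict[int, float]                 # per segment; apex always present
    trab_fraction: dict[int, float]      # %, per segment
    summed_tc_1_16: float
    average_tc_1_16: float
    n_segments_tc_gt: int
    tc_threshold: float = 2.3


def per_segment_metrics(segmap: SegmentMap, vol: LabelVolume,
                        compartments: LabelVolume | None = None,
                        rays_per_sector: int = 6,
                        tc_threshold: float = 2.3,
                        avoid_angles: dict[str, list[tuple[float, float]]]
                        | None = None,
                        intensity=None) -> SegmentMetrics:
    """Measure per-segment T/C (maximum over that segment's trajectories)
    and trabecular volume fraction.

    ``avoid_angles`` maps ring name -> angular intervals (deg) that
    trajectories must avoid (papillary crossings inflate the trabecular
    span; thickness criteria measure the mural layer).  The apex (segment
    17) is excluded from the summed and average T/C.

    When the grayscale ``intensity`` volume of the same acquisition is
    supplied, thickness trajectories are read off it at the 0.5 iso-contour
    with sub-voxel interpolation (as a reader measures on the image);
    otherwise they are read off the label volume.
    """
    sz = segmap.spacing[2]
    ring_slices = dict(zip(("basal", "mid", "apical"),
                           segmap.analysis_slices))
    ring_segs = {"basal": range(1, 7), "mid": range(7, 13),
                 "apical": range(13, 17)}
    ring_width = {"basal": 60.0, "mid": 60.0, "apical": 90.0}

    tc: dict[int, float] = {17: 0.0}
    for ring, segs in ring_segs.items():
        k = ring_slices[ring]
        z = (k + 0.5) * sz
        try:
            cxy = mm.slice_lumen_centroid(vol, z)
        except mm.EmptyProfileError:
            for seg in segs:
                tc[seg] = float("nan")
            continue
        zones = (avoid_angles or {}).get(ring, [])
        width = ring_width[ring]
        for j, seg in enumerate(segs):
            a0 = segmap.reference_angle + j * width
            best = 0.0
            got = False
            for m in range(rays_per_sector):
                ang = a0 + (m + 0.5) * width / rays_per_sector
                if any(_in_zone(ang, z0, z1) for z0, z1 in zones):
                    continue
                traj = mm.radial_trajectory(vol, ang, z, centroid_xy=cxy)
                try:
                    if intensity is not None:
                        prof = mm.extract_profile_intensity(intensity, traj)
                    else:
                        prof = mm.extract_profile(vol, traj)
                    meas = mm.measure_layers(prof)
                except (mm.EmptyProfileError, ValueError):
                    continue
                best = max(best, meas.TC)
                got = True
            tc[seg] = best if got else float("nan")

    frac: dict[int, float] = {}
    src = compartments if compartments is not None else vol
    for seg in range(1, 18):
        segmask = segmap.segment_mask(seg)
        t = float((src.grid[segmask] == Label.LV_TRABECULAR).sum())
        c = float((src.grid[segmask] == Label.LV_COMPACT).sum())
        frac[seg] = 100.0 * t / (t + c) if t + c > 0 else float("nan")

    vals = [tc[s] for s in range(1, 17)]
    finite = [v for v in vals if not math.isnan(v)]
    summed = float(sum(finite))
    return SegmentMetrics(
        tc=tc, trab_fraction=frac,
        summed_tc_1_16=summed,
        average_tc_1_16=summed / 16.0,
        n_segments_tc_gt=sum(1 for v in finite if v > tc_threshold),
        tc_threshold=tc_threshold)


def _in_zone(angle: float, z0: float, z1: float) -> bool:
    a = angle % 360.0
    z0, z1 = z0 % 360.0, z1 % 360.0
    if z0 <= z1:
        return z0 <= a <= z1
    return a >= z0 or a <= z1
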