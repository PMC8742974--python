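"""Synthetic ventricular phantoms with exactly known trabecular structure.

Two generators are provided:

* :func:`generate_phantom` builds a whole-ventricle label volume: a truncated
  prolate-ellipsoid LV with an outer compact shell, an inner layer of radial
  trabecular ridges detached from the shell by an intertrabecular recess,
  papillary muscles, a smooth outflow sector, and an optional RV crescent.
* :func:`generate_transmural_sample` builds a transmural wall slab in which
  an epicardium-to-endocardium trajectory crosses a known number of
  trabecular sheets separated by recesses — the substrate for studying how
  measured trabeculation depends on imaging resolution.

Counting semantics differ between the two: in the whole ventricle the
``n_trabeculations`` truth refers to the number of ridges crossed by a
circumferential trajectory through the mid-trabecular layer of one
short-axis ring, while a straight radial ray crosses a single (detached)
ridge.  In the slab, the trajectory itself crosses the stated number of
sheets, emulating a transmural count on a histological section.

All randomness flows from the integer ``seed`` of the spec through a named
:class:`numpy.random.Generator`; identical (spec, seed) gives bit-identical
volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume import Label, LabelVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "TransmuralSampleSpec",
    "SampleTruth",
    "Section",
    "generate_phantom",
    "generate_transmural_sample",
    "render_histology_section",
    "section_as_volume",
    "make_cohort",
    "make_lvrv_cohort",
    "COHORT_CLASS_PARAMS",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a whole-ventricle phantom (all lengths in mm).

    The LV is a truncated prolate half-ellipsoid: epicardial semi-axes
    ``(lv_epicardial_radius, lv_length)``, compact shell of nominal thickness
    ``compact_thickness`` (the actual transmural thickness grows toward the
    apex, as for offset ellipsoids).  ``n_trabeculations`` radial ridges of
    width drawn from ``trabeculation_width`` are placed at even angular pitch
    outside the smooth outflow sector, detached from the compact shell by an
    intertrabecular ``recess_gap`` and extending ``trabeculation_depth``
    toward the lumen.
    """

    lv_epicardial_radius: float = 14.0
    lv_length: float = 28.0
    compact_thickness: float = 3.8
    n_trabeculations: int = 18
    trabeculation_width: tuple[float, float] = (0.8, 1.2)   # (min, max)
    trabeculation_depth: float = 1.6
    recess_gap: float = 0.4
    papillary_count: int = 2
    papillary_radius: float = 1.4
    papillary_center_frac: float = 0.5    # of local endocardial radius
    papillary_z_frac: tuple[float, float] = (0.30, 0.55)  # of lv_length
    # clearance shell between papillary columns and trabecular ridges; wider
    # than the coarsest in-plane MRI voxel so the structures stay separable
    # after partial-volume degradation at high resolution
    papillary_clearance: float = 1.2
    outflow_sector: float = 60.0          # degrees of smooth wall
    outflow_center: float = 210.0         # degrees, absolute
    rv_present: bool = True
    rv_compact_thickness: float = 1.5
    rv_n_trabeculations: int = 8
    rv_trabeculation_width: float = 1.2
    rv_trabeculation_depth: float = 2.0
    rv_recess_gap: float = 0.5
    rv_bulge: float = 7.0                 # max crescent cavity depth
    rv_span: tuple[float, float] = (0.0, 150.0)  # degrees, absolute
    reference_angle: float = 0.0          # RV insertion; theta = 0
    generation_voxel: float = 0.1         # mm, isotropic
    margin: float = 2.0
    seed: int = 0

    # minimum residual lumen core radius below which ridges stop (apexward)
    lumen_core: float = 1.0
    # minimum circumferential clearance between neighbouring ridges
    min_ridge_clearance: float = 0.25

    def __post_init__(self) -> None:
        w_min, w_max = self.trabeculation_width
        if w_min <= 0 or w_max < w_min:
            raise ValueError("trabeculation_width must satisfy 0 < min <= max")
        if not (0.0 <= self.outflow_sector < 360.0):
            raise ValueError("outflow_sector must lie in [0, 360)")
        if self.generation_voxel <= 0:
            raise ValueError("generation_voxel must be positive")
        if self.n_trabeculations > 0 and self.generation_voxel > w_min / 3.0:
            raise ValueError(
                "generation_voxel must be <= min(trabeculation_width)/3 "
                "for the truth to be representable on the grid")
        r_ci0 = self.lv_epicardial_radius - self.compact_thickness
        if r_ci0 <= 0:
            raise ValueError("compact shell thicker than the epicardial radius")
        if self.recess_gap + self.trabeculation_depth >= r_ci0:
            raise ValueError("trabeculation_depth exceeds the lumen radius")
        if self.n_trabeculations > 0:
            pitch = math.radians(self._sector_deg) / self.n_trabeculations
            inner = r_ci0 - self.recess_gap - self.trabeculation_depth
            if pitch * inner < w_max + self.min_ridge_clearance:
                raise ValueError(
                    "trabeculations would overlap and merge (angular pitch "
                    "smaller than trabecular width): truth unrepresentable")

    # -- derived geometry ----------------------------------------------
    @property
    def _sector_deg(self) -> float:
        return 360.0 - self.outflow_sector

    @property
    def _outflow_end(self) -> float:
        """Absolute angle (deg) at which the trabeculated sector begins."""
        return (self.outflow_center + self.outflow_sector / 2.0) % 360.0

    def _r_epi(self, z: float | np.ndarray) -> float | np.ndarray:
        zeta = np.clip(np.asarray(z, dtype=float) / self.lv_length, 0.0, 1.0)
        return self.lv_epicardial_radius * np.sqrt(1.0 - zeta ** 2)

    def _r_ci(self, z: float | np.ndarray) -> float | np.ndarray:
        """Endocardial radius of the compact shell (inner offset ellipsoid)."""
        a = self.lv_epicardial_radius - self.compact_thickness
        b = self.lv_length - self.compact_thickness
        zeta = np.clip(np.asarray(z, dtype=float) / b, 0.0, 1.0)
        return a * np.sqrt(1.0 - zeta ** 2)

    def ridges_present(self, z: float) -> bool:
        """Ridges exist at height z if the lumen retains a free core and the
        inter-ridge clearance survives at the local ridge inner radius."""
        if self.n_trabeculations <= 0 or not 0.0 <= z <= self.lv_length:
            return False
        r_ci = float(self._r_ci(z))
        inner = r_ci - self.recess_gap - self.trabeculation_depth
        if inner < self.lumen_core:
            return False
        pitch = math.radians(self._sector_deg) / self.n_trabeculations
        w_max = self.trabeculation_width[1]
        return pitch * inner >= w_max + self.min_ridge_clearance


@dataclass
class GroundTruth:
    """Exact per-phantom record of what the generator put on the grid."""

    true_volumes: dict[str, float]          # ml per label name
    papillary_ml: float
    true_trab_fraction_lv: float            # %, papillaries included
    n_trabeculations: int
    true_count_by_trajectory: dict[str, int]
    true_C: float                           # nominal compact thickness, mm
    true_NC: float                          # recess gap + ridge depth, mm
    true_TC: float
    ridge_centers_deg: np.ndarray
    ridge_widths_mm: np.ndarray
    trab_z_range_mm: tuple[float, float] | None
    circ_trajectory: dict | None            # {"z_mm":..., "radius_mm":...}
    papillary_z_slices: tuple[int, int] | None
    papillary_angles_deg: tuple[float, ...]
    segment_truth: dict[int, float]
    base_z_mm: float                        # physical z of the LV base plane
    spec: PhantomSpec
    group: str | None = None


# ---------------------------------------------------------------------------
# whole-ventricle generator
# ---------------------------------------------------------------------------

def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    return np.mod(a, 360.0)


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, GroundTruth]:
    """Generate a seeded whole-ventricle label volume and its ground truth."""
    v = spec.generation_voxel
    rng = np.random.default_rng(spec.seed)

    rv_extra = (spec.rv_bulge + spec.rv_compact_thickness
                if spec.rv_present else 0.0)
    r_out = spec.lv_epicardial_radius + rv_extra
    nx = ny = int(math.ceil(2.0 * (r_out + spec.margin) / v))
    nz = int(math.ceil((spec.lv_length + 2.0 * spec.margin) / v))
    cx = nx * v / 2.0
    cy = ny * v / 2.0
    base_z = spec.margin

    xs = (np.arange(nx) + 0.5) * v - cx
    ys = (np.arange(ny) + 0.5) * v - cy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rho = np.sqrt(X ** 2 + Y ** 2)
    theta = _wrap_deg(np.degrees(np.arctan2(Y, X)))

    sector = spec._sector_deg
    n_tr = spec.n_trabeculations

    # papillary cross-section mask (constant over its z range)
    pap_mask = np.zeros((nx, ny), dtype=bool)
    pap_angles: list[float] = []
    pap_footprints: list[tuple[float, float]] = []
    z_tip = spec.papillary_z_frac[0] * spec.lv_length
    z_papbase = spec.papillary_z_frac[1] * spec.lv_length
    rho_p = spec.papillary_center_frac * float(spec._r_ci(z_papbase))
    if spec.papillary_count > 0:
        fracs = (np.arange(spec.papillary_count) + 1.0) / \
            (spec.papillary_count + 1.0)
        half = math.degrees(math.asin(min(
            0.999, (spec.papillary_radius + spec.papillary_clearance)
            / max(rho_p, 1e-6))))
        for f in fracs:
            phi = math.radians(spec._outflow_end + sector * f)
            px, py = rho_p * math.cos(phi), rho_p * math.sin(phi)
            pap_mask |= (X - px) ** 2 + (Y - py) ** 2 <= spec.papillary_radius ** 2
            ang = _wrap_deg(math.degrees(phi))
            pap_angles.append(ang)
            pap_footprints.append((ang - half, ang + half))

    # ridge angular mask + per-pixel ridge width (constant over z); a
    # clearance shell is carved around each papillary column so deep ridges
    # never merge with papillary muscle and every structure stays separable
    widths = (rng.uniform(*spec.trabeculation_width, size=n_tr)
              if n_tr > 0 else np.empty(0))
    u = _wrap_deg(theta - spec._outflow_end)
    in_sector = u < sector
    if n_tr > 0:
        pitch = sector / n_tr
        k = np.minimum((u / pitch).astype(np.int64), n_tr - 1)
        delta_rad = np.radians(u - (k + 0.5) * pitch)
        ridge_ang = in_sector & (np.abs(delta_rad) * rho <= widths[k] / 2.0)
        if spec.papillary_count > 0:
            pap_clear = np.zeros((nx, ny), dtype=bool)
            pap_r_outer = (rho_p + spec.papillary_radius
                           + spec.papillary_clearance)
            for f0, f1 in pap_footprints:
                centre = (f0 + f1) / 2.0
                half = (f1 - f0) / 2.0
                dist = np.abs((theta - centre + 180.0) % 360.0 - 180.0)
                pap_clear |= (dist <= half) & (rho <= pap_r_outer)
            ridge_ang &= ~pap_clear
        ridge_centers = _wrap_deg(spec._outflow_end
                                  + (np.arange(n_tr) + 0.5) * pitch)
    else:
        ridge_ang = np.zeros_like(in_sector)
        ridge_centers = np.empty(0)

    # RV angular profile (constant over z up to the axial taper)
    if spec.rv_present:
        rv_start, rv_end = spec.rv_span
        span = _wrap_deg(rv_end - rv_start)
        u_rv = _wrap_deg(theta - rv_start) / span
        rv_in = u_rv < 1.0
        rv_shape = np.where(rv_in, np.sin(np.pi * np.clip(u_rv, 0, 1)), 0.0)
        n_rv = spec.rv_n_trabeculations
        if n_rv > 0:
            pitch_rv = 0.7 * span / n_rv
            u_off = u_rv * span - 0.15 * span
            kr = np.clip((u_off / pitch_rv).astype(np.int64), 0, n_rv - 1)
            d_rv = np.radians(u_off - (kr + 0.5) * pitch_rv)
            rv_ridge_ang = (rv_in & (u_off >= 0) & (u_off < 0.7 * span)
                            & (np.abs(d_rv) * rho
                               <= spec.rv_trabeculation_width / 2.0))
        else:
            rv_ridge_ang = np.zeros_like(rv_in)
        l_rv = 0.85 * spec.lv_length

    grid = np.zeros((nx, ny, nz), dtype=np.uint8)
    pap_voxels = 0
    trab_slices: list[int] = []
    pap_slices: list[int] = []

    for kz in range(nz):
        z = (kz + 0.5) * v - base_z
        if not (0.0 <= z <= spec.lv_length):
            continue
        r_epi = float(spec._r_epi(z))
        r_ci = float(spec._r_ci(z))
        if r_epi <= 0:
            continue
        sl = np.zeros((nx, ny), dtype=np.uint8)
        lumen = rho <= r_ci
        sl[lumen] = Label.LV_LUMEN
        sl[(rho > r_ci) & (rho <= r_epi)] = Label.LV_COMPACT

        if spec.ridges_present(z):
            outer = r_ci - spec.recess_gap
            inner = outer - spec.trabeculation_depth
            band = (rho >= inner) & (rho <= outer)
            sl[lumen & band & ridge_ang] = Label.LV_TRABECULAR
            trab_slices.append(kz)

        if spec.papillary_count > 0 and z_tip <= z <= z_papbase:
            pm = pap_mask & lumen
            sl[pm] = Label.LV_TRABECULAR
            pap_voxels += int(pm.sum())
            pap_slices.append(kz)

        if spec.rv_present and z <= l_rv:
            s_rv = math.sqrt(max(0.0, 1.0 - (z / l_rv) ** 2))
            g = spec.rv_bulge * s_rv * rv_shape
            cav = rv_in & (rho > r_epi) & (rho <= r_epi + g)
            comp = rv_in & (rho > r_epi + g) \
                & (rho <= r_epi + g + spec.rv_compact_thickness)
            sl[cav] = Label.RV_LUMEN
            sl[comp] = Label.RV_COMPACT
            if spec.rv_n_trabeculations > 0:
                outer_rv = r_epi + g - spec.rv_recess_gap
                depth_eff = np.minimum(spec.rv_trabeculation_depth, 0.45 * g)
                band_rv = (rho >= outer_rv - depth_eff) & (rho <= outer_rv)
                sl[cav & band_rv & rv_ridge_ang
                   & (g > 3.0 * spec.rv_recess_gap)] = Label.RV_TRABECULAR
        grid[:, :, kz] = sl

    vol = LabelVolume(grid=grid, spacing=(v, v, v))
    truth = _build_ground_truth(spec, vol, widths, ridge_centers,
                                pap_voxels, trab_slices, pap_slices,
                                tuple(pap_angles), base_z)
    return vol, truth


def _build_ground_truth(spec, vol, widths, ridge_centers, pap_voxels,
                        trab_slices, pap_slices, pap_angles, base_z):
    vols = vol.volumes_ml()
    lv_t = vols["lv_trabecular"]
    lv_c = vols["lv_compact"]
    frac = 100.0 * lv_t / (lv_t + lv_c) if lv_t + lv_c > 0 else 0.0
    nc = spec.recess_gap + spec.trabeculation_depth \
        if spec.n_trabeculations > 0 else 0.0
    tc = nc / spec.compact_thickness

    v = spec.generation_voxel
    if trab_slices:
        z_lo = (trab_slices[0] + 0.5) * v - base_z
        z_hi = (trab_slices[-1] + 0.5) * v - base_z
        trab_range = (z_lo, z_hi)
        z_star = z_lo + 0.25 * (z_hi - z_lo)
        r_star = (float(spec._r_ci(z_star)) - spec.recess_gap
                  - spec.trabeculation_depth / 2.0)
        circ = {"z_mm": z_star + base_z, "radius_mm": r_star}
    else:
        trab_range, circ = None, None

    counts = {
        "circumferential_mid_trabecular":
            len(ridge_centers) if trab_range else 0,
        "radial_through_ridge": 1 if trab_range else 0,
        "radial_outflow": 0,
    }
    seg_truth = _segment_truth(spec, ridge_centers, widths)
    pap_range = (pap_slices[0], pap_slices[-1]) if pap_slices else None

    return GroundTruth(
        true_volumes=vols,
        papillary_ml=pap_voxels * vol.voxel_volume_ml,
        true_trab_fraction_lv=frac,
        n_trabeculations=spec.n_trabeculations,
        true_count_by_trajectory=counts,
        true_C=spec.compact_thickness,
        true_NC=nc,
        true_TC=tc,
        ridge_centers_deg=np.asarray(ridge_centers),
        ridge_widths_mm=np.asarray(widths),
        trab_z_range_mm=trab_range,
        circ_trajectory=circ,
        papillary_z_slices=pap_range,
        papillary_angles_deg=pap_angles,
        segment_truth=seg_truth,
        base_z_mm=base_z,
        spec=spec,
    )


def _intervals_overlap_circular(a0, a1, b0, b1):
    """Do angular intervals [a0,a1) and [b0,b1) (deg, may wrap) intersect?"""
    def norm(lo, hi):
        lo, hi = lo % 360.0, hi % 360.0
        return [(lo, hi)] if lo <= hi else [(lo, 360.0), (0.0, hi)]
    for x0, x1 in norm(a0, a1):
        for y0, y1 in norm(b0, b1):
            if max(x0, y0) < min(x1, y1):
                return True
    return False


def _segment_truth(spec: PhantomSpec, ridge_centers: np.ndarray,
                   ridge_widths: np.ndarray) -> dict[int, float]:
    """Analytic max T/C per 17-model segment, from the ridges actually drawn
    (papillaries excluded from the thickness measure; the apex cap, segment
    17, is 0 by convention)."""
    L = spec.lv_length
    z_tip = spec.papillary_z_frac[0] * L
    z_pb = spec.papillary_z_frac[1] * L
    rings = {
        "basal": ((0.0 + z_tip) / 2.0, range(1, 7), 60.0),
        "mid": ((z_tip + z_pb) / 2.0, range(7, 13), 60.0),
        "apical": ((z_pb + L) / 2.0, range(13, 17), 90.0),
    }
    out: dict[int, float] = {17: 0.0}
    for _, (z, seg_ids, width) in rings.items():
        have = spec.ridges_present(z)
        c_local = float(spec._r_epi(z)) - float(spec._r_ci(z))
        nc = spec.recess_gap + spec.trabeculation_depth
        r_mid = (float(spec._r_ci(z)) - spec.recess_gap
                 - spec.trabeculation_depth / 2.0)
        for j, seg in enumerate(seg_ids):
            a0 = spec.reference_angle + j * width
            tc = 0.0
            if have and c_local > 0:
                for ck, w in zip(ridge_centers, ridge_widths):
                    hw = math.degrees(w / 2.0 / max(r_mid, 1e-6))
                    if _intervals_overlap_circular(a0, a0 + width,
                                                   ck - hw, ck + hw):
                        tc = nc / c_local
                        break
            out[seg] = tc
    return out


# ---------------------------------------------------------------------------
# transmural slab samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransmuralSampleSpec:
    """A transmural wall slab: compact layer then ``n_trabeculae`` trabecular
    sheets separated by recesses along the transmural (x) axis.

    Each sheet covers a random sub-interval of the lateral (y) extent, so
    different trajectories through the same sample can cross different
    numbers of sheets, as on a real section.  z is the slice direction.
    """

    compact_thickness: float = 8.0
    n_trabeculae: int = 8
    width_range: tuple[float, float] = (0.4, 2.0)
    gap_range: tuple[float, float] = (0.3, 1.5)
    lateral_extent: float = 12.0
    slice_extent: float = 16.0
    sheet_coverage: tuple[float, float] = (0.7, 1.0)
    # the wall is sheared so trabecular sheets meet the section obliquely,
    # as on real cuts; transmural run lengths are unaffected but distinct
    # trajectories see the structure at different positions
    shear_range: tuple[float, float] = (0.1, 0.3)
    epi_margin: float = 1.0
    lumen_margin: float = 4.0
    generation_voxel: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_range[0] <= 0 or self.gap_range[0] <= 0:
            raise ValueError("widths and gaps must be positive")
        if self.generation_voxel > self.width_range[0] / 3.0:
            raise ValueError("generation_voxel must be <= min width / 3")
        if self.compact_thickness <= 0:
            raise ValueError("compact_thickness must be positive")


@dataclass
class SampleTruth:
    """Exact run structure of a transmural slab sample."""

    compact_thickness: float
    compact_x0: float
    sheets: list[dict]          # x0, x1, y0, y1, width, gap per sheet
    x_total: float
    n_trabeculae: int
    spec: TransmuralSampleSpec

    def count_at(self, y: float) -> int:
        return sum(1 for s in self.sheets if s["y0"] <= y < s["y1"])

    def nc_at(self, y: float) -> float:
        covering = [s for s in self.sheets if s["y0"] <= y < s["y1"]]
        if not covering:
            return 0.0
        wall_end = self.compact_x0 + self.compact_thickness
        return max(s["x1"] for s in covering) - wall_end

    def tc_at(self, y: float) -> float:
        return self.nc_at(y) / self.compact_thickness


def generate_transmural_sample(
        spec: TransmuralSampleSpec) -> tuple[LabelVolume, SampleTruth]:
    """Generate a seeded transmural wall slab and its exact run structure."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trabeculae
    widths = rng.uniform(*spec.width_range, size=n)
    gaps = rng.uniform(*spec.gap_range, size=n)
    cov = rng.uniform(*spec.sheet_coverage, size=n)
    Y = spec.lateral_extent
    offs = rng.uniform(0.0, np.maximum(Y * (1.0 - cov), 1e-9))
    shear = float(rng.uniform(*spec.shear_range) * rng.choice((-1.0, 1.0)))

    v = spec.generation_voxel
    x0 = spec.epi_margin
    sheets = []
    cur = x0 + spec.compact_thickness
    for i in range(n):
        sx0 = cur + gaps[i]
        sx1 = sx0 + widths[i]
        sheets.append({"x0": sx0, "x1": sx1,
                       "y0": float(offs[i]), "y1": float(offs[i] + cov[i] * Y),
                       "width": float(widths[i]), "gap": float(gaps[i])})
        cur = sx1
    # a margin absorbs the shear so the structure never leaves the grid
    shear_pad = abs(shear) * Y / 2.0
    x_total = cur + spec.lumen_margin + 2.0 * shear_pad

    nx = int(math.ceil(x_total / v))
    nyv = int(math.ceil(Y / v))
    nzv = int(math.ceil(spec.slice_extent / v))
    xc = (np.arange(nx) + 0.5) * v
    yc = (np.arange(nyv) + 0.5) * v
    # pure shear of the section: x_eff is the transmural coordinate in the
    # sheared frame; run lengths along any x trajectory are unchanged
    x_eff = xc[:, None] - shear * (yc - Y / 2.0)[None, :] - shear_pad

    plane = np.zeros((nx, nyv), dtype=np.uint8)
    plane[(x_eff >= x0) & (x_eff < x0 + spec.compact_thickness)] = \
        Label.LV_COMPACT
    plane[x_eff >= x0 + spec.compact_thickness] = Label.LV_LUMEN
    for s in sheets:
        ysel = (yc >= s["y0"]) & (yc < s["y1"])
        xsel = (x_eff >= s["x0"]) & (x_eff < s["x1"])
        plane[xsel & ysel[None, :]] = Label.LV_TRABECULAR
    # recesses between sheets remain lumen by construction
    grid = np.repeat(plane[:, :, None], nzv, axis=2)

    vol = LabelVolume(grid=grid, spacing=(v, v, v))
    truth = SampleTruth(compact_thickness=spec.compact_thickness,
                        compact_x0=x0, sheets=sheets, x_total=x_total,
                        n_trabeculae=n, spec=spec)
    return vol, truth


# ---------------------------------------------------------------------------
# histology-like 2D rendering
# ---------------------------------------------------------------------------

@dataclass
class Section:
    """A 2D binary tissue image of one plane, at a stated pixel size."""

    image: np.ndarray            # uint8, 1 = myocardium
    px_mm: float
    axis: int                    # normal axis of the plane (0, 1 or 2)
    position_mm: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def render_histology_section(vol: LabelVolume, axis: int = 2,
                             position_mm: float | None = None,
                             px_per_mm: float = 258.0) -> Section:
    """Render one axis-aligned plane as a binary tissue image.

    The plane normal is ``axis``; ``position_mm`` selects where along that
    axis (defaults to the mid-plane).  Pixel size is ``1/px_per_mm``, the
    plane geometry is sampled from the nearest label voxel.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    ext = vol.extent_mm()
    if position_mm is None:
        position_mm = ext[axis] / 2.0
    if not (0.0 <= position_mm < ext[axis]):
        raise ValueError("section plane lies outside the volume")
    k = int(position_mm / vol.spacing[axis])
    sl = np.take(vol.grid, k, axis=axis)
    sl_spacing = [s for i, s in enumerate(vol.spacing) if i != axis]
    if vol.binary:
        myo = sl > 0
    else:
        from .volume import TISSUE_LABELS
        myo = np.isin(sl, TISSUE_LABELS)

    p = 1.0 / px_per_mm
    n0 = int(math.floor(sl.shape[0] * sl_spacing[0] / p))
    n1 = int(math.floor(sl.shape[1] * sl_spacing[1] / p))
    i0 = np.minimum(((np.arange(n0) + 0.5) * p / sl_spacing[0]).astype(np.int64),
                    sl.shape[0] - 1)
    i1 = np.minimum(((np.arange(n1) + 0.5) * p / sl_spacing[1]).astype(np.int64),
                    sl.shape[1] - 1)
    img = myo[np.ix_(i0, i1)].astype(np.uint8)
    return Section(image=img, px_mm=p, axis=axis, position_mm=position_mm)


def section_as_volume(section: Section) -> LabelVolume:
    """Wrap a 2D section as a one-slice binary LabelVolume so the transmural
    measurement operations apply unchanged."""
    grid = section.image[:, :, None]
    p = section.px_mm
    return LabelVolume(grid=grid, spacing=(p, p, p), binary=True)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

# Construction classes.  `duty` is the target fraction of the trabeculated
# sector arc occupied by ridges; widths are derived from it so the classes
# sit well clear of the diagnostic thresholds (T/C 2.3, volume 25 %):
# normal ~ T/C 0.5, abnormal ~ T/C 1.8 with fraction < 25 %, ET ~ T/C 3.0
# with fraction > 25 %.
COHORT_CLASS_PARAMS: dict[str, dict] = {
    "normal": dict(radius=(13.0, 15.0), compact=(3.4, 4.2),
                   depth_frac=(0.50, 0.60), gap_frac=0.105,
                   duty=0.48, n_trab=18),
    "abnormal": dict(radius=(14.0, 16.0), compact=(2.6, 3.2),
                     depth_frac=(1.25, 1.40), gap_frac=0.30,
                     duty=0.38, n_trab=14),
    "excessively_trabeculated": dict(radius=(17.0, 19.0), compact=(2.0, 2.4),
                                     depth_frac=(2.65, 2.75), gap_frac=0.30,
                                     duty=0.40, n_trab=12),
}


def _cohort_spec(group: str, rng: np.random.Generator,
                 generation_voxel: float, rv_present: bool,
                 trab_scale: float = 1.0,
                 rv_trab_scale: float = 1.0) -> PhantomSpec:
    p = COHORT_CLASS_PARAMS[group]
    r0 = rng.uniform(*p["radius"])
    c = rng.uniform(*p["compact"])
    depth = rng.uniform(*p["depth_frac"]) * c * trab_scale
    gap = p["gap_frac"] * c
    n = p["n_trab"]
    sector = 300.0
    r_mid_ref = (r0 - c) * 0.95 - gap - depth / 2.0
    pitch_rad = math.radians(sector) / n
    w_mean = p["duty"] * pitch_rad * r_mid_ref
    w_mean = max(w_mean, 3.2 * generation_voxel / 0.85)
    rv_depth = max(1.2, 2.0 * rv_trab_scale)
    return PhantomSpec(
        lv_epicardial_radius=r0,
        lv_length=2.0 * r0,
        compact_thickness=c,
        n_trabeculations=n,
        trabeculation_width=(0.85 * w_mean, 1.15 * w_mean),
        trabeculation_depth=depth,
        recess_gap=gap,
        papillary_radius=max(1.0, 0.15 * (r0 - c)),
        rv_present=rv_present,
        rv_trabeculation_depth=rv_depth,
        generation_voxel=generation_voxel,
        seed=int(rng.integers(2 ** 31)),
    )


def make_cohort(n_normal: int, n_abnormal: int, n_et: int, seed: int,
                generation_voxel: float = 0.15,
                rv_present: bool = True) -> list[tuple[LabelVolume, GroundTruth]]:
    """Generate a cohort of phantoms in three construction classes.

    Excessively trabeculated (ET) phantoms satisfy, by truth, segment max
    T/C > 2.3 and trabecular fraction > 25 %; normal phantoms satisfy
    neither; abnormal phantoms are intermediate (more trabeculated than
    normal, below both thresholds).
    """
    if min(n_normal, n_abnormal, n_et) < 0:
        raise ValueError("cohort counts must be non-negative")
    rng = np.random.default_rng(seed)
    cohort = []
    for group, count in (("normal", n_normal), ("abnormal", n_abnormal),
                         ("excessively_trabeculated", n_et)):
        for _ in range(count):
            spec = _cohort_spec(group, rng, generation_voxel, rv_present)
            vol, gt = generate_phantom(spec)
            gt.group = group
            cohort.append((vol, gt))
    return cohort


def make_lvrv_cohort(n_hearts: int, coupling: float, seed: int,
                     generation_voxel: float = 0.15
                     ) -> list[tuple[LabelVolume, GroundTruth]]:
    """Cohort for the LV-RV correlation study.

    ``coupling`` in [0, 1] is the share of a latent per-heart factor common
    to LV and RV trabecular extent: 0 makes the two ventricles' trabecular
    volumes independent, 1 drives them from the same factor.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cohort = []
    groups = ["normal", "abnormal", "excessively_trabeculated"]
    for i in range(n_hearts):
        f = rng.normal()
        e_lv, e_rv = rng.normal(), rng.normal()
        z_lv = math.sqrt(coupling) * f + math.sqrt(1 - coupling) * e_lv
        z_rv = math.sqrt(coupling) * f + math.sqrt(1 - coupling) * e_rv
        lv_scale = float(np.exp(0.18 * z_lv))
        rv_scale = float(np.exp(0.30 * z_rv))
        group = groups[i % 3]
        spec = _cohort_spec(group, rng, generation_voxel, rv_present=True,
                            trab_scale=lv_scale, rv_trab_scale=rv_scale)
        vol, gt = generate_phantom(spec)
        gt.group = group
        cohort.append((vol, gt))
    return cohort
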