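"""Phantom generator: truth bookkeeping, invariants, error contracts."""

import numpy as np
import pytest
from scipy import ndimage

from trabscope.morphometry import circumferential_profile
from trabscope.phantom import (PhantomSpec, TransmuralSampleSpec,
                               generate_phantom, generate_transmural_sample,
                               make_cohort, render_histology_section)
from trabscope.volume import Label


def test_no_trabeculae_gives_zero_fraction_and_counts():
    spec = PhantomSpec(lv_epicardial_radius=10, lv_length=20,
                       compact_thickness=3.0, n_trabeculations=0,
                       papillary_count=0, rv_present=False,
                       generation_voxel=0.25, seed=0)
    vol, gt = generate_phantom(spec)
    assert gt.true_trab_fraction_lv == 0.0
    assert gt.true_volumes["lv_trabecular"] == 0.0
    assert all(v == 0 for v in gt.true_count_by_trajectory.values())
    assert max(gt.segment_truth.values()) == 0.0


def test_absent_rv_has_zero_rv_volumes(small_phantom):
    _, gt = small_phantom
    assert gt.true_volumes["rv_compact"] == 0.0
    assert gt.true_volumes["rv_trabecular"] == 0.0
    assert gt.true_volumes["rv_lumen"] == 0.0


def test_rv_present_has_positive_rv_volumes(rv_phantom):
    _, gt = rv_phantom
    assert gt.true_volumes["rv_compact"] > 0
    assert gt.true_volumes["rv_trabecular"] > 0


def test_determinism_bit_identical():
    spec = PhantomSpec(lv_epicardial_radius=9, lv_length=18,
                       compact_thickness=2.8, n_trabeculations=8,
                       trabeculation_width=(0.9, 1.2), papillary_radius=1.0,
                       rv_present=False, generation_voxel=0.25, seed=42)
    v1, g1 = generate_phantom(spec)
    v2, g2 = generate_phantom(spec)
    assert np.array_equal(v1.grid, v2.grid)
    assert g1.true_volumes == g2.true_volumes


def test_label_conservation(small_phantom):
    vol, gt = small_phantom
    total = vol.grid.size * vol.voxel_volume_ml
    assert sum(gt.true_volumes.values()) == pytest.approx(total, rel=1e-12)


def test_trab_fraction_definition(small_phantom):
    _, gt = small_phantom
    t = gt.true_volumes["lv_trabecular"]
    c = gt.true_volumes["lv_compact"]
    assert gt.true_trab_fraction_lv == pytest.approx(100 * t / (t + c))


def test_compact_shell_disconnects_lumen_per_slice(small_phantom):
    # removing lv_compact must disconnect the lumen from the outside in
    # every short-axis slice with a cavity (the base plane itself is open)
    vol, _ = small_phantom
    lumen_any = vol.label_mask(Label.LV_LUMEN).any(axis=(0, 1))
    ks = np.flatnonzero(lumen_any)
    for k in ks[:: max(len(ks) // 8, 1)]:
        sl = vol.grid[:, :, k]
        passable = sl != Label.LV_COMPACT
        lab, _ = ndimage.label(passable)
        border = set(np.concatenate([lab[0, :], lab[-1, :],
                                     lab[:, 0], lab[:, -1]]).tolist())
        lumen_ids = set(np.unique(lab[sl == Label.LV_LUMEN]).tolist())
        assert not (lumen_ids & border), f"lumen leaks at slice {k}"


def test_circumferential_count_matches_spec(small_phantom):
    # 12 ridges -> 12 myocardial runs on the mid-trabecular circle,
    # against the exhaustive run-count on the generated grid
    vol, gt = small_phantom
    circ = gt.circ_trajectory
    prof = circumferential_profile(vol, circ["radius_mm"], circ["z_mm"])
    assert len(prof.myo_runs()) == gt.n_trabeculations == 12


def test_outflow_sector_has_no_trabecular_voxels(small_phantom):
    vol, gt = small_phantom
    spec = gt.spec
    nx, ny, _ = vol.shape
    xs = (np.arange(nx) + 0.5) * vol.spacing[0] - nx * vol.spacing[0] / 2
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    theta = np.degrees(np.arctan2(Y, X)) % 360.0
    u = (theta - spec._outflow_end) % 360.0
    in_outflow = u >= spec._sector_deg
    trab = vol.label_mask(Label.LV_TRABECULAR)
    # papillary muscles are placed in the trabeculated sector, so any
    # trabecular voxel in the outflow wedge would be a ridge leak
    assert not (trab & in_outflow[:, :, None]).any()


def test_overlapping_ridges_rejected():
    with pytest.raises(ValueError, match="overlap"):
        PhantomSpec(lv_epicardial_radius=8, lv_length=16,
                    compact_thickness=2.5, n_trabeculations=40,
                    trabeculation_width=(1.2, 1.5), trabeculation_depth=2.0,
                    generation_voxel=0.2, rv_present=False)


def test_unrepresentable_voxel_rejected():
    with pytest.raises(ValueError, match="generation_voxel"):
        PhantomSpec(trabeculation_width=(0.4, 0.6), generation_voxel=0.2)


def test_depth_exceeding_lumen_rejected():
    with pytest.raises(ValueError, match="depth"):
        PhantomSpec(lv_epicardial_radius=8, compact_thickness=3.0,
                    trabeculation_depth=6.0, generation_voxel=0.2)


class TestCohort:
    def test_counts_and_construction_classes(self):
        cohort = make_cohort(1, 1, 2, seed=11, rv_present=False)
        assert len(cohort) == 4
        groups = [gt.group for _, gt in cohort]
        assert groups == ["normal", "abnormal",
                          "excessively_trabeculated",
                          "excessively_trabeculated"]
        for _, gt in cohort:
            max_tc = max(gt.segment_truth.values())
            frac = gt.true_trab_fraction_lv
            if gt.group == "excessively_trabeculated":
                assert frac > 25.0 and max_tc > 2.3
            else:
                assert frac < 25.0 and max_tc < 2.3

    def test_single_normal_below_thresholds(self):
        cohort = make_cohort(1, 0, 0, seed=0, rv_present=False)
        _, gt = cohort[0]
        assert all(v < 2.3 for v in gt.segment_truth.values())

    def test_same_seed_identical(self):
        a = make_cohort(1, 0, 1, seed=5, rv_present=False)
        b = make_cohort(1, 0, 1, seed=5, rv_present=False)
        for (va, _), (vb, _) in zip(a, b):
            assert np.array_equal(va.grid, vb.grid)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(-1, 0, 0, seed=0)


class TestTransmuralSample:
    def test_truth_structure(self, slab_sample):
        vol, truth = slab_sample
        assert truth.n_trabeculae == len(truth.sheets)
        y = vol.extent_mm()[1] / 2.0
        count = truth.count_at(y)
        assert 0 <= count <= truth.n_trabeculae
        if count > 0:
            assert truth.nc_at(y) > 0
            assert truth.tc_at(y) == pytest.approx(
                truth.nc_at(y) / truth.compact_thickness)
        covering = [s for s in truth.sheets if s["y0"] <= y < s["y1"]]
        assert count == len(covering)

    def test_determinism(self):
        spec = TransmuralSampleSpec(seed=9)
        v1, _ = generate_transmural_sample(spec)
        v2, _ = generate_transmural_sample(spec)
        assert np.array_equal(v1.grid, v2.grid)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TransmuralSampleSpec(width_range=(0.2, 0.5),
                                 generation_voxel=0.1)


class TestHistologySection:
    def test_identity_at_generation_resolution(self, slab_sample):
        vol, _ = slab_sample
        px_per_mm = 1.0 / vol.spacing[0]
        sec = render_histology_section(vol, axis=2, px_per_mm=px_per_mm)
        k = int((vol.extent_mm()[2] / 2.0) / vol.spacing[2])
        expected = (vol.grid[:, :, k] > 0) & \
            np.isin(vol.grid[:, :, k], (2, 3))
        assert np.array_equal(sec.image.astype(bool), expected)

    def test_pixel_size(self, slab_sample):
        vol, _ = slab_sample
        sec = render_histology_section(vol, px_per_mm=258.0)
        assert sec.px_mm == pytest.approx(1.0 / 258.0)

    def test_ring_section_components(self, small_phantom):
        # a plane through the ridge ring shows the 12 ridges as disjoint
        # interior components (plus 2 papillary muscles where present)
        vol, gt = small_phantom
        z = gt.circ_trajectory["z_mm"]
        sec = render_histology_section(vol, axis=2, position_mm=z,
                                       px_per_mm=5.0)
        lab, n = ndimage.label(sec.image)
        sizes = np.bincount(lab.ravel())[1:]
        # ring + 12 ridges (papillaries live higher up the long axis)
        assert n == 13

    def test_plane_outside_rejected(self, slab_sample):
        vol, _ = slab_sample
        with pytest.raises(ValueError):
            render_histology_section(vol, axis=2, position_mm=1e3)
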