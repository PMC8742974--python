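"""Transmural measurement: profiles, counting, layers, classification,
Cavalieri volumes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_annulus, make_annulus_with_ridges
from trabscope.morphometry import (EmptyProfileError, TransmuralProfile,
                                   axial_trajectory, cavalieri_volumes,
                                   classify_compartments,
                                   count_runs_brute_force,
                                   count_trabeculations, extract_profile,
                                   measure_layers, radial_trajectory)
from trabscope.volume import Label, LabelVolume


def profile(*runs):
    return TransmuralProfile(runs=list(runs), step=0.05)


class TestCounting:
    def test_compact_only_counts_zero(self):
        assert count_trabeculations(profile(("myo", 8.0))) == 0

    def test_definition_two_trabeculations(self):
        p = profile(("myo", 5), ("nonmyo", 1), ("myo", 1),
                    ("nonmyo", 1), ("myo", 1))
        assert count_trabeculations(p) == 2

    def test_empty_profile_raises(self):
        with pytest.raises(EmptyProfileError):
            count_trabeculations(TransmuralProfile(runs=[], step=0.05))


class TestMeasureLayers:
    def test_compact_only(self):
        m = measure_layers(profile(("myo", 10.0)))
        assert (m.C, m.NC, m.TC, m.count) == (10.0, 0.0, 0.0, 0)

    def test_tc_at_diagnostic_threshold(self):
        # C = 2 mm with a 4.6 mm trabecular span sits exactly at T/C = 2.3
        p = profile(("myo", 2.0), ("nonmyo", 1.6), ("myo", 3.0))
        m = measure_layers(p)
        assert m.TC == pytest.approx(2.3)

    def test_extreme_ratio_representable(self):
        # the format must carry ratios as large as the most excessively
        # trabeculated case on record (max T/C 8.5)
        p = profile(("myo", 2.0), ("nonmyo", 14.0), ("myo", 3.0))
        assert measure_layers(p).TC == pytest.approx(8.5)

    def test_recesses_counted_in_span_not_removed(self):
        p = profile(("myo", 4.0), ("nonmyo", 2.0), ("myo", 1.0),
                    ("nonmyo", 3.0), ("myo", 1.0), ("nonmyo", 5.0))
        m = measure_layers(p)
        assert m.NC == pytest.approx(7.0)   # trailing lumen excluded

    @given(st.lists(st.floats(0.1, 5.0), min_size=1, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_invariants_on_random_profiles(self, lengths):
        runs = [("myo" if i % 2 == 0 else "nonmyo", ln)
                for i, ln in enumerate(lengths)]
        m = measure_layers(TransmuralProfile(runs=runs, step=0.05))
        assert m.TC == pytest.approx(m.NC / m.C)
        assert (m.NC == 0) == (m.count == 0)
        assert m.count >= 0 and m.C > 0


class TestExtractProfile:
    def test_pure_annulus_single_run(self):
        vol = make_annulus()
        traj = radial_trajectory(vol, 40.0, vol.extent_mm()[2] / 2)
        p = extract_profile(vol, traj)
        assert [t for t, _ in p.runs if t == "myo"] == ["myo"]
        m = measure_layers(p)
        assert m.C == pytest.approx(4.0, abs=2 * vol.spacing[0])

    def test_annulus_with_ridge_three_runs(self):
        vol = make_annulus_with_ridges(n_ridges=8, gap=0.6, depth=1.5,
                                       width=1.2)
        # aim straight through the centre of ridge 0 (pitch 45 deg)
        traj = radial_trajectory(vol, 22.5, vol.extent_mm()[2] / 2)
        p = extract_profile(vol, traj)
        m = measure_layers(p)
        assert m.count == 1
        assert m.C == pytest.approx(4.0, abs=0.25)
        assert m.NC == pytest.approx(0.6 + 1.5, abs=0.25)

    def test_outflow_ray_counts_zero(self, small_phantom):
        vol, gt = small_phantom
        traj = radial_trajectory(vol, gt.spec.outflow_center,
                                 gt.circ_trajectory["z_mm"])
        p = extract_profile(vol, traj)
        assert count_trabeculations(p) == 0

    def test_missing_wall_raises(self):
        grid = np.zeros((10, 10, 4), dtype=np.uint8)
        vol = LabelVolume(grid=grid, spacing=(1, 1, 1))
        traj = axial_trajectory(vol, y_mm=5.0, z_mm=2.0)
        with pytest.raises(EmptyProfileError):
            extract_profile(vol, traj)


class TestOracleEquivalence:
    def test_counts_match_brute_force_on_random_rays(self, small_phantom):
        # run-length counting and direct interval counting on the sampled
        # boolean sequence must agree exactly
        vol, gt = small_phantom
        rng = np.random.default_rng(0)
        z = gt.circ_trajectory["z_mm"]
        for ang in rng.uniform(0, 360, size=60):
            traj = radial_trajectory(vol, float(ang), z)
            pts = traj.points()
            myo = np.isin(vol.sample(pts), (2, 3, 5, 6))
            if not myo.any():
                continue
            p = extract_profile(vol, traj)
            assert count_trabeculations(p) == \
                count_runs_brute_force(myo[np.argmax(myo):])


class TestClassification:
    def test_pure_annulus_fully_compact(self):
        vol = make_annulus(voxel=0.2, nz=6)
        res = classify_compartments(vol)
        myo = vol.myocardium_mask()
        assert (res.volume.grid[myo] == Label.LV_COMPACT).all()
        assert not res.has_gaps

    def test_ridges_classified_trabecular_within_one_voxel(self):
        vol = make_annulus_with_ridges(voxel=0.15, nz=4)
        res = classify_compartments(vol)
        truth_trab = vol.label_mask(Label.LV_TRABECULAR)
        got_trab = res.volume.label_mask(Label.LV_TRABECULAR)
        mismatch = truth_trab ^ got_trab
        # disagreements are confined to the compartment boundary: flood-fill
        # truth against classification differs by less than one voxel layer
        from scipy import ndimage
        boundary = ndimage.binary_dilation(truth_trab) & ~truth_trab \
            | (ndimage.binary_erosion(truth_trab) ^ truth_trab)
        assert mismatch.sum() <= max(boundary.sum(), 1)
        frac_true = truth_trab.sum() / (truth_trab.sum()
                                        + vol.label_mask(Label.LV_COMPACT).sum())
        got_c = res.volume.label_mask(Label.LV_COMPACT)
        frac_got = got_trab.sum() / (got_trab.sum() + got_c.sum())
        assert abs(frac_got - frac_true) < 0.02

    def test_recesses_remain_lumen(self):
        vol = make_annulus_with_ridges(voxel=0.15, nz=4)
        res = classify_compartments(vol)
        lumen_true = vol.label_mask(Label.LV_LUMEN)
        assert (res.volume.grid[lumen_true] != Label.LV_COMPACT).all()
        assert (res.volume.grid[lumen_true] != Label.LV_TRABECULAR).all()

    def test_broken_ring_flagged(self):
        vol = make_annulus(voxel=0.25, nz=4)
        g = vol.grid.copy()
        g[g.shape[0] // 2:, g.shape[1] // 2, :] = 0   # transmural cut
        g[g == Label.LV_LUMEN] = 0
        broken = LabelVolume(grid=g, spacing=vol.spacing)
        res = classify_compartments(broken)
        assert res.has_gaps


class TestCavalieri:
    def test_cylindrical_shell_exact(self):
        vol = make_annulus(voxel=0.25, nz=80)
        vr = cavalieri_volumes(vol, n_slices=10)
        exact = vol.volume_ml(Label.LV_COMPACT)
        assert vr.lv_compact == pytest.approx(exact, rel=1e-12)

    def test_all_slices_equals_voxel_count(self):
        vol = make_annulus(voxel=0.25, nz=40)
        vr = cavalieri_volumes(vol, n_slices=40)
        assert vr.lv_compact == pytest.approx(
            vol.volume_ml(Label.LV_COMPACT), rel=1e-12)

    def test_minimum_slices_enforced(self):
        vol = make_annulus(nz=30)
        with pytest.raises(ValueError, match="minimum"):
            cavalieri_volumes(vol, n_slices=9)

    def test_report_consistency(self, rv_phantom):
        vol, _ = rv_phantom
        vr = cavalieri_volumes(vol, n_slices=12)
        assert vr.lv_trab_fraction == pytest.approx(
            100 * vr.lv_trab / (vr.lv_trab + vr.lv_compact))
        assert vr.total_ventricles == pytest.approx(
            vr.lv_trab + vr.lv_compact + vr.rv_trab + vr.rv_compact)
        assert vr.rv_lv_ratio > 0
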