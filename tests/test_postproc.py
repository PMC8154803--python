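"""Rule-based post-processing steps and the tAB/AC/IC surface partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cartiq as cq
from conftest import CORONAL_AXES, make_volume


def slab_volume(rows, cols, n_slices=1, plate=cq.MT, shape=(16, 20)):
    vox = np.zeros((*shape, n_slices), np.int16)
    vox[np.ix_(rows, cols, range(n_slices))] = plate
    return make_volume(vox)


class TestFillGaps:
    def test_center_hole_filled(self):
        vox = np.zeros((9, 9, 1), np.int16)
        vox[2:7, 2:7, 0] = cq.MT
        vox[4, 4, 0] = 0
        out = cq.fill_gaps(make_volume(vox))
        assert np.count_nonzero(out.voxels) == 25

    def test_no_enclosed_regions_identity(self, flash_phantom):
        out = cq.fill_gaps(flash_phantom.truth.clean_labels)
        np.testing.assert_array_equal(
            out.voxels, flash_phantom.truth.clean_labels.voxels)

    def test_max_area_threshold(self):
        # ring around a 5x6 = 30 px hole
        vox = np.zeros((11, 12, 1), np.int16)
        vox[1:8, 1:9, 0] = cq.MT
        vox[2:7, 2:8, 0] = 0
        vol = make_volume(vox)
        kept = cq.fill_gaps(vol, max_area=25)
        np.testing.assert_array_equal(kept.voxels, vox)
        filled = cq.fill_gaps(vol, max_area=30)
        assert np.count_nonzero(filled.voxels) == 7 * 8

    def test_gap_between_two_plates_untouched(self):
        vox = np.zeros((9, 9, 1), np.int16)
        vox[2:7, 2:7, 0] = cq.MT
        vox[3:6, 3:6, 0] = cq.LT
        vox[4, 4, 0] = 0     # hole bordered by LT only
        out = cq.fill_gaps(make_volume(vox))
        assert out.voxels[4, 4, 0] == cq.LT

    def test_foreground_never_decreases(self, dess_phantom):
        before = np.count_nonzero(dess_phantom.labels.voxels)
        out = cq.fill_gaps(dess_phantom.labels)
        assert np.count_nonzero(out.voxels) >= before


class TestRemoveDisconnected:
    def test_distant_blob_removed(self):
        vox = np.zeros((10, 10, 30), np.int16)
        vox[3:7, 3:7, 5:16] = cq.MT          # main slab
        vox[1:3, 1:5, 25] = cq.MT            # 8-voxel blob far away
        out = cq.remove_disconnected(make_volume(vox))
        assert not out.voxels[:, :, 25].any()
        assert np.count_nonzero(out.voxels) == 4 * 4 * 11

    def test_single_component_identity(self, flash_phantom):
        clean = flash_phantom.truth.clean_labels
        out = cq.remove_disconnected(clean)
        np.testing.assert_array_equal(out.voxels, clean.voxels)

    def test_equal_size_tie_keeps_smallest_min_index(self):
        vox = np.zeros((10, 10, 5), np.int16)
        vox[1:3, 1:3, 1] = cq.MT             # min voxel (1,1,1)
        vox[6:8, 6:8, 3] = cq.MT             # equal size, larger min index
        out = cq.remove_disconnected(make_volume(vox))
        assert out.voxels[1, 1, 1] == cq.MT
        assert not out.voxels[:, :, 3].any()

    def test_keep_fraction_retains_secondary(self):
        vox = np.zeros((10, 10, 30), np.int16)
        vox[3:7, 3:7, 5:16] = cq.MT
        vox[1:4, 1:5, 25:28] = cq.MT          # 36 voxels vs 176
        out = cq.remove_disconnected(make_volume(vox), keep_fraction=0.1)
        assert out.voxels[:, :, 25].any()


class TestSmoothSpikes:
    def test_one_wide_tail_pruned(self):
        vox = np.zeros((12, 14, 1), np.int16)
        vox[2:7, 2:7, 0] = cq.MT
        vox[4, 7:10, 0] = cq.MT             # 3-pixel one-wide tail
        out = cq.smooth_spikes(make_volume(vox))
        assert np.count_nonzero(out.voxels) == 25
        assert not out.voxels[4, 7:10, 0].any()

    def test_solid_rectangle_unchanged(self):
        vol = slab_volume(range(3, 8), range(4, 12))
        out = cq.smooth_spikes(vol)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_idempotent_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        vox = (rng.random((12, 12, 2)) < 0.45).astype(np.int16) * cq.MT
        vol = make_volume(vox)
        once = cq.smooth_spikes(vol)
        twice = cq.smooth_spikes(once)
        np.testing.assert_array_equal(once.voxels, twice.voxels)
        assert np.count_nonzero(once.voxels) <= np.count_nonzero(vox)


class TestRoiCut:
    @pytest.mark.parametrize("notch,post,frac,expected", [
        (0.0, 50.0, 0.6, 30.0),
        (10.0, 110.0, 0.6, 70.0),
        (0.0, 50.0, 1.0, 50.0),
        (50.0, 0.0, 0.6, 20.0),     # reversed axis direction
    ])
    def test_cut_position(self, notch, post, frac, expected):
        assert cq.roi_cut_position(notch, post, frac) == pytest.approx(expected)

    def test_invalid_fraction(self):
        for frac in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                cq.roi_cut_position(0.0, 50.0, frac)

    def test_coincident_landmarks(self):
        with pytest.raises(ValueError):
            cq.roi_cut_position(5.0, 5.0, 0.6)


class TestApplyFemoralRoi:
    def _fem_volume(self, n_slices=55):
        vox = np.zeros((10, 10, n_slices), np.int16)
        vox[3:6, 2:8, :50] = cq.CMF          # AP positions 0..49 mm
        vox[7:9, 2:8, :50] = cq.MT
        return make_volume(vox)

    def test_posterior_overhang_removed(self):
        vol = self._fem_volume()
        meta = cq.KneeMetadata(landmarks={"cMF": {"notch_mm": 0.0,
                                                  "posterior_mm": 50.0}})
        out = cq.apply_femoral_roi(vol, meta)
        kept = np.where((out.voxels == cq.CMF).any(axis=(0, 1)))[0]
        extent = (kept.max() - kept.min() + 1) * vol.spacing[2]
        assert abs(extent - 30.0) <= vol.spacing[2] + 1e-9

    def test_tibial_plates_untouched(self):
        vol = self._fem_volume()
        meta = cq.KneeMetadata(landmarks={"cMF": {"notch_mm": 0.0,
                                                  "posterior_mm": 50.0}})
        out = cq.apply_femoral_roi(vol, meta)
        np.testing.assert_array_equal(out.voxels == cq.MT, vol.voxels == cq.MT)

    def test_all_inside_is_identity(self, flash_phantom):
        clean = flash_phantom.truth.clean_labels
        out = cq.apply_femoral_roi(clean, flash_phantom.meta)
        np.testing.assert_array_equal(out.voxels, clean.voxels)

    def test_missing_landmarks_rejected(self):
        vol = self._fem_volume()
        with pytest.raises(ValueError, match="landmarks"):
            cq.apply_femoral_roi(vol, cq.KneeMetadata())


class TestPartition:
    def test_two_row_slab_hand_enumerated(self):
        vol = slab_volume([4, 5], range(3, 13))
        part = cq.partition_surfaces(vol, cq.KneeMetadata())
        sp = part.slices(cq.MT)[0]
        # bottom row (inferior) is the bone interface, top row the surface
        assert {p for p in sp.tab if p[0] == 5} == {(5, c) for c in range(3, 13)}
        assert {p for p in sp.ac if p[0] == 4} == {(4, c) for c in range(3, 13)}
        # the two farthest points are shared corners
        assert set(sp.endpoints) == {(4, 3), (5, 12)}
        assert all(e in sp.tab and e in sp.ac for e in sp.endpoints)
        assert sp.ic == []

    def test_partition_identity_on_phantoms(self, flash_processed,
                                            dess_processed):
        for clean, part in (flash_processed, dess_processed):
            for plate, slices in part.plates.items():
                mask = clean.voxels == plate
                for k, sp in slices.items():
                    count = int(np.count_nonzero(mask[:, :, k]))
                    got = sum(len(set(p.tab)) + len(set(p.ac))
                              - len(set(p.endpoints)) + len(p.ic)
                              for p in (sp, *sp.extra))
                    assert got == count

    def test_surfaces_disjoint_except_endpoints(self, dess_processed):
        _, part = dess_processed
        for slices in part.plates.values():
            for sp in slices.values():
                if sp.degenerate:
                    continue
                shared = set(sp.tab) & set(sp.ac)
                assert shared == set(sp.endpoints)

    def test_farthest_tie_on_circle_deterministic(self):
        vox = np.zeros((15, 15, 1), np.int16)
        ii, jj = np.ogrid[:15, :15]
        vox[(ii - 7) ** 2 + (jj - 7) ** 2 <= 25, :] = cq.MT
        vol = make_volume(vox)
        p1 = cq.partition_surfaces(vol, cq.KneeMetadata())
        p2 = cq.partition_surfaces(vol, cq.KneeMetadata())
        e1 = p1.slices(cq.MT)[0].endpoints
        assert e1 == p2.slices(cq.MT)[0].endpoints
        # tie resolved toward the lexicographically smallest index pair
        bpts = p1.slices(cq.MT)[0].tab + p1.slices(cq.MT)[0].ac
        d = max(np.hypot(a[0] - b[0], a[1] - b[1])
                for a in bpts for b in bpts)
        best = min(tuple(sorted((a, b))) for a in bpts for b in bpts
                   if np.hypot(a[0] - b[0], a[1] - b[1]) >= d - 1e-12)
        assert tuple(sorted(e1)) == best

    def test_single_voxel_plate_degenerate(self):
        vol = slab_volume([5], [5])
        part = cq.partition_surfaces(vol, cq.KneeMetadata())
        sp = part.slices(cq.MT)[0]
        assert sp.degenerate
        assert sp.tab == sp.ac == [(5, 5)]


class TestFullChain:
    def test_clean_phantom_is_noop(self, flash_phantom, flash_processed):
        clean, part = flash_processed
        np.testing.assert_array_equal(
            clean.voxels, flash_phantom.truth.clean_labels.voxels)
        assert part.plates.keys() == {1, 2, 3, 4}

    def test_defects_restored_exactly(self):
        for seed in range(3):
            cfg = cq.PhantomConfig(preset="flash", seed=seed,
                                   n_holes=2, n_blobs=1)
            ph = cq.generate_phantom(cfg)
            assert not np.array_equal(ph.labels.voxels,
                                      ph.truth.clean_labels.voxels)
            out, _ = cq.run_postprocessing(ph.labels, ph.meta)
            np.testing.assert_array_equal(out.voxels,
                                          ph.truth.clean_labels.voxels)

    def test_idempotence_under_noise(self):
        cfg = cq.PhantomConfig(preset="dess", shape=(64, 24, 64), seed=2)
        v1, v2 = cq.generate_followup_pair(cfg, 0.1, 0.1)
        once, _ = cq.run_postprocessing(v2.labels, v2.meta)
        twice, _ = cq.run_postprocessing(once, v2.meta)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_monotone_voxel_contracts(self):
        cfg = cq.PhantomConfig(preset="flash", seed=6, n_holes=1, n_blobs=2)
        ph = cq.generate_phantom(cfg)
        filled = cq.fill_gaps(ph.labels)
        assert np.count_nonzero(filled.voxels) >= np.count_nonzero(ph.labels.voxels)
        pruned = cq.remove_disconnected(filled)
        assert np.count_nonzero(pruned.voxels) <= np.count_nonzero(filled.voxels)
        smoothed = cq.smooth_spikes(pruned)
        assert np.count_nonzero(smoothed.voxels) <= np.count_nonzero(pruned.voxels)
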