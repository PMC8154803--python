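"""Slice preprocessing, class weights and toy U-Net training behaviour."""

import numpy as np
import pytest

import cartiq as cq
from cartiq.unet import _encode_target, _weighted_ce, UNet2D


class TestPreprocessSlice:
    def test_zscore(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100.0, 10.0, (64, 64))
        out = cq.preprocess_slice(x, corner=0)
        assert abs(out.mean()) < 1e-9
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_slice_returns_zeros(self):
        out = cq.preprocess_slice(np.full((40, 40), 7.0), corner=0)
        assert not out.any()
        # still degenerate when the only variation is the zeroed corners
        x = np.zeros((40, 40))
        x[:5, :5] = 123.0
        assert not cq.preprocess_slice(x, corner=5).any()

    def test_bright_corners_zeroed_before_stats(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50.0, 5.0, (64, 64))
        x[:15, :15] = x[:15, -15:] = x[-15:, :15] = x[-15:, -15:] = 1e4
        out = cq.preprocess_slice(x, corner=15)
        # hand-computed oracle: zero corners, then z-score the full slice
        ref = x.copy()
        ref[:15, :15] = ref[:15, -15:] = ref[-15:, :15] = ref[-15:, -15:] = 0.0
        expected = (ref - ref.mean()) / ref.std()
        np.testing.assert_allclose(out, expected, atol=1e-12)
        # corner pixels map to the z-score of zero, far from 1e4-dominated
        assert out[0, 0] == pytest.approx((0 - ref.mean()) / ref.std())
        assert abs(out[0, 0]) < 5.0

    def test_too_small_slice_rejected(self):
        with pytest.raises(ValueError):
            cq.preprocess_slice(np.zeros((20, 64)), corner=15)


class TestClassWeights:
    @pytest.mark.parametrize("n,expected", [(4, (1 / 9, 2 / 9)),
                                            (2, (0.2, 0.4)),
                                            (1, (1 / 3, 2 / 3))])
    def test_printed_formula(self, n, expected):
        assert cq.class_weights(n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 7])
    def test_foreground_background_ratio_is_two(self, n):
        bg, fg = cq.class_weights(n)
        assert fg / bg == pytest.approx(2.0, abs=1e-12)

    def test_zero_classes_rejected(self):
        with pytest.raises(ValueError):
            cq.class_weights(0)


class TestSliceFiltering:
    def test_only_segmented_slices_kept(self):
        slices = []
        for k in range(30):
            img = np.zeros((16, 16))
            lab = np.zeros((16, 16), np.int16)
            if k < 10:
                lab[5:8, 5:8] = cq.MT
            slices.append((img, lab))
        assert len(cq.filter_segmented(slices, (cq.MT,))) == 10

    def test_empty_training_set_rejected(self):
        empty = [(np.zeros((16, 16)), np.zeros((16, 16), np.int16))]
        cfg = cq.NetConfig(classes=(1,), slice_shape=(16, 16), epochs=1,
                           base_width=2, corner=0)
        with pytest.raises(ValueError, match="training"):
            cq.train_model(empty, [], cfg)


def _toy_slices(seed, n_phantoms=2):
    cfg = cq.PhantomConfig(preset="flash", shape=(32, 32, 6), seed=seed,
                           plates=("MT", "LT"))
    out = []
    for i in range(n_phantoms):
        ph = cq.generate_phantom(
            cq.PhantomConfig(preset="flash", shape=(32, 32, 6),
                             seed=seed + i, plates=("MT", "LT")))
        for k in range(6):
            out.append((ph.gray[:, :, k], ph.labels.voxels[:, :, k]))
    return cq.filter_segmented(out, (1, 3))


TOY_NET = dict(classes=(1, 3), slice_shape=(32, 32), base_width=4, corner=0)


class TestTraining:
    def test_loss_decreases(self):
        cfg = cq.NetConfig(epochs=5, seed=0, **TOY_NET)
        rec = cq.train_model(_toy_slices(0), _toy_slices(50, 1), cfg)
        assert rec.train_loss[-1] < rec.train_loss[0]

    def test_reproducible_for_fixed_seed(self):
        cfg = cq.NetConfig(epochs=2, seed=7, **TOY_NET)
        a = cq.train_model(_toy_slices(0), _toy_slices(50, 1), cfg)
        b = cq.train_model(_toy_slices(0), _toy_slices(50, 1), cfg)
        assert a.train_loss == b.train_loss
        assert a.val_dsc == b.val_dsc
        assert a.selected_epoch == b.selected_epoch
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])

    def test_selected_epoch_attains_best_dsc(self):
        cfg = cq.NetConfig(epochs=3, seed=1, **TOY_NET)
        rec = cq.train_model(_toy_slices(0), _toy_slices(50, 1), cfg)
        assert rec.val_dsc[rec.selected_epoch] == max(rec.val_dsc)

    def test_record_invariant_enforced(self):
        with pytest.raises(AssertionError):
            cq.TrainingRecord(train_loss=[1.0, 0.5], val_dsc=[0.9, 0.2],
                              selected_epoch=1, weights={},
                              config=cq.NetConfig(epochs=2, **TOY_NET))


class TestSegmentAndMerge:
    def test_labels_subset_of_configured(self):
        cfg = cq.NetConfig(epochs=1, seed=0, **TOY_NET)
        rec = cq.train_model(_toy_slices(0), [], cfg)
        ph = cq.generate_phantom(cq.PhantomConfig(
            preset="flash", shape=(32, 32, 6), seed=3, plates=("MT", "LT")))
        vol = cq.segment_volume(rec, ph.gray, ph.labels.spacing,
                                ph.labels.plane, ph.labels.axes)
        assert set(np.unique(vol.voxels)) <= {0, 1, 3}

    def test_shape_mismatch_rejected(self):
        cfg = cq.NetConfig(epochs=1, seed=0, **TOY_NET)
        rec = cq.train_model(_toy_slices(0), [], cfg)
        with pytest.raises(ValueError, match="shape"):
            cq.segment_volume(rec, np.zeros((16, 16, 2)), (1, 1, 1),
                              "coronal", {"row": "sup-inf", "col": "med-lat",
                                          "slice": "ant-post"})

    def test_merge_disjoint_is_union(self):
        vox_a = np.zeros((8, 8, 2), np.int16); vox_a[1:3, 1:3, 0] = cq.MT
        vox_b = np.zeros((8, 8, 2), np.int16); vox_b[5:7, 5:7, 1] = cq.LT
        axes = {"row": "sup-inf", "col": "med-lat", "slice": "ant-post"}
        a = cq.LabelVolume(vox_a, (1, 1, 1), "coronal", axes)
        b = cq.LabelVolume(vox_b, (1, 1, 1), "coronal", axes)
        merged = cq.merge_segmentations([(a, np.full(vox_a.shape, 0.9)),
                                         (b, np.full(vox_b.shape, 0.8))])
        assert np.count_nonzero(merged.voxels == cq.MT) == 4
        assert np.count_nonzero(merged.voxels == cq.LT) == 4

    def test_merge_conflict_higher_score_then_lower_label(self):
        axes = {"row": "sup-inf", "col": "med-lat", "slice": "ant-post"}
        vox_a = np.zeros((4, 4, 1), np.int16); vox_a[1, 1, 0] = cq.LT
        vox_b = np.zeros((4, 4, 1), np.int16); vox_b[1, 1, 0] = cq.MT
        a = cq.LabelVolume(vox_a, (1, 1, 1), "coronal", axes)
        b = cq.LabelVolume(vox_b, (1, 1, 1), "coronal", axes)
        pa, pb = np.full(vox_a.shape, 0.6), np.full(vox_b.shape, 0.9)
        assert cq.merge_segmentations([(a, pa), (b, pb)]).voxels[1, 1, 0] == cq.MT
        # equal scores: lower label id wins
        assert cq.merge_segmentations([(a, pa), (b, pa)]).voxels[1, 1, 0] == cq.MT

    def test_save_load_roundtrip(self, tmp_path):
        cfg = cq.NetConfig(epochs=1, seed=0, **TOY_NET)
        rec = cq.train_model(_toy_slices(0), _toy_slices(50, 1), cfg)
        cq.save_model(rec, tmp_path / "model")
        back = cq.load_model(tmp_path / "model")
        assert back.config == rec.config
        assert back.selected_epoch == rec.selected_epoch
        for k in rec.weights:
            np.testing.assert_array_equal(back.weights[k], rec.weights[k])


class TestLossFunction:
    def test_weighted_ce_matches_manual_computation(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(1, 3, 4, 4))
        target = rng.integers(0, 3, size=(1, 4, 4))
        w_bg, w_fg = cq.class_weights(2)
        loss, _ = _weighted_ce(logits, target, w_bg, w_fg)
        # manual: softmax + weighted mean of -log p_true
        z = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = z / z.sum(axis=1, keepdims=True)
        acc = wsum = 0.0
        for i in range(4):
            for j in range(4):
                t = target[0, i, j]
                w = w_fg if t > 0 else w_bg
                acc += w * -np.log(p[0, t, i, j])
                wsum += w
        assert loss == pytest.approx(acc / wsum, abs=1e-12)
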