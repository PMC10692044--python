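"""Cascade contracts: VOI restriction, training loop, two-stage invariants.

Training tests run on deliberately easy miniature phantoms (no noise, no
blur, tiny grids and networks) so they finish in seconds while still
exercising the real training loop.
"""

import warnings

import numpy as np
import pytest

from crlmvol.cascade import (
    CascadeModel,
    EmptyLiverError,
    ModelConfig,
    TrainedSegmenter,
    build_unet,
    postprocess_liver,
    predict_volume,
    restrict_to_liver,
    segment_cascade,
    train_model,
)
from crlmvol.ct_io import MaskVolume
from crlmvol.phantoms import PhantomSpec, generate_cohort
from crlmvol.preprocess import NormalizedVolume

EASY = dict(
    grid_shape=(32, 32, 16),
    spacing_mm=(2.0, 2.0, 2.5),
    noise_sd_hu=0.0,
    blur_sigma_mm=0.0,
    liver_hu_sd=2.0,
    lesion_hu_sd=2.0,
    background_hu_sd=2.0,
)
FAST = dict(depth=2, base_filters=4, batch_size=8)


@pytest.fixture(scope="module")
def easy_cohort():
    spec = PhantomSpec(seed=31, **EASY)
    return generate_cohort(spec, n_patients=6, fractions=(0.5, 0.25, 0.25))


@pytest.fixture(scope="module")
def fitted(easy_cohort):
    manifest, data = easy_cohort
    model = CascadeModel(
        manifest,
        data,
        liver_config=ModelConfig(seed=1, epochs=25, early_stop_patience=25, learning_rate=3e-3, **FAST),
        tumor_config=ModelConfig(seed=2, epochs=60, early_stop_patience=60, learning_rate=3e-3, **FAST),
    )
    return model, model.fit()


class TestModelConfig:
    @pytest.mark.parametrize("kwargs", [dict(prob_threshold=0.0), dict(prob_threshold=1.0),
                                        dict(depth=0), dict(epochs=0), dict(loss="focal")])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)

    def test_build_reports_parameter_count(self):
        net = build_unet(ModelConfig(depth=1, base_filters=4))
        assert net.n_params > 0


class TestRestrictToLiver:
    @staticmethod
    def _norm(values, spacing=(1.0, 1.0, 1.0)):
        return NormalizedVolume("s", np.asarray(values, dtype=np.float32), spacing, {})

    def test_full_mask_is_identity(self):
        vals = np.random.default_rng(0).random((6, 6, 6)).astype(np.float32)
        vol = self._norm(vals)
        mask = MaskVolume("s", np.ones((6, 6, 6), dtype=np.uint8), (1, 1, 1))
        roi = restrict_to_liver(vol, mask, margin_mm=0.0)
        assert roi.offset == (0, 0, 0)
        np.testing.assert_array_equal(roi.values, vals)

    def test_single_voxel_margin_zero(self):
        vals = np.ones((5, 5, 5), dtype=np.float32)
        mask_arr = np.zeros((5, 5, 5), dtype=np.uint8)
        mask_arr[2, 3, 1] = 1
        roi = restrict_to_liver(self._norm(vals), MaskVolume("s", mask_arr, (1, 1, 1)), margin_mm=0.0)
        assert roi.values.shape == (1, 1, 1)
        assert roi.offset == (2, 3, 1)

    def test_paste_roundtrip_restores_coordinates(self):
        rng = np.random.default_rng(1)
        vals = rng.random((8, 7, 6)).astype(np.float32)
        mask_arr = np.zeros((8, 7, 6), dtype=np.uint8)
        mask_arr[2:5, 1:4, 2:5] = 1
        roi = restrict_to_liver(self._norm(vals), MaskVolume("s", mask_arr, (1, 1, 1)), margin_mm=0.0)
        pasted = roi.paste(roi.values)
        np.testing.assert_array_equal(pasted[mask_arr.astype(bool)], vals[mask_arr.astype(bool)])
        assert np.all(pasted[~mask_arr.astype(bool)] == 0)

    def test_margin_expands_voi(self):
        vals = np.ones((9, 9, 9), dtype=np.float32)
        mask_arr = np.zeros((9, 9, 9), dtype=np.uint8)
        mask_arr[4, 4, 4] = 1
        roi = restrict_to_liver(self._norm(vals), MaskVolume("s", mask_arr, (1, 1, 1)), margin_mm=2.0)
        assert roi.dilated_mask.sum() > 1
        assert roi.values.shape > (1, 1, 1)

    def test_empty_liver_is_an_error(self):
        vol = self._norm(np.zeros((4, 4, 4)))
        empty = MaskVolume("s", np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(EmptyLiverError, match="no liver"):
            restrict_to_liver(vol, empty)


class TestPredictVolume:
    def test_threshold_semantics_and_geometry(self):
        net = build_unet(ModelConfig(depth=1, base_filters=2, seed=0))
        vals = np.random.default_rng(2).random((16, 16, 5)).astype(np.float32)
        cfg = ModelConfig(depth=1, base_filters=2, prob_threshold=0.5)
        prob, mask = predict_volume(net, vals, cfg)
        assert prob.shape == vals.shape and mask.shape == vals.shape
        np.testing.assert_array_equal(mask, prob >= 0.5)

    def test_incompatible_slice_size_names_padding(self):
        net = build_unet(ModelConfig(depth=3, base_filters=2))
        vals = np.zeros((30, 32, 4), dtype=np.float32)
        with pytest.raises(ValueError, match="pad"):
            predict_volume(net, vals, ModelConfig(depth=3, base_filters=2))


class TestPostprocessLiver:
    def test_keeps_largest_component_and_fills_holes(self):
        arr = np.zeros((10, 10, 10), dtype=bool)
        arr[1:8, 1:8, 1:8] = True
        arr[4, 4, 4] = False  # internal hole
        arr[9, 9, 9] = True  # spurious island
        out = postprocess_liver(arr, (1, 1, 1))
        assert out[4, 4, 4]  # hole filled
        assert not out[9, 9, 9]  # island removed

    def test_empty_input_stays_empty(self):
        out = postprocess_liver(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
        assert not out.any()


class TestTrainModel:
    @staticmethod
    def _toy_slices(n=12, size=16, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 1, size, size)).astype(np.float32)
        y = (x > 0.6).astype(np.float32)
        return x, y

    def test_single_epoch_contract(self):
        x, y = self._toy_slices()
        cfg = ModelConfig(epochs=1, early_stop_patience=0, **FAST)
        _, hist = train_model(x, y, [(x, y, "v")], cfg)
        assert len(hist["train_loss"]) == 1
        assert len(hist["val_dsc"]) == 1

    def test_history_reproducible_with_fixed_seed(self):
        x, y = self._toy_slices()
        cfg = ModelConfig(epochs=3, early_stop_patience=3, seed=5, **FAST)
        _, h1 = train_model(x, y, [(x, y, "v")], cfg)
        _, h2 = train_model(x, y, [(x, y, "v")], cfg)
        assert np.allclose(h1["train_loss"], h2["train_loss"])
        assert np.allclose(h1["val_dsc"], h2["val_dsc"])

    def test_all_background_warns(self):
        x, _ = self._toy_slices()
        y = np.zeros_like(x)
        with pytest.warns(UserWarning, match="background"):
            train_model(x, y, [], ModelConfig(epochs=1, **FAST))

    def test_early_stopping_restores_best_epoch(self):
        x, y = self._toy_slices(n=8)
        cfg = ModelConfig(epochs=6, early_stop_patience=1, seed=3, **FAST)
        net, hist = train_model(x, y, [(x, y, "v")], cfg)
        assert hist["best_epoch"] <= len(hist["val_dsc"]) - 1
        # returned net reproduces the best epoch's validation DSC
        prob = net.predict_proba(x)
        pred = prob >= cfg.prob_threshold
        dsc = 2 * (pred * y).sum() / (pred.sum() + y.sum())
        assert dsc == pytest.approx(max(hist["val_dsc"]), abs=1e-6)


class TestEndToEndOnEasyPhantoms:
    def test_liver_stage_learns_separable_intensities(self, fitted):
        _, res = fitted
        assert max(res.liver.history["val_dsc"]) > 0.95

    def test_cascade_invariants_and_zero_lesion_case(self, fitted, easy_cohort):
        manifest, data = easy_cohort
        _, res = fitted
        test_ids = list(manifest.scans("test")["scan_id"])
        for sid in test_ids:
            ct = data[sid][0]
            out = res.segment(ct)
            # tumor ⊆ liver by construction
            assert not np.any(out.tumor_mask.labels & ~out.liver_mask.labels)
            assert out.liver_prob.shape == ct.shape
        # zero-lesion phantom: adequate liver stage -> empty tumor mask
        spec = PhantomSpec(seed=77, n_lesions_range=(0, 0), **EASY)
        from crlmvol.phantoms import generate_phantom

        ct0, _, _, _ = generate_phantom(spec, "zero", "pz")
        out0 = res.segment(ct0)
        frac = out0.tumor_mask.labels.mean()
        assert frac < 0.01

    def test_cascade_deterministic(self, fitted, easy_cohort):
        manifest, data = easy_cohort
        _, res = fitted
        sid = manifest.scans("test")["scan_id"].iloc[0]
        a = res.segment(data[sid][0])
        b = res.segment(data[sid][0])
        np.testing.assert_array_equal(a.tumor_mask.labels, b.tumor_mask.labels)
        np.testing.assert_array_equal(a.liver_prob, b.liver_prob)

    def test_provenance_mismatch_refused(self, fitted):
        _, res = fitted
        other = TrainedSegmenter(
            net=res.tumor.net,
            config=res.tumor.config,
            provenance={**res.tumor.provenance, "bins": 64},
            target="tumor",
        )
        ct = np.zeros((32, 32, 8), dtype=np.float32)
        from crlmvol.ct_io import CTVolume

        with pytest.raises(ValueError, match="preprocessing"):
            segment_cascade(CTVolume("s", ct, (1, 1, 1)), res.liver, other)

    def test_checkpoint_roundtrip(self, fitted, tmp_path):
        _, res = fitted
        path = tmp_path / "liver.npz"
        res.liver.save(path)
        loaded = TrainedSegmenter.load(path)
        assert loaded.config == res.liver.config
        assert loaded.provenance == res.liver.provenance
        x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(loaded.net.predict_proba(x), res.liver.net.predict_proba(x))
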