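"""Calibration tests: patch extraction, training behavior, folds, apply."""

import numpy as np
import pytest
from dataclasses import replace

from mp3rage.calibration import (
    CalibConfig,
    PatchSet,
    apply_calibrator,
    build_regressor,
    extract_patches,
    load_model,
    make_folds,
    save_model,
    train_calibrator,
)
from mp3rage.inference import T1MapResult
from mp3rage.phantom import CGM, CSF, SGM, WM


def _result(t1, valid=None, sigma=None):
    t1 = np.asarray(t1, dtype=float)
    return T1MapResult(t1_s=t1,
                       valid_mask=np.ones(t1.shape, bool) if valid is None else valid,
                       sigma_t1_s=sigma)


def _patchset_from_volume(vol, labels, cfg, target_vol):
    return extract_patches(_result(vol), labels, cfg, target=_result(target_vol))


@pytest.fixture()
def flat_volume():
    rng = np.random.default_rng(0)
    vol = rng.normal(1.5, 0.2, size=(10, 10, 1))
    labels = np.full((10, 10, 1), WM)
    return vol, labels


class TestExtractPatches:
    def test_one_sample_per_tissue_voxel(self, flat_volume):
        vol, labels = flat_volume
        cfg = CalibConfig(patch_size=5, seed=0)
        ps = _patchset_from_volume(vol, labels, cfg, vol)
        assert len(ps) == 100

    def test_degenerate_patch_equals_center(self, flat_volume):
        vol, labels = flat_volume
        cfg = CalibConfig(patch_size=1, seed=0)
        ps = _patchset_from_volume(vol, labels, cfg, vol)
        idx = tuple(ps.voxel_indices.T)
        assert np.allclose(ps.patches[:, 0, 0, 0], vol[idx], atol=1e-6)

    def test_csf_centers_excluded(self, flat_volume):
        vol, labels = flat_volume
        labels = labels.copy()
        labels[:5] = CSF
        cfg = CalibConfig(patch_size=5, seed=0)
        ps = _patchset_from_volume(vol, labels, cfg, vol)
        assert len(ps) == 50
        assert np.all(labels[tuple(ps.voxel_indices.T)] == WM)

    def test_invalid_neighbors_take_center_value(self):
        vol = np.full((7, 7, 1), 2.0)
        vol[3, 4, 0] = 99.0
        valid = np.ones(vol.shape, bool)
        valid[3, 4, 0] = False          # neighbor invalid
        labels = np.full(vol.shape, SGM)
        cfg = CalibConfig(patch_size=3, seed=0)
        ps = extract_patches(_result(vol, valid), labels, cfg, target=_result(vol))
        sample = ps[np.flatnonzero((ps.voxel_indices == [3, 3, 0]).all(1))[0]]
        assert np.all(sample.patch == 2.0)   # 99 masked, replaced by center

    def test_empty_label_set_rejected(self):
        cfg = CalibConfig(patch_size=5, seed=0)
        with pytest.raises(ValueError, match="no WM/SGM/CGM"):
            extract_patches(_result(np.ones((6, 6, 1))),
                            np.zeros((6, 6, 1), int), cfg)

    def test_two_channel_requires_sigma(self, flat_volume):
        vol, labels = flat_volume
        cfg = CalibConfig(patch_size=3, in_channels=2, seed=0)
        with pytest.raises(ValueError, match="sigma"):
            extract_patches(_result(vol), labels, cfg)
        ps = extract_patches(_result(vol, sigma=0.1 * vol), labels, cfg)
        assert ps.patches.shape[1] == 2


class TestFolds:
    def test_four_subjects_rotate_test_exactly_once(self):
        folds = make_folds([0, 1, 2, 3])
        assert len(folds) == 4
        assert sorted(f.test_subject for f in folds) == [0, 1, 2, 3]
        for f in folds:
            ids = set(f.train_subjects) | {f.val_subject, f.test_subject}
            assert ids == {0, 1, 2, 3}
            assert len(f.train_subjects) == 2

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            make_folds([0, 1, 2])


def _smooth_volume(rng, shape):
    """Spatially correlated field, like a real T1 map (iid noise would make
    center-pixel extraction adversarial for a conv + global-pool net)."""
    from scipy import ndimage
    v = ndimage.gaussian_filter(rng.normal(size=shape), sigma=(2, 2, 0))
    return 1.5 + 0.3 * v / v.std()


@pytest.fixture(scope="module")
def training_data():
    """Patches whose target is the center value plus a constant offset.

    Learnability checks run at lr 1e-3 so the scaled-width CPU model
    converges within a few hundred steps."""
    rng = np.random.default_rng(4)
    vol = _smooth_volume(rng, (24, 24, 2))
    labels = np.full(vol.shape, WM)
    cfg = CalibConfig(patch_size=5, base_width=2, max_steps=600,
                      learning_rate=1e-3, val_every=50, patience_steps=600, seed=2)
    train = extract_patches(_result(vol), labels, cfg,
                            target=_result(vol + 0.3))
    vol_v = _smooth_volume(rng, (12, 12, 1))
    val = extract_patches(_result(vol_v), np.full(vol_v.shape, WM), cfg,
                          target=_result(vol_v + 0.3))
    return cfg, train, val


@pytest.fixture(scope="module")
def trained_model(training_data):
    cfg, train, val = training_data
    model, hist = train_calibrator(train, val, cfg)
    return model, hist


class TestTraining:
    def test_constant_offset_recovered(self, training_data, trained_model):
        cfg, train, val = training_data
        model, _ = trained_model
        preds = model.predict(val.patches)
        bias = np.mean(preds - val.targets)
        assert abs(bias) < 0.05

    def test_identity_task_beats_target_variance(self, training_data):
        cfg, train, val = training_data
        identity_train = PatchSet(train.patches, train.patches[:, 0, 2, 2],
                                  train.subject_ids, train.voxel_indices)
        identity_val = PatchSet(val.patches, val.patches[:, 0, 2, 2],
                                val.subject_ids, val.voxel_indices)
        model, hist = train_calibrator(identity_train, identity_val, cfg)
        assert hist["best_val_loss"] < 0.1 * np.var(identity_val.targets)

    def test_flat_validation_triggers_early_stop(self, training_data):
        cfg, train, val = training_data
        # constant targets: loss at the mean-initialized head cannot improve
        const_train = PatchSet(train.patches, np.full(len(train), 1.5, np.float32),
                               train.subject_ids, train.voxel_indices)
        const_val = PatchSet(val.patches, np.full(len(val), 1.5, np.float32),
                             val.subject_ids, val.voxel_indices)
        long_cfg = replace(cfg, max_steps=100_000, patience_steps=100, val_every=50)
        model, hist = train_calibrator(const_train, const_val, long_cfg)
        assert hist["stopped_at"] < long_cfg.max_steps

    def test_checkpoint_is_best_validation(self, training_data, trained_model):
        cfg, train, val = training_data
        model, hist = trained_model
        vx, vt = val.patches, val.targets
        final_val = float(np.mean((model.predict(vx[:2048]) - vt[:2048]) ** 2))
        assert final_val <= min(hist["val_loss"]) + 1e-6

    def test_reproducible_history(self, training_data):
        cfg, train, val = training_data
        short = replace(cfg, max_steps=150, patience_steps=150)
        _, h1 = train_calibrator(train, val, short)
        _, h2 = train_calibrator(train, val, short)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]


class TestApply:
    def test_output_masked_to_brain_tissue(self, training_data, trained_model):
        cfg, train, val = training_data
        model, _ = trained_model
        vol = np.full((10, 10, 1), 1.5)
        labels = np.full(vol.shape, CSF)
        labels[2:8, 2:8, :] = CGM
        out = apply_calibrator(model, _result(vol), labels, cfg)
        assert out.method == "calibrated"
        assert out.valid_mask.sum() == 36
        assert not out.valid_mask[labels == CSF].any()

    def test_inference_deterministic(self, training_data, trained_model):
        cfg, train, val = training_data
        model, _ = trained_model
        vol = np.random.default_rng(1).normal(1.5, 0.2, (8, 8, 1))
        labels = np.full(vol.shape, WM)
        a = apply_calibrator(model, _result(vol), labels, cfg)
        b = apply_calibrator(model, _result(vol), labels, cfg)
        assert np.array_equal(a.t1_s[a.valid_mask], b.t1_s[b.valid_mask])

    def test_channel_mismatch_rejected(self, training_data, trained_model):
        cfg, train, val = training_data
        model, _ = trained_model
        bad = replace(cfg, in_channels=2)
        with pytest.raises(ValueError, match="disagree"):
            apply_calibrator(model, _result(np.ones((6, 6, 1))),
                             np.full((6, 6, 1), WM), bad)

    def test_model_save_load_round_trip(self, tmp_path, training_data, trained_model):
        cfg, train, val = training_data
        model, _ = trained_model
        path = tmp_path / "model.pkl"
        save_model(model, cfg, path)
        loaded, chash = load_model(path)
        assert chash == cfg.config_hash()
        x = val.patches[:16]
        assert np.array_equal(loaded.predict(x), model.predict(x))


class TestCalibConfig:
    def test_patience_must_align_with_val_every(self):
        with pytest.raises(ValueError):
            CalibConfig(val_every=50, patience_steps=1025)

    def test_build_regressor_respects_channels(self):
        cfg = CalibConfig(in_channels=2, base_width=2, seed=0)
        model = build_regressor(cfg)
        assert model.in_channels == 2


class TestSensitivitySweeps:
    def test_noise_and_patch_sweeps(self, phantom_subjects):
        """Uncalibrated RMSE grows with the Monte-Carlo noise level while
        calibration holds the error roughly constant, and every patch size
        trains without architecture errors (bounded problem sizes)."""
        from mp3rage.calibration import sensitivity_sweeps

        spec, subjects = phantom_subjects
        cfg = CalibConfig(patch_size=5, base_width=2, max_steps=300, seed=19)
        rep = sensitivity_sweeps(subjects, spec, cfg,
                                 patch_sizes=(1, 5, 9, 13),
                                 noise_sigmas=(0.001, 0.005, 0.01, 0.015, 0.02),
                                 sweep_trials=200_000, train_folds=1)
        for entry in rep["patch_sweep"]:
            assert all(np.isfinite(v) for v in entry["rmse_after"].values())

        before = [np.mean(list(e["rmse_before"].values())) for e in rep["noise_sweep"]]
        after = [np.mean(list(e["rmse_after"].values())) for e in rep["noise_sweep"]]
        assert all(a <= b + 1e-12 for a, b in zip(before, before[1:]))
        assert (max(after) - min(after)) < (max(before) - min(before))
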