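"""Patch-based residual-CNN calibration of MAP MP2RAGE T1 to IR T1.

A small residual convolutional regressor maps a P x P in-plane (axial)
patch of MAP MP2RAGE T1 values (optionally with the posterior sigma-T1 map
as a second channel) to the multi-TI IR T1 value at the patch center.
Training minimizes voxelwise mean squared error with adaptive-moment
gradient descent; early stopping monitors validation loss.  Subject-level
leave-one-out cross-validation (train 2 / validate 1 / test 1, four
rotating folds) measures how much the calibration reduces the per-tissue
RMSE against the IR reference.

Inputs and targets are fed in seconds without standardization: both live
on the same ~[0.5, 3.5] s scale.  The affine head's bias is initialized to
the training-target mean so the network starts from an unbiased constant
predictor and learns the tissue- and neighborhood-dependent correction.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .evaluation import paired_t, rmse_by_tissue
from .inference import MonteCarloConfig, T1MapResult, map_t1_volume
from .nn import Adam, ResNetRegressor, mse_loss
from .phantom import CGM, SGM, WM, PhantomSpec, SubjectData, inject_tissue_bias

__all__ = [
    "PatchSample", "PatchSet", "CalibConfig", "FoldSplit", "CVResult",
    "extract_patches", "build_regressor", "make_folds", "train_calibrator",
    "apply_calibrator", "loo_cv", "sensitivity_sweeps",
    "save_model", "load_model",
]

_BRAIN_TISSUES = (WM, SGM, CGM)


@dataclass(frozen=True)
class CalibConfig:
    """Calibration model and training hyperparameters."""

    patch_size: int = 5
    in_channels: int = 1
    learning_rate: float = 1e-5
    batch_size: int = 256
    max_steps: int = 10_000
    val_every: int = 50
    patience_steps: int = 1000
    base_width: int = 64
    max_val_samples: int = 2048
    seed: int = 0

    def __post_init__(self):
        if self.patch_size % 2 == 0 or self.patch_size < 1:
            raise ValueError("patch_size must be odd and >= 1")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.patience_steps % self.val_every != 0:
            raise ValueError("patience_steps must be a multiple of val_every")
        if min(self.learning_rate, self.batch_size, self.max_steps,
               self.val_every, self.patience_steps, self.base_width) <= 0:
            raise ValueError("all training parameters must be positive")

    def config_hash(self) -> str:
        payload = json.dumps([self.patch_size, self.in_channels, self.learning_rate,
                              self.batch_size, self.max_steps, self.val_every,
                              self.patience_steps, self.base_width, self.seed]).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PatchSample:
    """One training sample: input patch(es), IR target, and provenance."""

    patch: np.ndarray            # (C, P, P)
    target: float
    subject_id: int
    voxel_index: tuple[int, int, int]


class PatchSet:
    """Batched patch samples with deterministic (slice, row, column) order."""

    def __init__(self, patches: np.ndarray, targets: np.ndarray,
                 subject_ids: np.ndarray, voxel_indices: np.ndarray):
        self.patches = patches          # (N, C, P, P)
        self.targets = targets          # (N,)
        self.subject_ids = subject_ids
        self.voxel_indices = voxel_indices

    def __len__(self) -> int:
        return len(self.targets)

    def __getitem__(self, i: int) -> PatchSample:
        return PatchSample(self.patches[i], float(self.targets[i]),
                           int(self.subject_ids[i]), tuple(self.voxel_indices[i]))

    @classmethod
    def concatenate(cls, sets: list["PatchSet"]) -> "PatchSet":
        return cls(np.concatenate([s.patches for s in sets]),
                   np.concatenate([s.targets for s in sets]),
                   np.concatenate([s.subject_ids for s in sets]),
                   np.concatenate([s.voxel_indices for s in sets]))


@dataclass(frozen=True)
class FoldSplit:
    train_subjects: tuple[int, ...]
    val_subject: int
    test_subject: int
    fold_index: int

    def __post_init__(self):
        ids = set(self.train_subjects) | {self.val_subject, self.test_subject}
        if len(ids) != len(self.train_subjects) + 2:
            raise ValueError("fold subject sets must be disjoint")


def _channel_volume(vol: np.ndarray, valid: np.ndarray, labels: np.ndarray,
                    patch: int) -> np.ndarray:
    """Reflect-pad each axial slice in-plane; invalid voxels become NaN."""
    half = patch // 2
    v = np.where(valid, vol, np.nan)
    return np.pad(v, ((half, half), (half, half), (0, 0)), mode="reflect")


def extract_patches(
    t1: T1MapResult,
    labels: np.ndarray,
    cfg: CalibConfig,
    target: T1MapResult | None = None,
    sigma: np.ndarray | None = None,
    subject_id: int = 0,
) -> PatchSet:
    """One sample per WM/SGM/CGM voxel of each axial slice.

    In-plane edges are reflect-padded; invalid neighbors take the center
    voxel's value.  Order is deterministic by (slice, row, column).
    """
    if not np.any(np.isin(labels, _BRAIN_TISSUES)):
        raise ValueError("label map contains no WM/SGM/CGM voxels")
    p = cfg.patch_size
    half = p // 2
    channels = [t1.t1_s]
    if cfg.in_channels == 2:
        if sigma is None:
            sigma = t1.sigma_t1_s
        if sigma is None:
            raise ValueError("two-channel extraction needs a sigma map")
        channels.append(sigma)

    centers = np.argwhere(np.isin(labels, _BRAIN_TISSUES) & t1.valid_mask)
    # deterministic ordering by (slice, row, column)
    order = np.lexsort((centers[:, 1], centers[:, 0], centers[:, 2]))
    centers = centers[order]
    n = len(centers)
    patches = np.empty((n, cfg.in_channels, p, p), dtype=np.float32)
    for c, vol in enumerate(channels):
        padded = _channel_volume(np.asarray(vol, dtype=float), t1.valid_mask, labels, p)
        win = np.lib.stride_tricks.sliding_window_view(padded, (p, p), axis=(0, 1))
        pv = win[centers[:, 0], centers[:, 1], centers[:, 2]]  # (n, p, p)
        center_vals = pv[:, half, half]
        pv = np.where(np.isnan(pv), center_vals[:, None, None], pv)
        patches[:, c] = pv
    targets = (np.asarray(target.t1_s, dtype=float)[tuple(centers.T)]
               if target is not None else np.full(n, np.nan))
    return PatchSet(patches, targets.astype(np.float32),
                    np.full(n, subject_id, dtype=np.int32), centers)


def build_regressor(cfg: CalibConfig) -> ResNetRegressor:
    """Seeded 18-layer residual regressor sized for ``cfg.patch_size``."""
    return ResNetRegressor(in_channels=cfg.in_channels, patch_size=cfg.patch_size,
                           base_width=cfg.base_width, seed=cfg.seed)


def train_calibrator(
    train: PatchSet,
    val: PatchSet,
    cfg: CalibConfig,
    model: ResNetRegressor | None = None,
) -> tuple[ResNetRegressor, dict]:
    """Train with MSE loss, seeded shuffling, and early stopping.

    Validation MSE is computed every ``val_every`` steps (on up to
    ``max_val_samples`` seeded-subsampled validation patches); training
    halts at ``max_steps`` or once the best validation loss has not
    improved within ``patience_steps``.  Returns the best-validation
    checkpoint and the loss history.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    model = model or build_regressor(cfg)
    # start from an unbiased constant predictor at the target mean
    model.head.b["value"][:] = np.float32(np.mean(train.targets))
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.Generator(np.random.Philox(key=(np.uint64(cfg.seed & 0x7FFFFFFF),
                                                    np.uint64(0xE5))))
    if len(val) > cfg.max_val_samples:
        vidx = rng.choice(len(val), size=cfg.max_val_samples, replace=False)
    else:
        vidx = np.arange(len(val))
    vx, vt = val.patches[vidx], val.targets[vidx]

    history = {"step": [], "train_loss": [], "val_step": [], "val_loss": []}
    best_val = np.inf
    best_state = model.get_state()
    best_step = 0
    perm = rng.permutation(len(train))
    cursor = 0
    step = 0
    while step < cfg.max_steps:
        if cursor + cfg.batch_size > len(perm):
            perm = rng.permutation(len(train))
            cursor = 0
        idx = perm[cursor:cursor + cfg.batch_size]
        cursor += cfg.batch_size
        pred = model.forward(train.patches[idx], train=True)
        loss, grad = mse_loss(pred, train.targets[idx])
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at step {step}: loss={loss}")
        model.backward(grad)
        opt.step()
        step += 1
        history["step"].append(step)
        history["train_loss"].append(loss)
        if step % cfg.val_every == 0:
            vloss = float(np.mean((model.predict(vx) - vt) ** 2))
            history["val_step"].append(step)
            history["val_loss"].append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_state = model.get_state()
                best_step = step
            elif step - best_step >= cfg.patience_steps:
                break
    model.set_state(best_state)
    history["best_val_loss"] = float(best_val)
    history["best_step"] = best_step
    history["stopped_at"] = step
    return model, history


def apply_calibrator(
    model: ResNetRegressor,
    t1: T1MapResult,
    labels: np.ndarray,
    cfg: CalibConfig,
    sigma: np.ndarray | None = None,
) -> T1MapResult:
    """Calibrated T1 at WM/SGM/CGM voxels; everything else is masked."""
    if model.in_channels != cfg.in_channels or model.patch_size != cfg.patch_size:
        raise ValueError("model and config disagree on channels or patch size")
    patches = extract_patches(t1, labels, cfg, sigma=sigma)
    preds = model.predict(patches.patches)
    out = np.full(t1.t1_s.shape, np.nan)
    valid = np.zeros(t1.t1_s.shape, dtype=bool)
    idx = tuple(patches.voxel_indices.T)
    out[idx] = preds
    valid[idx] = True
    return T1MapResult(t1_s=out, valid_mask=valid, method="calibrated")


@dataclass
class CVResult:
    """Per-fold and aggregated leave-one-out cross-validation metrics."""

    folds: list[FoldSplit]
    rmse_before: list[dict]
    rmse_after: list[dict]
    mean_rmse_before: dict = field(default_factory=dict)
    mean_rmse_after: dict = field(default_factory=dict)
    sd_rmse_after: dict = field(default_factory=dict)
    ttest: dict = field(default_factory=dict)
    histories: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "folds": [[list(f.train_subjects), f.val_subject, f.test_subject] for f in self.folds],
            "rmse_before": self.rmse_before,
            "rmse_after": self.rmse_after,
            "mean_rmse_before": self.mean_rmse_before,
            "mean_rmse_after": self.mean_rmse_after,
            "sd_rmse_after": self.sd_rmse_after,
            "ttest": self.ttest,
        }


def make_folds(subject_ids: list[int]) -> list[FoldSplit]:
    """Rotating leave-one-out folds: test subject i, validate on the next."""
    n = len(subject_ids)
    if n < 4:
        raise ValueError("leave-one-out CV needs at least 4 subjects")
    folds = []
    for i in range(n):
        test = subject_ids[i]
        val = subject_ids[(i + 1) % n]
        train = tuple(s for s in subject_ids if s not in (test, val))
        folds.append(FoldSplit(train_subjects=train, val_subject=val,
                               test_subject=test, fold_index=i))
    return folds


def _subject_patches(subj: SubjectData, cfg: CalibConfig) -> PatchSet:
    return extract_patches(subj.mp2rage_biased, subj.labels, cfg,
                           target=subj.ir_truth, subject_id=subj.subject_id)


def loo_cv(subjects: list[SubjectData], cfg: CalibConfig,
           folds: list[FoldSplit] | None = None) -> CVResult:
    """Leave-one-out cross-validation of the calibrator across subjects."""
    by_id = {s.subject_id: s for s in subjects}
    folds = folds or make_folds(sorted(by_id))
    patch_cache = {sid: _subject_patches(by_id[sid], cfg) for sid in by_id}

    result = CVResult(folds=folds, rmse_before=[], rmse_after=[])
    for fold in folds:
        assert not ({fold.test_subject} & set(fold.train_subjects)
                    or {fold.val_subject} & set(fold.train_subjects)
                    or fold.test_subject == fold.val_subject), "subject leakage"
        train = PatchSet.concatenate([patch_cache[s] for s in fold.train_subjects])
        val = patch_cache[fold.val_subject]
        model, hist = train_calibrator(train, val, cfg)
        test_subj = by_id[fold.test_subject]
        calibrated = apply_calibrator(model, test_subj.mp2rage_biased,
                                      test_subj.labels, cfg)
        result.rmse_before.append(
            rmse_by_tissue(test_subj.mp2rage_biased, test_subj.ir_truth, test_subj.labels))
        result.rmse_after.append(
            rmse_by_tissue(calibrated, test_subj.ir_truth, test_subj.labels))
        result.histories.append(hist)

    tissues = result.rmse_before[0].keys()
    for t in tissues:
        before = [r[t] for r in result.rmse_before]
        after = [r[t] for r in result.rmse_after]
        result.mean_rmse_before[t] = float(np.mean(before))
        result.mean_rmse_after[t] = float(np.mean(after))
        result.sd_rmse_after[t] = (float(np.std(after, ddof=1))
                                   if len(after) > 1 else 0.0)
    if len(folds) >= 2:
        mean_before = [float(np.mean(list(r.values()))) for r in result.rmse_before]
        mean_after = [float(np.mean(list(r.values()))) for r in result.rmse_after]
        tt = paired_t(mean_before, mean_after)
        result.ttest = {"t": tt.t_statistic, "p": tt.p_value,
                        "significant": tt.significant_at_0p05}
    return result


def sensitivity_sweeps(
    subjects: list[SubjectData],
    spec: PhantomSpec,
    cfg: CalibConfig,
    patch_sizes=(1, 5, 9, 13),
    noise_sigmas=(0.001, 0.005, 0.01, 0.015, 0.02),
    sweep_trials: int = 1_000_000,
    train_folds: int = 1,
    posterior_cache: dict | None = None,
) -> dict:
    """Patch-size and noise-level sensitivity of the calibration.

    The patch sweep retrains on the given subjects at each patch size; the
    noise sweep regenerates MAP maps at each Monte-Carlo noise level
    (``sweep_trials`` trials) and records uncalibrated and calibrated
    per-tissue RMSE.  ``train_folds`` limits how many LOO folds are
    trained per setting to bound runtime.
    """
    by_id = {s.subject_id: s for s in subjects}
    folds = make_folds(sorted(by_id))[:train_folds]
    report = {"patch_sweep": [], "noise_sweep": []}

    for p in patch_sizes:
        cv = loo_cv(subjects, replace(cfg, patch_size=int(p)), folds=folds)
        report["patch_sweep"].append({
            "patch_size": int(p),
            "rmse_before": cv.mean_rmse_before,
            "rmse_after": cv.mean_rmse_after,
        })

    cache = posterior_cache if posterior_cache is not None else {}
    for sig in noise_sigmas:
        mc = MonteCarloConfig(n_trials=sweep_trials, noise_sigma=float(sig), seed=spec.seed)
        resim = []
        for s in subjects:
            mp = map_t1_volume(s.gres, s.b1map, _default_params(), mc,
                               mode="pair", posterior_cache=cache)
            biased = inject_tissue_bias(mp.t1_s, s.labels, spec, seed=s.subject_id)
            clone = SubjectData(
                subject_id=s.subject_id, labels=s.labels, true_t1=s.true_t1,
                b1map=s.b1map, gres=s.gres, ir_truth=s.ir_truth,
                mp2rage_map=mp,
                mp2rage_biased=T1MapResult(
                    t1_s=biased,
                    valid_mask=mp.valid_mask & np.isin(s.labels, _BRAIN_TISSUES),
                    sigma_t1_s=mp.sigma_t1_s, method="map_mp2rage"))
            resim.append(clone)
        cv = loo_cv(resim, cfg, folds=folds)
        report["noise_sweep"].append({
            "noise_sigma": float(sig),
            "rmse_before": cv.mean_rmse_before,
            "rmse_after": cv.mean_rmse_after,
        })
    return report


def _default_params():
    from .forward import mp3rage_7t_protocol
    return mp3rage_7t_protocol()


def save_model(model: ResNetRegressor, cfg: CalibConfig, path: str | Path) -> None:
    """Single-file checkpoint with the embedded config hash."""
    with open(path, "wb") as fh:
        pickle.dump({"state": model.get_state(),
                     "in_channels": model.in_channels,
                     "patch_size": model.patch_size,
                     "config_hash": cfg.config_hash(),
                     "base_width": cfg.base_width,
                     "seed": cfg.seed}, fh)


def load_model(path: str | Path) -> tuple[ResNetRegressor, str]:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    model = ResNetRegressor(in_channels=blob["in_channels"],
                            patch_size=blob["patch_size"],
                            base_width=blob["base_width"], seed=blob["seed"])
    model.set_state(blob["state"])
    return model, blob["config_hash"]
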