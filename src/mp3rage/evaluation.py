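"""Agreement metrics, label morphology, NIfTI/report I/O and orchestration.

Metrics follow the agreement-analysis conventions of quantitative-MRI
comparisons: per-tissue RMSE, relative value (ratio of tissue means, in
percent), and a Bland-Altman-style decomposition of the voxelwise error
into bias (mean error) and variance with limits of agreement at
``bias +/- 1.96 * SD``.  Population variance is used so the identity
``rmse^2 = bias^2 + variance`` holds exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import ndimage, stats

from .inference import T1MapResult

logger = logging.getLogger("mp3rage")

__all__ = [
    "MetricsReport", "TTestResult", "TISSUE_NAMES",
    "erode_labels", "rmse_by_tissue", "relative_value_by_tissue",
    "bland_altman", "paired_t", "compare_maps",
    "save_nifti", "load_nifti", "run_pipeline",
]

TISSUE_NAMES = {2: "wm", 3: "sgm", 4: "cgm"}


@dataclass
class MetricsReport:
    """Per-tissue agreement metrics between two T1 maps."""

    method_pair: tuple[str, str]
    rmse_s: dict = field(default_factory=dict)
    relative_value_pct: dict = field(default_factory=dict)
    bias_s: dict = field(default_factory=dict)
    loa_low_s: dict = field(default_factory=dict)
    loa_high_s: dict = field(default_factory=dict)
    error_variance_s2: dict = field(default_factory=dict)
    n_voxels: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "MetricsReport":
        raw = json.loads(payload)
        raw["method_pair"] = tuple(raw["method_pair"])
        return cls(**raw)


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    significant_at_0p05: bool
    n_pairs: int
    degenerate: bool = False


def erode_labels(labels: np.ndarray, tissue_code: int, cube_side: int = 3) -> np.ndarray:
    """Erode one tissue's mask by a cubic structuring element.

    Eroded-away voxels become background; other labels are untouched.
    ``cube_side`` must be odd; 1 is the identity.
    """
    if cube_side < 1 or cube_side % 2 == 0:
        raise ValueError("cube_side must be odd and >= 1")
    out = np.array(labels, copy=True)
    mask = labels == tissue_code
    if not np.any(mask):
        logger.warning("tissue code %d absent; erosion is the identity", tissue_code)
        return out
    if cube_side == 1:
        return out
    eroded = ndimage.binary_erosion(mask, structure=np.ones((cube_side,) * labels.ndim, dtype=bool))
    out[mask & ~eroded] = 0
    return out


def _tissue_pairs(map_a: T1MapResult, ref: T1MapResult, labels: np.ndarray, tissues):
    for code in tissues:
        sel = (labels == code) & map_a.valid_mask & ref.valid_mask
        yield code, map_a.t1_s[sel], ref.t1_s[sel]


def rmse_by_tissue(map_a: T1MapResult, ref: T1MapResult, labels: np.ndarray,
                   tissues=(2, 3, 4)) -> dict:
    """Per-tissue root-mean-square error over the intersection of masks."""
    out = {}
    for code, a, r in _tissue_pairs(map_a, ref, labels, tissues):
        out[TISSUE_NAMES.get(code, str(code))] = (
            float(np.sqrt(np.mean((a - r) ** 2))) if a.size else float("nan"))
    return out


def relative_value_by_tissue(map_a: T1MapResult, ref: T1MapResult, labels: np.ndarray,
                             tissues=(2, 3, 4), voxelwise: bool = False) -> dict:
    """Per-tissue relative value: 100 * mean(a) / mean(ref) (percent).

    ``voxelwise=True`` averages the voxel ratios instead of taking the
    ratio of means.
    """
    out = {}
    for code, a, r in _tissue_pairs(map_a, ref, labels, tissues):
        name = TISSUE_NAMES.get(code, str(code))
        if a.size == 0 or np.mean(r) == 0:
            out[name] = float("nan")
        elif voxelwise:
            out[name] = float(100.0 * np.mean(a / r))
        else:
            out[name] = float(100.0 * np.mean(a) / np.mean(r))
    return out


def bland_altman(map_a: T1MapResult, ref: T1MapResult, labels: np.ndarray,
                 tissues=(2, 3, 4)) -> MetricsReport:
    """Bias / limits-of-agreement / variance decomposition per tissue."""
    rep = MetricsReport(method_pair=(map_a.method, ref.method))
    for code, a, r in _tissue_pairs(map_a, ref, labels, tissues):
        name = TISSUE_NAMES.get(code, str(code))
        rep.n_voxels[name] = int(a.size)
        if a.size == 0:
            for d in (rep.rmse_s, rep.bias_s, rep.loa_low_s, rep.loa_high_s, rep.error_variance_s2):
                d[name] = float("nan")
            continue
        err = a - r
        bias = float(np.mean(err))
        var = float(np.var(err))          # population variance: exact identity
        sd = float(np.sqrt(var))
        rep.bias_s[name] = bias
        rep.error_variance_s2[name] = var
        rep.loa_low_s[name] = bias - 1.96 * sd
        rep.loa_high_s[name] = bias + 1.96 * sd
        rep.rmse_s[name] = float(np.sqrt(bias ** 2 + var))
    return rep


def compare_maps(map_a: T1MapResult, ref: T1MapResult, labels: np.ndarray,
                 tissues=(2, 3, 4)) -> MetricsReport:
    """Full agreement report: RMSE, relative value and Bland-Altman."""
    rep = bland_altman(map_a, ref, labels, tissues)
    rep.relative_value_pct = relative_value_by_tissue(map_a, ref, labels, tissues)
    return rep


def paired_t(values_a, values_b) -> TTestResult:
    """Classical two-sided paired t-test on matched metric vectors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equally sized vectors of length >= 2")
    d = a - b
    sd = np.std(d, ddof=1)
    n = d.size
    if sd == 0:
        return TTestResult(t_statistic=0.0 if np.mean(d) == 0 else float("inf"),
                           p_value=float("nan"), significant_at_0p05=False,
                           n_pairs=n, degenerate=True)
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t_statistic=t, p_value=p, significant_at_0p05=bool(p < 0.05), n_pairs=n)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_nifti(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config_path: str | Path) -> dict:
    """Run phantom -> MAP/point/SIR fitting -> calibration CV -> metrics.

    The YAML config controls every stage; see the CLI ``run-all`` command.
    Returns the report bundle (also written to ``out_dir``).
    """
    import yaml

    from .calibration import CalibConfig, loo_cv
    from .inference import MonteCarloConfig
    from .phantom import PhantomSpec, synth_subjects

    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out_dir = Path(cfg.get("out_dir", "mp3rage_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    logging.basicConfig(level=logging.INFO)

    spec = PhantomSpec(seed=seed, n_subjects=int(cfg.get("n_subjects", 4)),
                       noise_sigma=float(cfg.get("noise_sigma", 0.005)))
    mc = MonteCarloConfig(n_trials=int(cfg.get("n_trials", 1_000_000)),
                          noise_sigma=spec.noise_sigma, seed=seed)
    logger.info("stage phantom: seed=%d subjects=%d", seed, spec.n_subjects)
    try:
        subjects = synth_subjects(spec, mc_cfg=mc, with_sir=bool(cfg.get("with_sir", False)))
    except Exception as exc:
        raise RuntimeError(f"stage phantom failed: {exc}") from exc

    calib_cfg = CalibConfig(
        patch_size=int(cfg.get("patch_size", 5)),
        max_steps=int(cfg.get("max_steps", 2000)),
        base_width=int(cfg.get("base_width", 8)),
        seed=seed,
    )
    logger.info("stage calibration: config hash %s", calib_cfg.config_hash())
    try:
        cv = loo_cv(subjects, calib_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage calibration failed: {exc}") from exc

    bundle = {
        "seed": seed,
        "mc_config_hash": mc.config_hash(),
        "calib_config_hash": calib_cfg.config_hash(),
        "cv": cv.to_dict(),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    logger.info("pipeline complete: %s", out_dir / "report.json")
    return bundle
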