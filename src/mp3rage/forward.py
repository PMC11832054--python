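"""MP2RAGE / MP3RAGE steady-state forward signal model.

The sequence plays an adiabatic inversion every ``cycle_tr_s`` seconds and
reads out K gradient-echo (GRE) blocks of ``n_excitations`` low-flip-angle
pulses at inversion times ``inversion_times_s`` (measured from the inversion
to the k-space center of each block).  Longitudinal magnetization (M0
normalized to 1) evolves through each cycle by composition of affine maps

* inversion:            ``Mz -> -eff * Mz``
* free recovery over t: ``Mz -> Mz * exp(-t/T1) + (1 - exp(-t/T1))``
* one excitation period (flip ``b1*alpha``, spacing ``TR_exc``):
  ``Mz -> Mz * cos(b1*alpha) * E1 + (1 - E1)`` with ``E1 = exp(-TR_exc/T1)``.

A run of ``m`` identical excitation periods composes in closed form via the
geometric series, with fractional ``m`` permitted (block-center convention:
the readout samples Mz after ``n/2`` periods).  The full cycle is an affine
map ``Mz -> A*Mz + B`` whose steady state is ``B / (1 - A)``; ideal GRE
signal k is ``sin(b1*alpha_k) * Mz`` at the center of block k.

The "uniform" T1-weighted image combines two complex GREs as
``Re(conj(GRE_i) * GRE_j) / (|GRE_i|^2 + |GRE_j|^2)``, which is bounded in
[-0.5, 0.5] and insensitive to T2*, B0 and receive sensitivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("mp3rage")

__all__ = [
    "AcquisitionParams",
    "DerivedTiming",
    "ComplexGREImage",
    "UniformSignalImage",
    "RobustImageParams",
    "B1Map",
    "InvalidProtocolError",
    "mp3rage_7t_protocol",
    "load_acquisition_config",
    "derive_block_timing",
    "mp2rage_signals",
    "steady_state_longitudinal",
    "uniform_signal",
    "robust_uniform_signal",
]


class InvalidProtocolError(ValueError):
    """Raised when acquisition timing cannot be realized (negative gaps)."""


@dataclass(frozen=True)
class AcquisitionParams:
    """MP2RAGE/MP3RAGE sequence timing and flip angles (times in seconds)."""

    inversion_times_s: tuple[float, ...]
    excitation_tr_s: float
    cycle_tr_s: float
    n_excitations: int
    flip_deg: tuple[float, ...]
    inversion_efficiency: float = 0.84

    def __post_init__(self):
        object.__setattr__(self, "inversion_times_s", tuple(float(t) for t in self.inversion_times_s))
        object.__setattr__(self, "flip_deg", tuple(float(a) for a in self.flip_deg))
        k = len(self.inversion_times_s)
        if k not in (2, 3):
            raise ValueError(f"expected 2 or 3 GRE blocks, got {k}")
        if len(self.flip_deg) != k:
            raise ValueError("flip_deg must match inversion_times_s in length")
        if any(t2 <= t1 for t1, t2 in zip(self.inversion_times_s, self.inversion_times_s[1:])):
            raise ValueError("inversion times must be strictly increasing")
        if not (0.0 <= self.inversion_efficiency <= 1.0):
            raise ValueError("inversion_efficiency must lie in [0, 1]")
        if self.excitation_tr_s <= 0 or self.cycle_tr_s <= 0 or self.n_excitations <= 0:
            raise ValueError("timings and n_excitations must be positive")

    @property
    def n_blocks(self) -> int:
        return len(self.inversion_times_s)

    def with_b1(self, b1: float) -> "AcquisitionParams":
        """Return a copy with flip angles scaled by a B1+ correction factor."""
        return replace(self, flip_deg=tuple(b1 * a for a in self.flip_deg))


@dataclass(frozen=True)
class DerivedTiming:
    """Decomposition of one inversion cycle into recovery gaps and GRE blocks."""

    pre_first_block_s: float          # TA: inversion -> first block start
    inter_block_gaps_s: tuple[float, ...]
    post_last_block_s: float          # TD: last block end -> next inversion
    block_duration_s: float

    def total_s(self, n_blocks: int) -> float:
        return (self.pre_first_block_s + n_blocks * self.block_duration_s
                + sum(self.inter_block_gaps_s) + self.post_last_block_s)


@dataclass
class ComplexGREImage:
    """One complex-valued GRE volume at a given inversion index."""

    data: np.ndarray
    inversion_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("GRE data must be finite")


@dataclass
class UniformSignalImage:
    """Real-valued uniform image, bounded in [-0.5, 0.5]."""

    data: np.ndarray
    pair: tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class RobustImageParams:
    """Regularization for the background-suppressed uniform image.

    ``beta_fraction`` multiplies the volume-mean sum of squared GRE
    magnitudes to obtain the additive denominator constant beta.
    """

    beta_fraction: float = 0.25

    def __post_init__(self):
        if self.beta_fraction < 0:
            raise ValueError("beta_fraction must be >= 0")


@dataclass
class B1Map:
    """Unitless multiplicative flip-angle correction factors, clipped to [0, 2]."""

    data: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if np.any(data < 0) or np.any(data > 2):
            logger.warning("B1 map values outside [0, 2]; clipping on ingest")
            data = np.clip(data, 0.0, 2.0)
        self.data = data


def mp3rage_7t_protocol() -> AcquisitionParams:
    """The 7 T MP3RAGE protocol used throughout this package.

    TI = 1010/3683/6355 ms, TR_exc = 6 ms, cycle TR = 8.25 s, 225 excitations
    per block, 4 degree flips, inversion efficiency 0.84.
    """
    return AcquisitionParams(
        inversion_times_s=(1.010, 3.683, 6.355),
        excitation_tr_s=0.006,
        cycle_tr_s=8.25,
        n_excitations=225,
        flip_deg=(4.0, 4.0, 4.0),
        inversion_efficiency=0.84,
    )


def load_acquisition_config(path: str | Path) -> AcquisitionParams:
    """Read acquisition parameters from a YAML config (times given in ms)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return AcquisitionParams(
        inversion_times_s=tuple(t / 1000.0 for t in raw["inversion_times_ms"]),
        excitation_tr_s=raw["excitation_tr_ms"] / 1000.0,
        cycle_tr_s=raw["cycle_tr_ms"] / 1000.0,
        n_excitations=int(raw["n_excitations"]),
        flip_deg=tuple(raw["flip_deg"]),
        inversion_efficiency=float(raw.get("inversion_efficiency", 0.84)),
    )


# ---------------------------------------------------------------------------
# timing decomposition
# ---------------------------------------------------------------------------

def derive_block_timing(params: AcquisitionParams) -> DerivedTiming:
    """Decompose the cycle into free-recovery gaps and GRE block durations.

    Uses the block-center convention: the recorded inversion time points at
    ``(n/2) * TR_exc`` after the start of each block, so
    ``TA = TI1 - (n/2)*TR_exc`` and ``TD = cycle_TR - TI_K - (n/2)*TR_exc``.
    """
    n, tr = params.n_excitations, params.excitation_tr_s
    block = n * tr
    half = 0.5 * n * tr
    tis = params.inversion_times_s
    ta = tis[0] - half
    gaps = tuple(tis[k + 1] - tis[k] - block for k in range(len(tis) - 1))
    td = params.cycle_tr_s - tis[-1] - half

    tol = -1e-12
    if ta < tol:
        raise InvalidProtocolError(f"pre-first-block gap TA = {ta:.6f} s is negative")
    for k, g in enumerate(gaps):
        if g < tol:
            raise InvalidProtocolError(f"inter-block gap {k + 1} = {g:.6f} s is negative")
    if td < tol:
        raise InvalidProtocolError(f"post-last-block gap TD = {td:.6f} s is negative")
    return DerivedTiming(max(ta, 0.0), tuple(max(g, 0.0) for g in gaps), max(td, 0.0), block)


# ---------------------------------------------------------------------------
# steady-state signal model
# ---------------------------------------------------------------------------

def _relax(t: float, t1):
    """Affine coefficients (A, B) for free recovery over time t."""
    e = np.exp(-t / t1)
    return e, 1.0 - e


def _block_periods(m: float, cos_flip, e1):
    """Affine coefficients for m consecutive excitation periods (m may be
    fractional) via the closed-form geometric series."""
    a1 = cos_flip * e1
    a = a1 ** m
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(np.isclose(a1, 1.0), m * (1.0 - e1), (1.0 - e1) * (1.0 - a) / (1.0 - a1))
    return a, b


def _compose(op2, op1):
    """Compose affine maps: apply op1 first, then op2."""
    a2, b2 = op2
    a1, b1 = op1
    return a2 * a1, a2 * b1 + b2


def _cycle_affine(params: AcquisitionParams, timing: DerivedTiming, t1, b1):
    """Affine map (A, B) of one full cycle, starting just before inversion."""
    eff = params.inversion_efficiency
    n = params.n_excitations
    e1 = np.exp(-params.excitation_tr_s / t1)
    op = (np.asarray(-eff, dtype=float), np.asarray(0.0))          # inversion
    op = _compose(_relax(timing.pre_first_block_s, t1), op)
    for k in range(params.n_blocks):
        cos_flip = np.cos(np.deg2rad(b1 * params.flip_deg[k]))
        op = _compose(_block_periods(float(n), cos_flip, e1), op)
        if k < params.n_blocks - 1:
            op = _compose(_relax(timing.inter_block_gaps_s[k], t1), op)
    op = _compose(_relax(timing.post_last_block_s, t1), op)
    return op


def steady_state_longitudinal(t1_s, params: AcquisitionParams, b1=1.0):
    """Steady-state Mz immediately before the inversion pulse.

    The cycle is affine, ``Mz -> A*Mz + B`` with ``|A| < 1``; the fixed point
    is ``B / (1 - A)``.  Broadcasts over arrays of ``t1_s`` and ``b1``.
    """
    t1 = np.asarray(t1_s, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    timing = derive_block_timing(params)
    a, b = _cycle_affine(params, timing, t1, np.asarray(b1, dtype=float))
    return b / (1.0 - a)


def mp2rage_signals(t1_s, params: AcquisitionParams, b1=1.0) -> np.ndarray:
    """Ideal (noiseless, real-valued) GRE signals at each block center.

    Parameters broadcast: ``t1_s`` and ``b1`` may be scalars or arrays of a
    common shape.  Returns an array of shape ``(K,) + broadcast_shape`` with
    M0 normalized to 1; signal k is ``sin(b1*alpha_k) * Mz`` at block-k
    center.
    """
    t1 = np.asarray(t1_s, dtype=float)
    b1a = np.asarray(b1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    timing = derive_block_timing(params)
    shape = np.broadcast_shapes(t1.shape, b1a.shape)
    t1, b1a = np.broadcast_to(t1, shape), np.broadcast_to(b1a, shape)

    mz = steady_state_longitudinal(t1, params, b1a)
    e1 = np.exp(-params.excitation_tr_s / t1)
    half = 0.5 * params.n_excitations

    # propagate from the fixed point through one cycle, sampling block centers
    mz = -params.inversion_efficiency * mz
    a, b = _relax(timing.pre_first_block_s, t1)
    mz = a * mz + b
    signals = np.empty((params.n_blocks,) + shape, dtype=float)
    for k in range(params.n_blocks):
        flip = np.deg2rad(b1a * params.flip_deg[k])
        cos_flip = np.cos(flip)
        a, b = _block_periods(half, cos_flip, e1)
        mz_center = a * mz + b
        signals[k] = np.sin(flip) * mz_center
        a, b = _block_periods(half, cos_flip, e1)
        mz = a * mz_center + b
        if k < params.n_blocks - 1:
            a, b = _relax(timing.inter_block_gaps_s[k], t1)
            mz = a * mz + b
    return signals


# ---------------------------------------------------------------------------
# uniform (T1-weighted) image combination
# ---------------------------------------------------------------------------

def uniform_signal(gre_i, gre_j) -> np.ndarray:
    """Combine two complex GREs into the uniform T1-weighted image.

    ``Re(conj(gre_i) * gre_j) / (|gre_i|^2 + |gre_j|^2)``, with 0/0 defined
    as 0.  The result is bounded in [-0.5, 0.5] (AM-GM inequality).
    """
    gi = np.asarray(gre_i, dtype=complex)
    gj = np.asarray(gre_j, dtype=complex)
    if gi.shape != gj.shape:
        raise ValueError(f"shape mismatch: {gi.shape} vs {gj.shape}")
    num = np.real(np.conj(gi) * gj)
    den = np.abs(gi) ** 2 + np.abs(gj) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def robust_uniform_signal(gre_i, gre_j, params: RobustImageParams = RobustImageParams()) -> np.ndarray:
    """Background-suppressed uniform image with additive denominator beta.

    ``beta = beta_fraction * mean(|gre_i|^2 + |gre_j|^2)`` over the volume.
    For registration-support imagery only; never used for T1 fitting.
    """
    gi = np.asarray(gre_i, dtype=complex)
    gj = np.asarray(gre_j, dtype=complex)
    if gi.shape != gj.shape:
        raise ValueError(f"shape mismatch: {gi.shape} vs {gj.shape}")
    ssq = np.abs(gi) ** 2 + np.abs(gj) ** 2
    beta = params.beta_fraction * float(np.mean(ssq))
    num = np.real(np.conj(gi) * gj)
    den = ssq + beta
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out
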