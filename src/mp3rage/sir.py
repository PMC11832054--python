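"""Selective inversion recovery (SIR) two-pool T1 model and fitting.

SIR samples the longitudinal recovery of a coupled two-pool system — free
water (f) and macromolecular protons (m) — at multiple inversion times.
With equal intrinsic relaxation rates (R1f = R1m = R1), the recovery of the
deviation from equilibrium ``M - M_inf`` follows

    d/dt (Mf, Mm) = -(R1*I + X) (M - M_inf),
    X = [[kfm, -kmf], [-kfm, kmf]],  kfm = psr * kmf,

whose eigen-rates are ``lambda1 = R1`` (eigenvector (kmf, kfm)) and
``lambda2 = R1 + kmf*(1 + psr)`` (eigenvector (1, -1)) — a biexponential
recovery.  The sequence model assumes complete saturation of both pools
after each readout, recovery over the constant pre-delay ``td``, scaling of
the pools by the inversion coefficients (Sf, Sm), and recovery over the
inversion time ``ti``; the observed signal is the free-pool magnetization
Mf(ti).  The reported T1 is ``1 / R1f``.

The macromolecular inversion coefficient Sm depends on B1+ through the
shaped inversion pulse and is consumed here as a lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .forward import B1Map
from .inference import T1MapResult

__all__ = [
    "SIRModelParams",
    "SmLookup",
    "SIRFitResult",
    "DEFAULT_TI_S",
    "DEFAULT_TD_S",
    "sir_signal",
    "fit_sir",
    "sir_t1_volume",
]

# canonical inversion-time grid (seconds) and pre-delay of the protocol
DEFAULT_TI_S: tuple[float, ...] = (
    0.006, 0.010, 0.016, 0.043, 0.068, 0.110, 0.178,
    0.288, 0.468, 0.760, 1.230, 2.000, 8.000,
)
DEFAULT_TD_S: float = 0.0025

# fit bounds: (r1 [1/s], psr, kmf [1/s], sf, m0f)
_LOWER = np.array([0.1, 0.0, 0.0, -1.0, 1e-12])
_UPPER = np.array([5.0, 0.5, 100.0, 0.0, np.inf])


@dataclass(frozen=True)
class SIRModelParams:
    """Two-pool SIR parameters under the R1f = R1m constraint."""

    r1_per_s: float
    psr: float = 0.1
    kmf_per_s: float = 10.0
    sf: float = -0.95
    sm: float = 0.83
    m0f: float = 1.0
    ti_s: tuple[float, ...] = DEFAULT_TI_S
    td_s: float = DEFAULT_TD_S

    def __post_init__(self):
        if self.r1_per_s <= 0:
            raise ValueError("r1 must be positive")
        if self.psr < 0 or self.kmf_per_s < 0:
            raise ValueError("psr and kmf must be non-negative")
        if not (-1.0 <= self.sf <= 1.0):
            raise ValueError("sf must lie in [-1, 1]")

    @property
    def t1_s(self) -> float:
        return 1.0 / self.r1_per_s

    @property
    def eigen_rates(self) -> tuple[float, float]:
        """Recovery eigen-rates (lambda1, lambda2), lambda2 >= lambda1."""
        return self.r1_per_s, self.r1_per_s + self.kmf_per_s * (1.0 + self.psr)


@dataclass
class SmLookup:
    """Monotone (B1 factor -> Sm) table, endpoint-clamped on interpolation."""

    b1: np.ndarray
    sm: np.ndarray

    def __post_init__(self):
        self.b1 = np.atleast_1d(np.asarray(self.b1, dtype=float))
        self.sm = np.atleast_1d(np.asarray(self.sm, dtype=float))
        if self.b1.size != self.sm.size:
            raise ValueError("b1 and sm must have equal length")
        if np.any(np.diff(self.b1) <= 0):
            raise ValueError("b1 values must be strictly increasing")

    @classmethod
    def constant(cls, sm: float = 0.83) -> "SmLookup":
        return cls(b1=np.array([1.0]), sm=np.array([sm]))

    def __call__(self, b1):
        # np.interp clamps to the table endpoints outside the domain
        return np.interp(np.asarray(b1, dtype=float), self.b1, self.sm)


@dataclass
class SIRFitResult:
    params: SIRModelParams
    residual_norm: float
    converged: bool
    flagged: bool = False
    message: str = ""

    @property
    def t1_s(self) -> float:
        return self.params.t1_s


def _recover_free(d0f, d0m, minf_f, minf_m, r1, psr, kmf, t):
    """Free-pool magnetization after recovering for time t from deviation d0.

    Decomposes the deviation onto the eigenvectors (kmf, kfm) at rate R1 and
    (1, -1) at rate R1 + kmf*(1+psr); degenerates to single-exponential
    recovery when both exchange rates vanish.  Broadcasts over arrays.
    """
    kfm = psr * kmf
    ktot = kmf + kfm
    lam2 = r1 + ktot
    e1 = np.exp(-r1 * t)
    scalar_k = np.ndim(ktot) == 0
    if scalar_k and ktot == 0:
        return minf_f + d0f * e1, minf_m + d0m * e1
    e2 = np.exp(-lam2 * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(ktot > 0, (d0f + d0m) / np.where(ktot > 0, ktot, 1.0), 0.0)
    c2f = d0f - c1 * kmf
    c2m = d0m - c1 * kfm
    mf = minf_f + c1 * kmf * e1 + c2f * e2
    mm = minf_m + c1 * kfm * e1 + c2m * e2
    if not scalar_k:
        mf = np.where(ktot > 0, mf, minf_f + d0f * e1)
        mm = np.where(ktot > 0, mm, minf_m + d0m * e1)
    return mf, mm


def sir_signal(p: SIRModelParams, ti=None):
    """Free-pool longitudinal signal Mf(ti) of the SIR sequence model.

    Both pools start saturated (M = 0) after the previous readout, recover
    for ``td``, are scaled by the inversion coefficients (Sf, Sm), and
    recover for ``ti``.  ``ti`` may be a scalar or array; defaults to the
    parameter set's sampling grid.
    """
    ti_arr = np.asarray(p.ti_s if ti is None else ti, dtype=float)
    r1, psr, kmf = p.r1_per_s, p.psr, p.kmf_per_s
    minf_f, minf_m = p.m0f, p.psr * p.m0f
    # saturation -> recovery over td
    mf_td, mm_td = _recover_free(-minf_f, -minf_m, minf_f, minf_m, r1, psr, kmf, p.td_s)
    # inversion scaling, then recovery over ti
    mf, _ = _recover_free(p.sf * mf_td - minf_f, p.sm * mm_td - minf_m,
                          minf_f, minf_m, r1, psr, kmf, ti_arr)
    return mf


def _sir_signal_theta(theta, sm, ti, td):
    """Vectorized model for the fitter: theta = (r1, psr, kmf, sf, m0f)."""
    r1, psr, kmf, sf, m0f = theta
    minf_f, minf_m = m0f, psr * m0f
    mf_td, mm_td = _recover_free(-minf_f, -minf_m, minf_f, minf_m, r1, psr, kmf, td)
    mf, _ = _recover_free(sf * mf_td - minf_f, sm * mm_td - minf_m,
                          minf_f, minf_m, r1, psr, kmf, ti)
    return mf


def fit_sir(
    signals,
    ti_s=DEFAULT_TI_S,
    td_s: float = DEFAULT_TD_S,
    sm: float = 0.83,
    p0: SIRModelParams | None = None,
    magnitude: bool = False,
    multi_start: int = 1,
) -> SIRFitResult:
    """Nonlinear least-squares fit of the two-pool SIR model to one voxel.

    Free parameters are (R1, PSR, kmf, Sf, M0f); Sm, td and the sampling
    grid are fixed.  ``magnitude=True`` fits |Mf| for polarity-free
    magnitude data.  ``multi_start > 1`` perturbs the initial guess
    deterministically and keeps the lowest-residual solution.
    Non-convergence or degenerate data flags the result instead of raising.
    """
    y = np.asarray(signals, dtype=float)
    ti = np.asarray(ti_s, dtype=float)
    if y.size != ti.size:
        raise ValueError("signals and ti_s must have equal length")
    if y.size < 6:
        raise ValueError("need at least 6 samples spanning early and late ti")
    spread = float(np.ptp(y))
    scale = float(np.max(np.abs(y)))
    if scale <= 0 or spread < 1e-9 * max(scale, 1.0):
        dummy = SIRModelParams(r1_per_s=1.0, sm=sm, ti_s=tuple(ti), td_s=td_s)
        return SIRFitResult(dummy, float("nan"), False, flagged=True,
                            message="degenerate signal: no decay information")

    if p0 is None:
        p0 = SIRModelParams(r1_per_s=1.0, psr=0.1, kmf_per_s=10.0, sf=-0.95,
                            sm=sm, m0f=scale, ti_s=tuple(ti), td_s=td_s)
    theta0 = np.array([p0.r1_per_s, p0.psr, p0.kmf_per_s, p0.sf, p0.m0f])

    def residuals(theta):
        model = _sir_signal_theta(theta, sm, ti, td_s)
        if magnitude:
            model = np.abs(model)
        return model - y

    # deterministic multi-start perturbations on (r1, m0f)
    factors = [(1.0, 1.0), (0.6, 1.0), (1.6, 1.0)][:max(1, multi_start)]
    best = None
    for fr, fm in factors:
        start = theta0 * np.array([fr, 1.0, 1.0, 1.0, fm])
        start = np.clip(start, _LOWER + 1e-12, np.where(np.isfinite(_UPPER), _UPPER - 1e-12, start))
        try:
            sol = least_squares(residuals, start, bounds=(_LOWER, _UPPER),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        dummy = SIRModelParams(r1_per_s=1.0, sm=sm, ti_s=tuple(ti), td_s=td_s)
        return SIRFitResult(dummy, float("nan"), False, flagged=True,
                            message="optimizer failure")
    r1, psr, kmf, sf, m0f = best.x
    fitted = SIRModelParams(r1_per_s=float(r1), psr=float(psr), kmf_per_s=float(kmf),
                            sf=float(sf), sm=sm, m0f=float(m0f),
                            ti_s=tuple(ti), td_s=td_s)
    return SIRFitResult(fitted, float(np.sqrt(2 * best.cost)), bool(best.success),
                        flagged=not best.success, message=best.message)


def sir_t1_volume(
    ir_volumes: np.ndarray,
    b1map: B1Map | None = None,
    sm_lookup: SmLookup | None = None,
    ti_s=DEFAULT_TI_S,
    td_s: float = DEFAULT_TD_S,
    magnitude: bool = False,
    voxel_mask: np.ndarray | None = None,
) -> T1MapResult:
    """Voxelwise SIR T1 fit of a 4-D volume (last axis ordered by ti).

    Sm is interpolated per voxel from the B1 map (endpoint-clamped);
    all-zero and failed voxels are masked rather than raised.
    """
    vols = np.asarray(ir_volumes, dtype=float)
    shape = vols.shape[:-1]
    if vols.shape[-1] != len(tuple(ti_s)):
        raise ValueError("last axis of ir_volumes must match ti_s")
    lookup = sm_lookup if sm_lookup is not None else SmLookup.constant()
    b1 = np.broadcast_to(np.asarray(b1map.data, dtype=float) if b1map is not None else 1.0, shape)

    t1 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    candidates = np.any(vols != 0, axis=-1)
    if voxel_mask is not None:
        candidates &= np.asarray(voxel_mask, dtype=bool)
    for idx in np.argwhere(candidates):
        key = tuple(idx)
        res = fit_sir(vols[key], ti_s=ti_s, td_s=td_s,
                      sm=float(lookup(b1[key])), magnitude=magnitude)
        if not res.flagged:
            t1[key] = res.t1_s
            valid[key] = True
    return T1MapResult(t1_s=t1, valid_mask=valid, method="sir")
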