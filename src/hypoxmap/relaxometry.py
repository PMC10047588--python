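"""Voxelwise quantitative MRI fitting: ADC, multi-echo T2, and variable-flip-angle T1.

Models
------
* Diffusion:  S(b)  = S0 * exp(-b * ADC)            (mono-exponential, b in s/mm^2)
* T2:         S(TE) = S0 * exp(-TE / T2)            (TE in ms)
* VFA T1 (spoiled gradient echo, steady state):
              S(a)  = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),  E1 = exp(-TR/T1)

ADC uses a log-linear least-squares fit.  T2 and T1 use a closed-form
linearization (log-linear / DESPOT1) refined by a damped Gauss-Newton
iteration that runs vectorized over all masked voxels, so whole-volume maps
fit in seconds.  Voxels whose fit leaves the configured physical bounds, or
whose signals are non-positive where a logarithm is needed, are flagged
invalid and excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import BinaryMask, ImageGrid, ScalarVolume

__all__ = [
    "SignalSeries",
    "FitMap",
    "fit_adc",
    "fit_t2",
    "fit_t1_vfa",
    "ADC_BOUNDS",
    "T2_BOUNDS_MS",
    "T1_BOUNDS_MS",
]

ADC_BOUNDS = (0.0, 1e-2)  # mm^2/s; free water ~3e-3
T2_BOUNDS_MS = (0.0, 5000.0)
T1_BOUNDS_MS = (0.0, 10000.0)


@dataclass
class SignalSeries:
    """An ordered stack of single-frame volumes sharing one grid.

    ``encoding`` holds the per-frame acquisition variable (b-value, flip angle,
    echo time, or frame time), sorted non-decreasing.  Repeated encoding values
    are allowed (signal averages); fitters average them before fitting.
    """

    frames: list[ScalarVolume]
    encoding: np.ndarray
    tr_ms: Optional[float] = None
    te_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a signal series needs at least 2 frames")
        self.encoding = np.asarray(self.encoding, dtype=float)
        if self.encoding.shape != (len(self.frames),):
            raise ValueError("one encoding value per frame required")
        if np.any(np.diff(self.encoding) < 0):
            raise ValueError("encoding values must be sorted ascending")
        g = self.frames[0].grid
        for fr in self.frames[1:]:
            if not fr.grid.same_geometry(g):
                raise ValueError("all frames must share one grid")

    @property
    def grid(self) -> ImageGrid:
        return self.frames[0].grid

    def stack(self) -> np.ndarray:
        """(n_frames, *shape) signal array."""
        return np.stack([fr.values for fr in self.frames], axis=0)

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Average frames sharing an encoding value -> (unique encodings, stack)."""
        enc, inverse = np.unique(self.encoding, return_inverse=True)
        data = self.stack()
        out = np.zeros((len(enc),) + data.shape[1:])
        counts = np.bincount(inverse, minlength=len(enc)).astype(float)
        for i, j in enumerate(inverse):
            out[j] += data[i]
        out /= counts.reshape((-1,) + (1,) * (data.ndim - 1))
        return enc, out


@dataclass
class FitMap:
    """Per-voxel model fit: parameter map, amplitude, residual RMS, validity."""

    parameter: ScalarVolume
    amplitude: ScalarVolume
    fit_error: ScalarVolume
    valid: BinaryMask

    def masked_values(self, mask: Optional[BinaryMask] = None) -> np.ndarray:
        sel = self.valid.membership
        if mask is not None:
            sel = sel & mask.membership
        return self.parameter.values[sel]


def _log_linear(enc: np.ndarray, sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-free LSQ of ln(sig) = ln(A) - enc * rate, vectorized over voxels.

    sig: (n_enc, n_vox), strictly positive.  Returns (A, rate)."""
    y = np.log(sig)
    x = enc.reshape(-1, 1)
    xm = x.mean()
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    slope = sxy / sxx
    intercept = ym - slope * xm
    return np.exp(intercept), -slope


def _gauss_newton_exp(
    t: np.ndarray, sig: np.ndarray, a0: np.ndarray, r0: np.ndarray, n_iter: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Refine S = A*exp(-r*t) by damped Gauss-Newton, vectorized over voxels."""
    A, r = a0.copy(), r0.copy()

    def cost(A, r):
        model = A[None, :] * np.exp(-np.outer(t, r))
        return ((model - sig) ** 2).sum(axis=0)

    c = cost(A, r)
    for _ in range(n_iter):
        E = np.exp(-np.outer(t, r))  # (nt, nv)
        model = A[None, :] * E
        res = sig - model
        JA = E
        Jr = -t[:, None] * model
        # 2x2 normal equations per voxel
        g11 = (JA * JA).sum(axis=0)
        g12 = (JA * Jr).sum(axis=0)
        g22 = (Jr * Jr).sum(axis=0)
        b1 = (JA * res).sum(axis=0)
        b2 = (Jr * res).sum(axis=0)
        det = g11 * g22 - g12**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        dA = (g22 * b1 - g12 * b2) / det
        dr = (g11 * b2 - g12 * b1) / det
        step = 1.0
        improved = np.zeros(A.shape, dtype=bool)
        A_new, r_new = A.copy(), r.copy()
        for _halve in range(6):
            cand_A = A + step * np.where(np.isfinite(dA), dA, 0.0)
            cand_r = r + step * np.where(np.isfinite(dr), dr, 0.0)
            c_cand = cost(cand_A, cand_r)
            better = (c_cand < c) & ~improved
            A_new[better] = cand_A[better]
            r_new[better] = cand_r[better]
            c[better] = c_cand[better]
            improved |= better
            step *= 0.5
            if improved.all():
                break
        A, r = A_new, r_new
    return A, r


def _empty_fitmap(grid: ImageGrid, units: str) -> dict:
    shape = grid.shape
    return dict(
        param=np.zeros(shape),
        amp=np.zeros(shape),
        err=np.zeros(shape),
        valid=np.zeros(shape, dtype=bool),
        units=units,
    )


def _assemble(grid, mask_idx, param, amp, err, ok, shape, units) -> FitMap:
    pmap = np.zeros(shape)
    amap = np.zeros(shape)
    emap = np.zeros(shape)
    vmap = np.zeros(shape, dtype=bool)
    pmap[mask_idx] = param
    amap[mask_idx] = amp
    emap[mask_idx] = err
    vmap[mask_idx] = ok
    return FitMap(
        parameter=ScalarVolume(grid, pmap, units=units),
        amplitude=ScalarVolume(grid, amap, units="arbitrary"),
        fit_error=ScalarVolume(grid, emap, units="arbitrary"),
        valid=BinaryMask(grid, vmap),
    )


def fit_adc(series: SignalSeries, mask: BinaryMask) -> FitMap:
    """Log-linear ADC fit over b-values; ADC in mm^2/s.

    Voxels with any non-positive signal in the series are invalid, as are
    fitted values outside ``ADC_BOUNDS``.
    """
    enc, data = series.averaged()
    if len(enc) < 2:
        raise ValueError("fit_adc needs at least 2 distinct b-values")
    if not mask.grid.same_geometry(series.grid):
        raise ValueError("mask grid must match series grid")
    mask_idx = np.nonzero(mask.membership)
    sig = data[(slice(None),) + mask_idx]  # (nb, nv)
    positive = (sig > 0).all(axis=0)
    safe = np.where(sig > 0, sig, 1.0)
    s0, adc = _log_linear(enc, safe)
    model = s0[None, :] * np.exp(-np.outer(enc, adc))
    err = np.sqrt(((model - sig) ** 2).mean(axis=0))
    ok = positive & (adc > ADC_BOUNDS[0]) & (adc <= ADC_BOUNDS[1]) & np.isfinite(adc)
    return _assemble(series.grid, mask_idx, adc, s0, err, ok, series.grid.shape, "mm^2/s")


def fit_t2(series: SignalSeries, mask: BinaryMask) -> FitMap:
    """Mono-exponential T2 fit over echo times (ms), log-linear init + Gauss-Newton.

    T2 bounded to (0, 5000] ms; non-decaying or non-positive-signal voxels are
    invalid (parameter clamped at the bound for inspection).
    """
    enc, data = series.averaged()
    if len(enc) < 2:
        raise ValueError("fit_t2 needs at least 2 distinct echo times")
    mask_idx = np.nonzero(mask.membership)
    sig = data[(slice(None),) + mask_idx]
    positive = (sig > 0).all(axis=0)
    safe = np.where(sig > 0, sig, 1.0)
    s0, r2 = _log_linear(enc, safe)
    s0, r2 = _gauss_newton_exp(enc, np.where(sig > 0, sig, 0.0), s0, r2)
    with np.errstate(divide="ignore"):
        t2 = np.where(r2 > 0, 1.0 / np.maximum(r2, 1e-300), np.inf)
    inside = (t2 > T2_BOUNDS_MS[0]) & (t2 <= T2_BOUNDS_MS[1])
    t2c = np.clip(t2, 1e-6, T2_BOUNDS_MS[1])
    model = s0[None, :] * np.exp(-np.outer(enc, 1.0 / t2c))
    err = np.sqrt(((model - sig) ** 2).mean(axis=0))
    ok = positive & inside & np.isfinite(t2) & (s0 > 0)
    return _assemble(series.grid, mask_idx, t2c, s0, err, ok, series.grid.shape, "ms")


def _spgr(m0: np.ndarray, e1: np.ndarray, sin_a: np.ndarray, cos_a: np.ndarray) -> np.ndarray:
    return m0[None, :] * sin_a[:, None] * (1 - e1[None, :]) / (1 - e1[None, :] * cos_a[:, None])


def fit_t1_vfa(series: SignalSeries, tr_ms: Optional[float] = None, mask: BinaryMask = None) -> FitMap:
    """VFA T1 fit: DESPOT1 linearization refined by Gauss-Newton on (M0, T1).

    Repeated frames at equal flip angles are averaged before fitting
    (signal-average acquisitions).  The linearization regresses S/sin(a) on
    S/tan(a); the slope is E1 = exp(-TR/T1).  T1 bounded to (0, 10000] ms.
    """
    if tr_ms is None:
        tr_ms = series.tr_ms
    if tr_ms is None or tr_ms <= 0:
        raise ValueError("fit_t1_vfa requires TR > 0")
    enc, data = series.averaged()
    if len(enc) < 2:
        raise ValueError("fit_t1_vfa needs at least 2 distinct flip angles")
    if np.any(enc <= 0) or np.any(enc > 90):
        raise ValueError("flip angles must lie in (0, 90] degrees")
    mask_idx = np.nonzero(mask.membership)
    sig = data[(slice(None),) + mask_idx]  # (na, nv)
    a_rad = np.deg2rad(enc)
    sin_a, cos_a, tan_a = np.sin(a_rad), np.cos(a_rad), np.tan(a_rad)
    y = sig / sin_a[:, None]
    x = sig / tan_a[:, None]
    xm, ym = x.mean(axis=0), y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = sxy / sxx
    e1 = np.where(np.isfinite(e1), e1, 0.0)
    intercept = ym - e1 * xm
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = intercept / (1 - e1)

    usable = (e1 > 0) & (e1 < 1) & (m0 > 0)
    e1f = np.where(usable, e1, 0.5)
    m0f = np.where(usable, m0, np.maximum(sig.max(axis=0), 1.0))
    m0f, e1f = _gn_spgr(sig, sin_a, cos_a, m0f, e1f)

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = -tr_ms / np.log(e1f)
    inside = (e1f > 0) & (e1f < 1) & np.isfinite(t1) & (t1 > T1_BOUNDS_MS[0]) & (t1 <= T1_BOUNDS_MS[1])
    t1c = np.where(inside, t1, np.clip(np.nan_to_num(t1, nan=T1_BOUNDS_MS[1], posinf=T1_BOUNDS_MS[1], neginf=1e-6), 1e-6, T1_BOUNDS_MS[1]))
    model = _spgr(m0f, e1f, sin_a, cos_a)
    err = np.sqrt(((model - sig) ** 2).mean(axis=0))
    # A signal that does not vary with flip angle carries no T1 information.
    varies = (sig.max(axis=0) - sig.min(axis=0)) > 1e-9 * np.maximum(sig.max(axis=0), 1.0)
    ok = usable & inside & (m0f > 0) & varies
    return _assemble(series.grid, mask_idx, t1c, m0f, err, ok, series.grid.shape, "ms")


def _gn_spgr(
    sig: np.ndarray, sin_a: np.ndarray, cos_a: np.ndarray,
    m0: np.ndarray, e1: np.ndarray, n_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Gauss-Newton on the SPGR model in (M0, E1), vectorized."""

    def cost(m0, e1):
        return ((_spgr(m0, np.clip(e1, 0.0, 1 - 1e-9), sin_a, cos_a) - sig) ** 2).sum(axis=0)

    c = cost(m0, e1)
    for _ in range(n_iter):
        e1c = np.clip(e1, 0.0, 1 - 1e-9)
        denom = 1 - e1c[None, :] * cos_a[:, None]
        model = _spgr(m0, e1c, sin_a, cos_a)
        res = sig - model
        Jm = model / np.where(m0[None, :] == 0, 1.0, m0[None, :])
        # d/dE1 [ (1-E1)/(1-E1 c) ] = (c - 1) / (1 - E1 c)^2
        Je = m0[None, :] * sin_a[:, None] * (cos_a[:, None] - 1) / denom**2
        g11 = (Jm * Jm).sum(axis=0)
        g12 = (Jm * Je).sum(axis=0)
        g22 = (Je * Je).sum(axis=0)
        b1 = (Jm * res).sum(axis=0)
        b2 = (Je * res).sum(axis=0)
        det = g11 * g22 - g12**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        dm = (g22 * b1 - g12 * b2) / det
        de = (g11 * b2 - g12 * b1) / det
        dm = np.where(np.isfinite(dm), dm, 0.0)
        de = np.where(np.isfinite(de), de, 0.0)
        step = 1.0
        improved = np.zeros(m0.shape, dtype=bool)
        m0_new, e1_new = m0.copy(), e1.copy()
        for _halve in range(6):
            cm = m0 + step * dm
            ce = np.clip(e1 + step * de, 0.0, 1 - 1e-9)
            cc = cost(cm, ce)
            better = (cc < c) & ~improved
            m0_new[better] = cm[better]
            e1_new[better] = ce[better]
            c[better] = cc[better]
            improved |= better
            step *= 0.5
            if improved.all():
                break
        m0, e1 = m0_new, e1_new
    return m0, e1
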