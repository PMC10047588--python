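"""Dynamic contrast-enhanced MRI pharmacokinetics: extended Tofts model.

The tissue concentration under the extended Tofts model is

    Ct(t) = vp * Cp(t) + Ktrans * int_0^t Cp(tau) exp(-kep (t - tau)) dtau,
    kep = Ktrans / ve,

driven by a Parker population arterial input function (AIF).  Signal is
converted to concentration through the spoiled-gradient-echo steady-state
equation using a baseline-normalized R1 inversion with a supplied T10 map,
C(t) = (R1(t) - R1(0)) / r1.

Fitting is a deterministic variable-projection scheme: for each candidate kep
the model is linear in (Ktrans, vp), solved by non-negative 2x2 least squares
vectorized over all voxels; the best kep per voxel from a log-spaced grid is
then refined by a vectorized golden-section search.  The convolution uses
exact piecewise-linear integration of Cp (no FFT), so results are
deterministic and grid-convergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import BinaryMask, ImageGrid, ScalarVolume
from .relaxometry import SignalSeries

__all__ = [
    "DceSeries",
    "Aif",
    "PkMap",
    "parker_aif",
    "signal_to_concentration",
    "extended_tofts_forward",
    "fit_extended_tofts",
]

# Parker et al. population AIF parameters (minutes / mM blood concentration).
_PARKER = dict(
    A1=0.809, A2=0.330, T1=0.17046, T2=0.365,
    s1=0.0563, s2=0.132, alpha=1.050, beta=0.1685, s=38.078, tau=0.483,
)

DEFAULT_HEMATOCRIT = 0.42
DEFAULT_RELAXIVITY = 3.6  # mM^-1 s^-1, gadoterate at 1.5 T


@dataclass
class DceSeries:
    """Dynamic series: uniformly sampled frames with a pre-contrast baseline."""

    series: SignalSeries  # encoding = frame times in seconds
    n_baseline: int = 5
    temporal_resolution_s: float = 10.0

    def __post_init__(self) -> None:
        n = len(self.series.frames)
        if not (1 <= self.n_baseline < n):
            raise ValueError("n_baseline must be >= 1 and smaller than the frame count")
        t = self.series.encoding
        if not np.allclose(np.diff(t), self.temporal_resolution_s, atol=1e-6):
            raise ValueError("frame times must be uniform at temporal_resolution_s")

    @property
    def times_s(self) -> np.ndarray:
        return self.series.encoding

    @property
    def grid(self) -> ImageGrid:
        return self.series.grid


@dataclass
class Aif:
    """Arterial input function: plasma concentration Cp(t) in mM."""

    times_s: np.ndarray
    cp_mM: np.ndarray
    hematocrit: float = DEFAULT_HEMATOCRIT

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.cp_mM = np.asarray(self.cp_mM, dtype=float)
        if self.times_s.shape != self.cp_mM.shape:
            raise ValueError("times and Cp must have equal length")
        if not (0 < self.hematocrit < 1):
            raise ValueError("hematocrit must lie in (0, 1)")
        if np.any(self.cp_mM < -1e-12) or not np.all(np.isfinite(self.cp_mM)):
            raise ValueError("Cp must be finite and non-negative")


def parker_aif(
    times_s: np.ndarray,
    arrival_s: float = 0.0,
    hematocrit: float = DEFAULT_HEMATOCRIT,
) -> Aif:
    """Parker population AIF sampled at ``times_s``, bolus arriving at ``arrival_s``.

    The Parker form gives whole-blood concentration; plasma concentration is
    Cb / (1 - hematocrit).  Cp = 0 before arrival.
    """
    t_min = (np.asarray(times_s, dtype=float) - arrival_s) / 60.0
    p = _PARKER
    cb = np.zeros_like(t_min)
    pos = t_min > 0
    tm = t_min[pos]
    g1 = p["A1"] / (p["s1"] * np.sqrt(2 * np.pi)) * np.exp(-((tm - p["T1"]) ** 2) / (2 * p["s1"] ** 2))
    g2 = p["A2"] / (p["s2"] * np.sqrt(2 * np.pi)) * np.exp(-((tm - p["T2"]) ** 2) / (2 * p["s2"] ** 2))
    washout = p["alpha"] * np.exp(-p["beta"] * tm) / (1 + np.exp(-p["s"] * (tm - p["tau"])))
    cb[pos] = g1 + g2 + washout
    cp = cb / (1.0 - hematocrit)
    return Aif(np.asarray(times_s, dtype=float), cp, hematocrit)


def _spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    e1 = np.exp(-tr_ms / t1_ms)
    a = np.deg2rad(flip_deg)
    return m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def signal_to_concentration(
    series: DceSeries,
    t10_map: ScalarVolume,
    relaxivity: float = DEFAULT_RELAXIVITY,
    tr_ms: float = 8.4,
    flip_deg: float = 25.0,
    mask: Optional[BinaryMask] = None,
) -> SignalSeries:
    """Invert the SPGR equation frame-by-frame to contrast concentration (mM).

    The pre-contrast baseline average fixes the effective M0*sin(a) scale per
    voxel given T10, then each frame's signal is solved for E1(t) -> R1(t) and
    C(t) = (R1(t) - R1(0)) / r1.  Voxels with non-positive T10 (or outside
    ``mask`` if given) are set to NaN.
    """
    if relaxivity <= 0:
        raise ValueError("relaxivity must be strictly positive")
    data = series.series.stack()  # (nt, *shape)
    nb = series.n_baseline
    t10 = t10_map.values
    ok = t10 > 0
    if mask is not None:
        ok = ok & mask.membership
    a = np.deg2rad(flip_deg)
    cos_a = np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e10 = np.where(ok, np.exp(-tr_ms / np.where(ok, t10, 1.0)), 0.0)
        s_base = data[:nb].mean(axis=0)
        # K = M0 sin(a); from baseline: S0 = K (1-E10)/(1-E10 cos a)
        K = s_base * (1 - e10 * cos_a) / np.where(ok, (1 - e10), 1.0)
        r10 = 1000.0 / np.where(ok, t10, np.inf)  # s^-1
        conc_frames = []
        for i in range(data.shape[0]):
            S = data[i]
            e1 = (K - S) / np.where(ok, (K - S * cos_a), 1.0)
            e1 = np.clip(e1, 1e-12, 1 - 1e-12)
            r1 = -np.log(e1) * 1000.0 / tr_ms  # s^-1
            c = (r1 - r10) / relaxivity
            c = np.where(ok, c, np.nan)
            conc_frames.append(ScalarVolume(series.grid, c, units="mM"))
    return SignalSeries(conc_frames, series.times_s)


def _pl_convolve(cp: np.ndarray, times_s: np.ndarray, kep_per_min) -> np.ndarray:
    """Exact convolution of piecewise-linear Cp with exp(-kep * t).

    ``kep_per_min`` may be a scalar or an array of per-voxel rates (min^-1);
    the result has shape (n_times,) or (n_times, n_vox).  Uses expm1-stable
    closed forms for each linear segment; the kep -> 0 limit is the running
    trapezoid integral.  Times in seconds, integration variable in minutes
    (so the result times Ktrans[min^-1] gives mM).
    """
    t = np.asarray(times_s, dtype=float) / 60.0
    kep = np.atleast_1d(np.asarray(kep_per_min, dtype=float))
    scalar = np.ndim(kep_per_min) == 0
    nv = kep.shape[0]
    nt = len(t)
    out = np.zeros((nt, nv))
    acc = np.zeros(nv)
    small = kep < 1e-12
    for k in range(1, nt):
        dt = t[k] - t[k - 1]
        a = cp[k - 1]
        b = (cp[k] - cp[k - 1]) / dt
        x = kep * dt
        E = np.exp(-x)
        with np.errstate(divide="ignore", invalid="ignore"):
            one_minus_E_over_k = np.where(small, dt, -np.expm1(-x) / np.where(small, 1.0, kep))
            # int_0^dt (a + b u) e^{-kep (dt - u)} du
            seg = a * one_minus_E_over_k + b * np.where(
                small, dt * dt / 2.0, (dt - one_minus_E_over_k) / np.where(small, 1.0, kep)
            )
        acc = acc * E + seg
        out[k] = acc
    return out[:, 0] if scalar else out


def extended_tofts_forward(
    aif: Aif, ktrans: float, ve: float, vp: float, times_s: np.ndarray
) -> np.ndarray:
    """Tissue concentration curve (mM) for one (Ktrans, ve, vp) triple.

    Reduces to the standard Tofts model at vp = 0 and to a pure blood-pool
    term at Ktrans = 0.
    """
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) < 0):
        raise ValueError("times must be sorted ascending")
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve must be > 0 when ktrans > 0")
    cp = np.interp(times_s, aif.times_s, aif.cp_mM)
    ct = vp * cp
    if ktrans > 0:
        kep = ktrans / ve
        ct = ct + ktrans * _pl_convolve(cp, times_s, kep)
    return ct


@dataclass
class PkMap:
    """Extended-Tofts parameter maps with per-voxel fit diagnostics."""

    ktrans: ScalarVolume  # min^-1
    kep: ScalarVolume  # min^-1
    ve: ScalarVolume  # fraction
    vp: ScalarVolume  # fraction
    fit_error: ScalarVolume
    valid: BinaryMask


def _nnls2(K: np.ndarray, cp: np.ndarray, ct: np.ndarray):
    """Non-negative LSQ of ct ~ x1*K + x2*cp per voxel (columns of K/ct).

    K, ct: (nt, nv); cp: (nt,).  Returns (x1, x2, sse)."""
    g11 = (K * K).sum(axis=0)
    g12 = (K * cp[:, None]).sum(axis=0)
    g22 = float((cp * cp).sum())
    b1 = (K * ct).sum(axis=0)
    b2 = (cp[:, None] * ct).sum(axis=0)
    ctct = (ct * ct).sum(axis=0)
    det = g11 * g22 - g12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        x1 = (g22 * b1 - g12 * b2) / det
        x2 = (g11 * b2 - g12 * b1) / det
        x1_only = np.where(g11 > 0, b1 / g11, 0.0)
        x2_only = np.where(g22 > 0, b2 / g22, 0.0)
    both_ok = np.isfinite(x1) & np.isfinite(x2) & (x1 >= 0) & (x2 >= 0)
    x1o = np.clip(x1_only, 0.0, None)
    x2o = np.clip(x2_only, 0.0, None)
    sse_both = ctct - (x1 * b1 + x2 * b2)
    sse_x1 = ctct - x1o * b1
    sse_x2 = ctct - x2o * b2
    use_x1 = ~both_ok & (sse_x1 <= sse_x2)
    out1 = np.where(both_ok, x1, np.where(use_x1, x1o, 0.0))
    out2 = np.where(both_ok, x2, np.where(use_x1, 0.0, x2o))
    sse = np.where(both_ok, sse_both, np.where(use_x1, sse_x1, sse_x2))
    return out1, out2, np.maximum(sse, 0.0)


def fit_extended_tofts(
    ct_series: SignalSeries,
    aif: Aif,
    mask: BinaryMask,
    kep_grid: Optional[np.ndarray] = None,
    n_refine: int = 40,
    error_ceiling: float = np.inf,
) -> PkMap:
    """Fit (Ktrans, ve, vp) per voxel by variable projection over kep.

    For each kep on a log-spaced grid the convolution basis is shared by all
    voxels and (Ktrans, vp) follow from non-negative linear least squares; the
    per-voxel best kep is then refined by golden-section search between its
    grid neighbours.  ve = Ktrans/kep.  Valid voxels satisfy Ktrans, kep >= 0,
    0 <= ve, vp <= 1 and fit RMS below ``error_ceiling``.  All-zero curves
    yield Ktrans = vp = 0 and are valid.
    """
    times = ct_series.encoding
    n_post = (times > aif.times_s[0]).sum()
    if len(times) < 12:
        raise ValueError("fit_extended_tofts needs a reasonable dynamic series")
    if aif.times_s.shape != times.shape or not np.allclose(aif.times_s, times, atol=1e-6):
        raise ValueError("AIF must be sampled on the series frame times")
    cp = aif.cp_mM
    data = ct_series.stack()
    mask_idx = np.nonzero(mask.membership)
    ct = data[(slice(None),) + mask_idx]  # (nt, nv)
    ct = np.nan_to_num(ct, nan=0.0)
    ct_fit = np.clip(ct, -0.5, None)  # tolerate small noise negatives
    nv = ct.shape[1]

    if kep_grid is None:
        kep_grid = np.concatenate([[0.0], np.geomspace(0.02, 15.0, 28)])

    best_sse = np.full(nv, np.inf)
    best_i = np.zeros(nv, dtype=int)
    best_kt = np.zeros(nv)
    best_vp = np.zeros(nv)
    for i, kep in enumerate(kep_grid):
        K = _pl_convolve(cp, times, float(kep))
        kt, vp, sse = _nnls2(K[:, None], cp, ct_fit)
        better = sse < best_sse - 1e-15
        best_sse[better] = sse[better]
        best_i[better] = i
        best_kt[better] = kt[better]
        best_vp[better] = vp[better]

    # Golden-section refinement of kep between the neighbouring grid points.
    lo_i = np.maximum(best_i - 1, 0)
    hi_i = np.minimum(best_i + 1, len(kep_grid) - 1)
    lo = np.asarray(kep_grid)[lo_i]
    hi = np.asarray(kep_grid)[hi_i]
    gr = (np.sqrt(5.0) - 1) / 2

    def sse_at(kep_vec):
        K = _pl_convolve(cp, times, kep_vec)  # (nt, nv)
        g11 = (K * K).sum(axis=0)
        g12 = (K * cp[:, None]).sum(axis=0)
        g22 = float((cp * cp).sum())
        b1 = (K * ct_fit).sum(axis=0)
        b2 = (cp[:, None] * ct_fit).sum(axis=0)
        ctct = (ct_fit * ct_fit).sum(axis=0)
        det = g11 * g22 - g12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            x1 = (g22 * b1 - g12 * b2) / det
            x2 = (g11 * b2 - g12 * b1) / det
            x1_only = np.where(g11 > 0, b1 / g11, 0.0)
        both_ok = np.isfinite(x1) & np.isfinite(x2) & (x1 >= 0) & (x2 >= 0)
        x1o = np.clip(x1_only, 0.0, None)
        x2o = np.clip(np.where(g22 > 0, b2 / g22, 0.0), 0.0, None)
        sse_both = ctct - (x1 * b1 + x2 * b2)
        sse_1 = ctct - x1o * b1
        sse_2 = ctct - x2o * b2
        use1 = ~both_ok & (sse_1 <= sse_2)
        kt = np.where(both_ok, x1, np.where(use1, x1o, 0.0))
        vp = np.where(both_ok, x2, np.where(use1, 0.0, x2o))
        sse = np.where(both_ok, sse_both, np.where(use1, sse_1, sse_2))
        return np.maximum(sse, 0.0), kt, vp

    a_, b_ = lo.copy(), hi.copy()
    c_ = b_ - gr * (b_ - a_)
    d_ = a_ + gr * (b_ - a_)
    fc, _, _ = sse_at(c_)
    fd, _, _ = sse_at(d_)
    for _ in range(n_refine):
        left = fc < fd
        b_ = np.where(left, d_, b_)
        a_ = np.where(left, a_, c_)
        c_ = b_ - gr * (b_ - a_)
        d_ = a_ + gr * (b_ - a_)
        fc, _, _ = sse_at(c_)
        fd, _, _ = sse_at(d_)
    kep_ref = (a_ + b_) / 2.0
    sse_ref, kt_ref, vp_ref = sse_at(kep_ref)
    take = sse_ref < best_sse
    kep_best = np.where(take, kep_ref, np.asarray(kep_grid)[best_i])
    kt_best = np.where(take, kt_ref, best_kt)
    vp_best = np.where(take, vp_ref, best_vp)
    sse_best = np.where(take, sse_ref, best_sse)

    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(kep_best > 0, kt_best / kep_best, 0.0)
    kep_out = np.where(kt_best > 0, kep_best, 0.0)
    rms = np.sqrt(sse_best / len(times))
    ok = (
        (kt_best >= 0)
        & (kep_out >= 0)
        & (ve >= 0)
        & (ve <= 1.0 + 1e-9)
        & (vp_best >= 0)
        & (vp_best <= 1.0 + 1e-9)
        & (rms <= error_ceiling)
    )

    grid = ct_series.grid
    shape = grid.shape

    def vol(vals, units):
        arr = np.zeros(shape)
        arr[mask_idx] = vals
        return ScalarVolume(grid, arr, units=units)

    vmap = np.zeros(shape, dtype=bool)
    vmap[mask_idx] = ok
    return PkMap(
        ktrans=vol(kt_best, "min^-1"),
        kep=vol(kep_out, "min^-1"),
        ve=vol(np.clip(ve, 0.0, 1.0), "fraction"),
        vp=vol(np.clip(vp_best, 0.0, 1.0), "fraction"),
        fit_error=vol(rms, "mM"),
        valid=BinaryMask(grid, vmap),
    )
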