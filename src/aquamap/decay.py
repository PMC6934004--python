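"""Voxel-wise extrapolation to TE = 0.

Mono-exponential decay fitting in the log domain, background-gradient
estimation from multi-echo phase, through-slice sinc correction and the
per-voxel echo-selection rules (half-intensity qualification for gradient
maps, 0.8*pi dephasing cutoff for the decay fit).
"""
from __future__ import annotations

import dataclasses

import numpy as np

from ._utils import sinc, wrap_phase
from .io import EchoSeriesVolume

__all__ = [
    "GradientMaps",
    "DecayMaps",
    "estimate_background_gradients",
    "select_echoes",
    "fit_monoexponential",
    "fit_monoexponential_nls",
    "sinc_corrected_fit",
    "fit_volume",
    "DEPHASING_LIMIT",
    "T2STAR_BOUNDS_MS",
]

#: maximum through-slice dephasing gamma*|gz|*dz*TE admitted into the fit
DEPHASING_LIMIT = 0.8 * np.pi
#: displayable T2* range; values outside are clamped and flagged
T2STAR_BOUNDS_MS = (1.0, 2000.0)
_SINC_FLOOR = 1e-6


@dataclasses.dataclass
class GradientMaps:
    """Estimated background field gradients, T/m, one volume per axis."""

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    n_echoes_used: np.ndarray
    valid: np.ndarray


@dataclasses.dataclass
class DecayMaps:
    """Voxel-wise decay-fit output."""

    s0: np.ndarray
    t2star_ms: np.ndarray
    r2star: np.ndarray        # s^-1, 1000/t2star_ms
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    echoes_used: np.ndarray
    rss: np.ndarray
    valid: np.ndarray


def estimate_background_gradients(series: EchoSeriesVolume,
                                  subtract_phi0: bool = True) -> GradientMaps:
    """Per-voxel background gradients from spatial phase differences.

    For each axis the forward phase difference to the next voxel is wrapped
    to (-pi, pi], divided by ``gamma * dx_i * TE_n`` and averaged over the
    qualifying echoes — those whose magnitude is at least half the
    first-echo magnitude of the voxel. With ``subtract_phi0`` (default) the
    first-echo phase is removed voxel-wise first and ``TE_n`` is replaced by
    ``TE_n - TE_1``, which cancels any TE-independent receive-phase offset;
    the literal per-echo form is kept as a mode for comparison.

    Voxels with no qualifying echo get zero gradients and are flagged
    invalid. The trailing voxel along each axis (no forward neighbor)
    copies its inner neighbor's gradient.
    """
    p = series.protocol
    if p.n_echoes < 2:
        raise ValueError("at least 2 echoes required")
    ph = series.phase
    te = p.te_s
    qual = series.magnitude >= 0.5 * series.magnitude[..., :1]
    if subtract_phi0:
        ph = wrap_phase(ph - ph[..., :1])
        te_eff = te - te[0]
        qual = qual.copy()
        qual[..., 0] = False
    else:
        te_eff = te
    inv_te = np.zeros_like(te_eff)
    np.divide(1.0, te_eff, out=inv_te, where=te_eff > 0)

    n_used = qual.sum(axis=-1)
    valid = n_used >= 1
    grads = []
    for ax, dx_mm in enumerate(p.voxel_mm):
        dphi = wrap_phase(np.diff(ph, axis=ax))
        per_echo = dphi * inv_te / (p.gamma * dx_mm * 1e-3)
        q = np.take(qual, np.arange(dphi.shape[ax]), axis=ax)
        n = q.sum(axis=-1)
        g = np.zeros(n.shape)
        np.divide((per_echo * q).sum(axis=-1), n, out=g, where=n > 0)
        last = np.take(g, [g.shape[ax] - 1], axis=ax)
        grads.append(np.concatenate([g, last], axis=ax))
    gx, gy, gz = (np.where(valid, g, 0.0) for g in grads)
    return GradientMaps(gx=gx, gy=gy, gz=gz, n_echoes_used=n_used, valid=valid)


def select_echoes(series: EchoSeriesVolume, gz: np.ndarray,
                  max_echoes: int | None = None) -> np.ndarray:
    """Per-voxel count of leading echoes whose through-slice dephasing
    ``gamma * |gz| * dz * TE_n`` stays within ``DEPHASING_LIMIT`` (0.8 pi),
    optionally capped at ``max_echoes``. Counts below 3 invalidate the voxel
    downstream."""
    p = series.protocol
    dz_m = p.voxel_mm[2] * 1e-3
    deph = p.gamma * np.abs(np.asarray(gz))[..., None] * dz_m * p.te_s
    counts = (deph <= DEPHASING_LIMIT).sum(axis=-1)  # TE increasing -> prefix
    if max_echoes is not None:
        counts = np.minimum(counts, max_echoes)
    return counts.astype(np.int32)


def _fit_loglinear(te_ms: np.ndarray, signal: np.ndarray, include: np.ndarray,
                   weights_mode: str = "intensity2",
                   t2_bounds_ms: tuple[float, float] = T2STAR_BOUNDS_MS):
    """Vectorized weighted least squares on ln(signal) vs TE.

    ``signal`` and ``include`` share shape (..., n_echoes). Returns
    (s0, t2star_ms, rss, n_included, valid); the log-domain RSS is
    unweighted over the included echoes.
    """
    x = np.asarray(te_ms, dtype=float)
    sig = np.asarray(signal, dtype=float)
    inc = np.asarray(include, bool) & (sig > 0) & np.isfinite(sig)
    y = np.where(inc, np.log(np.where(inc, sig, 1.0)), 0.0)
    if weights_mode == "intensity2":
        w = np.where(inc, sig * sig, 0.0)
    elif weights_mode == "uniform":
        w = inc.astype(float)
    else:
        raise ValueError(f"unknown weights_mode {weights_mode!r}")

    W = w.sum(axis=-1)
    Wx = (w * x).sum(axis=-1)
    Wy = (w * y).sum(axis=-1)
    Wxx = (w * x * x).sum(axis=-1)
    Wxy = (w * x * y).sum(axis=-1)
    denom = W * Wxx - Wx * Wx
    n_inc = inc.sum(axis=-1)
    ok = (n_inc >= 3) & (denom > 0)

    slope = np.zeros(W.shape)
    np.divide(W * Wxy - Wx * Wy, denom, out=slope, where=ok)
    t2_lo, t2_hi = t2_bounds_ms
    with np.errstate(divide="ignore"):
        t2 = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), t2_hi)
    t2 = np.clip(t2, t2_lo, t2_hi)
    b = -1.0 / t2
    a = np.zeros(W.shape)
    np.divide(Wy - b * Wx, W, out=a, where=ok)
    s0 = np.where(ok, np.exp(a), np.nan)
    resid = np.where(inc, y - a[..., None] - b[..., None] * x, 0.0)
    rss = np.where(ok, (resid * resid).sum(axis=-1), np.nan)
    t2 = np.where(ok, t2, np.nan)
    return s0, t2, rss, n_inc, ok


def fit_monoexponential(te_ms, signal, weights_mode: str = "intensity2",
                        t2_bounds_ms: tuple[float, float] = T2STAR_BOUNDS_MS):
    """Fit ``S(TE) = S0 exp(-TE/T2*)`` to one voxel's echoes.

    Weighted least squares on the log-transformed signal; intensity-squared
    weighting by default (maximum-likelihood approximation for
    log-transformed data in the Gaussian-dominated regime). Non-positive
    signals are excluded; fewer than 3 surviving echoes gives NaNs.

    Returns ``(s0, t2star_ms, rss)`` with rss in the log domain.
    """
    te_ms = np.asarray(te_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if te_ms.shape != signal.shape or te_ms.ndim != 1:
        raise ValueError("te_ms and signal must be 1D and the same length")
    s0, t2, rss, _, ok = _fit_loglinear(te_ms, signal, np.ones_like(signal, bool),
                                        weights_mode, t2_bounds_ms)
    if not ok:
        return float("nan"), float("nan"), float("nan")
    return float(s0), float(t2), float(rss)


def fit_monoexponential_nls(te_ms, signal, p0=None):
    """Nonlinear least-squares reference fit of the same model (slower;
    used for cross-checking the log-linear path)."""
    from scipy.optimize import curve_fit

    te_ms = np.asarray(te_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)
    keep = signal > 0
    if keep.sum() < 3:
        return float("nan"), float("nan")
    if p0 is None:
        s0_init, t2_init, _ = fit_monoexponential(te_ms, signal)
        if not np.isfinite(s0_init):
            s0_init, t2_init = float(signal[keep][0]), 50.0
        p0 = (s0_init, t2_init)
    popt, _ = curve_fit(lambda t, s0, t2: s0 * np.exp(-t / t2),
                        te_ms[keep], signal[keep], p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


def sinc_corrected_fit(te_ms, signal, gz: float, dz_mm: float,
                       gamma: float = None, **fit_kw):
    """Divide each echo by the through-slice sinc factor, then fit.

    Echoes where the sinc factor magnitude falls below 1e-6 are dropped
    (cannot occur under the 0.8*pi selection rule, which keeps the argument
    strictly below pi).
    """
    from .acquisition import GAMMA_PROTON

    gamma = GAMMA_PROTON if gamma is None else gamma
    te_ms = np.asarray(te_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)
    factor = sinc(0.5 * gamma * gz * dz_mm * 1e-3 * te_ms * 1e-3)
    keep = np.abs(factor) > _SINC_FLOOR
    corrected = np.where(keep, signal / np.where(keep, factor, 1.0), -1.0)
    s0, t2, rss, _, ok = _fit_loglinear(te_ms, corrected, keep, **fit_kw)
    if not ok:
        return float("nan"), float("nan"), float("nan")
    return float(s0), float(t2), float(rss)


def fit_volume(series: EchoSeriesVolume, correct_gradients: bool = True,
               subtract_phi0: bool = True, max_echoes: int | None = None,
               weights_mode: str = "intensity2",
               t2_bounds_ms: tuple[float, float] = T2STAR_BOUNDS_MS) -> DecayMaps:
    """Whole-volume decay fit.

    With ``correct_gradients`` the background gradients are estimated from
    phase, the per-voxel echo subset is chosen by the 0.8*pi dephasing rule,
    the through-slice sinc modulation is divided out and the log-linear fit
    is applied; without it a plain fit over (up to ``max_echoes``) echoes is
    performed. Deterministic for fixed input.
    """
    p = series.protocol
    mag = series.magnitude
    shape = series.shape
    n = p.n_echoes
    idx = np.arange(n)

    if correct_gradients:
        grads = estimate_background_gradients(series, subtract_phi0=subtract_phi0)
        counts = select_echoes(series, grads.gz, max_echoes=max_echoes)
        dz_m = p.voxel_mm[2] * 1e-3
        factor = sinc(0.5 * p.gamma * grads.gz[..., None] * dz_m * p.te_s)
        keep = np.abs(factor) > _SINC_FLOOR
        sig = np.where(keep, mag / np.where(keep, factor, 1.0), 0.0)
        include = (idx < counts[..., None]) & keep
    else:
        zeros = np.zeros(shape)
        grads = GradientMaps(gx=zeros, gy=zeros.copy(), gz=zeros.copy(),
                             n_echoes_used=np.full(shape, n, dtype=np.int32),
                             valid=np.ones(shape, bool))
        cap = n if max_echoes is None else min(n, max_echoes)
        counts = np.full(shape, cap, dtype=np.int32)
        sig = mag
        include = np.broadcast_to(idx < cap, mag.shape)

    s0, t2, rss, n_inc, ok = _fit_loglinear(p.te_ms, sig, include,
                                            weights_mode, t2_bounds_ms)
    r2star = np.full(shape, np.nan)
    np.divide(1000.0, t2, out=r2star, where=np.isfinite(t2) & (t2 > 0))
    return DecayMaps(s0=s0, t2star_ms=t2, r2star=r2star,
                     gx=grads.gx, gy=grads.gy, gz=grads.gz,
                     echoes_used=n_inc.astype(np.int32), rss=rss, valid=ok)
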