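"""Multiplicative bias-field removal via Gaussian-mixture segmentation.

The combined transmit/receive inhomogeneity of the extrapolated S0 map is
modeled as the exponential of a low-order cosine-basis (DCT) expansion and
estimated jointly with an intensity-only Gaussian mixture over tissue
classes: EM alternates mixture responsibilities, class-parameter updates
and a Gauss-Newton step on the log-bias coefficients, all maximizing one
log-likelihood. The DC coefficient is gauge-fixed so the bias field has
unit geometric mean over the fitted region. No atlas registration or
spatial priors are used — long-TR proton-density contrast separates the
classes on its own.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from ._utils import dct_basis

__all__ = [
    "SegmentationResult",
    "segment_and_debias",
    "brain_mask",
    "tissue_masks",
    "correct_bias",
]

TISSUE_ORDER = ("WM", "GM", "CSF")  # ascending proton-density contrast


@dataclasses.dataclass
class SegmentationResult:
    """Mixture segmentation plus estimated multiplicative bias field.

    ``prob`` has shape (nx, ny, nz, n_classes) with channels ordered by
    ascending bias-corrected class mean; ``class_labels`` names each channel
    (the top three are WM, GM, CSF, anything below is ``other``).
    Probabilities sum to 1 inside the fitted foreground region; outside,
    tissue channels are zero.
    """

    prob: np.ndarray
    bias: np.ndarray
    log_bias_coeffs: np.ndarray
    class_params: list[dict]
    class_labels: list[str]
    n_iter: int
    converged: bool
    fg_mask: np.ndarray
    log_likelihood: list[float]

    def prob_of(self, label: str) -> np.ndarray:
        return self.prob[..., self.class_labels.index(label)]


def _design_matrix(shape, order, coords=None):
    bx = dct_basis(shape[0], order)
    by = dct_basis(shape[1], order)
    bz = dct_basis(shape[2], order)
    xi, yi, zi = coords
    a = (bx[xi][:, :, None, None] * by[yi][:, None, :, None]
         * bz[zi][:, None, None, :])
    return a.reshape(len(xi), -1)


def _mixture_ll_and_resp(c, means, variances, weights):
    log_pdf = (-0.5 * (c[:, None] - means[None, :]) ** 2 / variances[None, :]
               - 0.5 * np.log(2 * np.pi * variances[None, :])
               + np.log(weights[None, :]))
    m = log_pdf.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
    resp = np.exp(log_pdf - lse[:, None])
    return float(lse.sum()), resp


def segment_and_debias(s0: np.ndarray, n_classes: int = 4, basis_order: int = 4,
                       max_iter: int = 200, tol: float = 1e-6, seed: int = 0,
                       fg_threshold: float = 0.05, warmup: int = 5,
                       var_floor_frac: float = 1e-6) -> SegmentationResult:
    """Jointly segment an S0 volume and estimate its smooth bias field.

    Parameters
    ----------
    s0 : 3D volume of TE=0 intensities (finite; non-positive voxels are
        treated as background).
    n_classes : number of Gaussian components (>= 2). The top three by
        corrected mean are labeled WM/GM/CSF.
    basis_order : DCT components per axis of the log-bias expansion.
    tol : relative log-likelihood change for convergence.
    seed : accepted for interface stability; initialization is a
        deterministic quantile placement so the seed currently has no
        effect on the result.
    fg_threshold : foreground cut as a fraction of the robust (99th
        percentile) maximum, so air does not dominate the mixture.
    """
    vol = np.asarray(s0, dtype=float)
    if vol.ndim != 3:
        raise ValueError("s0 must be a 3D volume")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    finite = np.isfinite(vol) & (vol > 0)
    if not np.any(finite):
        raise ValueError("s0 contains no positive finite voxels")
    robust_max = np.percentile(vol[finite], 99.0)
    fg = finite & (vol > fg_threshold * robust_max)
    if fg.sum() < 10 * n_classes:
        raise ValueError("too few foreground voxels to fit the mixture")

    y = vol[fg]
    coords = np.nonzero(fg)
    A = _design_matrix(vol.shape, basis_order, coords)
    n_coef = A.shape[1]

    # deterministic quantile initialization (seeded jitter not needed;
    # quantiles of the data already spread the components)
    del seed
    q = (np.arange(n_classes) + 0.5) / n_classes
    means = np.quantile(y, q)
    variances = np.full(n_classes, (np.std(y) / n_classes) ** 2 + 1e-12)
    weights = np.full(n_classes, 1.0 / n_classes)
    var_floor = var_floor_frac * np.var(y) + 1e-30

    beta = np.zeros(n_coef)
    logb = A @ beta
    ll_hist: list[float] = []
    converged = False
    n_iter = 0

    for it in range(1, max_iter + 1):
        n_iter = it
        c = y * np.exp(-logb)
        ll, resp = _mixture_ll_and_resp(c, means, variances, weights)
        ll_hist.append(ll)
        if len(ll_hist) >= 2:
            prev = ll_hist[-2]
            if abs(ll - prev) <= tol * abs(prev):
                converged = True
                break

        # M-step
        nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        means = (resp * c[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        variances = ((resp * (c[:, None] - means[None, :]) ** 2).sum(axis=0)
                     / np.maximum(nk, 1e-12))
        if np.any(variances < var_floor):
            warnings.warn("degenerate mixture component; variance floored",
                          RuntimeWarning, stacklevel=2)
            variances = np.maximum(variances, var_floor)

        # Gauss-Newton update of the log-bias coefficients
        if it > warmup:
            w_prec = (resp / variances[None, :]).sum(axis=1)
            err = (resp * (c[:, None] - means[None, :]) / variances[None, :]).sum(axis=1)
            g = A.T @ (c * err)                     # -grad of the LS objective
            h_diag_w = w_prec * c * c
            H = (A * h_diag_w[:, None]).T @ A
            H[np.diag_indices_from(H)] += 1e-8 * np.trace(H) / n_coef + 1e-30
            delta = np.linalg.solve(H, g)
            ll_cur, _ = _mixture_ll_and_resp(c, means, variances, weights)
            step = 1.0
            for _ in range(12):
                beta_try = beta + step * delta
                logb_try = A @ beta_try
                shift = logb_try.mean()
                beta_try[0] -= shift          # DC basis column is constant 1
                logb_try -= shift
                ll_try, _ = _mixture_ll_and_resp(y * np.exp(-logb_try),
                                                 means, variances, weights)
                if ll_try >= ll_cur - 1e-10:
                    beta, logb = beta_try, logb_try
                    break
                step *= 0.5
    else:  # pragma: no cover - loop exhausted without break
        pass

    if not converged and n_iter == max_iter:
        warnings.warn("segment_and_debias did not converge", RuntimeWarning,
                      stacklevel=2)

    # final responsibilities and class ordering
    c = y * np.exp(-logb)
    _, resp = _mixture_ll_and_resp(c, means, variances, weights)
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    resp = resp[:, order]

    labels = ["other%d" % i for i in range(n_classes - 3)] if n_classes > 3 else []
    labels += list(TISSUE_ORDER[-min(3, n_classes):])

    prob = np.zeros(vol.shape + (n_classes,))
    for k in range(n_classes):
        prob[..., k][fg] = resp[:, k]
    if n_classes > 3:
        prob[..., 0][~fg] = 1.0  # lowest-mean class doubles as background

    full_coords = np.nonzero(np.ones(vol.shape, bool))
    A_full = _design_matrix(vol.shape, basis_order, full_coords)
    bias = np.exp(A_full @ beta).reshape(vol.shape)

    params = [{"mean": float(m), "variance": float(v), "weight": float(w)}
              for m, v, w in zip(means, variances, weights)]
    return SegmentationResult(
        prob=prob, bias=bias,
        log_bias_coeffs=beta.reshape(basis_order, basis_order, basis_order),
        class_params=params, class_labels=labels, n_iter=n_iter,
        converged=converged, fg_mask=fg, log_likelihood=ll_hist)


def correct_bias(s0: np.ndarray, result: SegmentationResult) -> np.ndarray:
    """Divide out the estimated multiplicative field."""
    return np.asarray(s0, dtype=float) / result.bias


def brain_mask(result: SegmentationResult) -> np.ndarray:
    """Voxels with probability above 0.25 in any tissue class (WM/GM/CSF)."""
    probs = [result.prob_of(t) for t in TISSUE_ORDER if t in result.class_labels]
    return np.max(probs, axis=0) > 0.25


def tissue_masks(result: SegmentationResult,
                 threshold: float = 0.98) -> dict[str, np.ndarray]:
    """Exclusive high-confidence masks: tissue X is set where P_X >= 0.98
    and both other tissue probabilities are below 0.98."""
    present = [t for t in TISSUE_ORDER if t in result.class_labels]
    probs = {t: result.prob_of(t) for t in present}
    masks = {}
    for t in present:
        others = [probs[o] < threshold for o in present if o != t]
        m = probs[t] >= threshold
        for o in others:
            m = m & o
        masks[t] = m
    return masks
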