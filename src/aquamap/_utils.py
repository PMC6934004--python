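"""Small numerical helpers shared across modules."""
from __future__ import annotations

import numpy as np

__all__ = [
    "sinc",
    "wrap_phase",
    "dct_basis",
    "separable_field",
    "histogram_mode",
]


def sinc(x):
    """Unnormalized sinc, sin(x)/x with *x* in radians and sinc(0) = 1."""
    # np.sinc is the normalized variant sin(pi t)/(pi t)
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def wrap_phase(x):
    """Wrap angles to the half-open interval (-pi, pi]."""
    w = np.mod(np.asarray(x, dtype=float), 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


def dct_basis(n: int, order: int) -> np.ndarray:
    """Cosine basis matrix, shape ``(n, order)``.

    Column ``k`` is ``cos(pi * k * (2i + 1) / (2n))`` evaluated at sample
    ``i`` — the synthesis functions of the type-II DCT, so a field built from
    the first ``order`` columns has all of its DCT power in those components.
    Column 0 is the constant (DC) term.
    """
    i = np.arange(n)[:, None]
    k = np.arange(order)[None, :]
    return np.cos(np.pi * k * (2 * i + 1) / (2 * n))


def separable_field(coeffs: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Expand a 3D tensor of cosine coefficients into a volume of ``shape``."""
    coeffs = np.asarray(coeffs, dtype=float)
    bx = dct_basis(shape[0], coeffs.shape[0])
    by = dct_basis(shape[1], coeffs.shape[1])
    bz = dct_basis(shape[2], coeffs.shape[2])
    return np.einsum("ia,jb,kc,abc->ijk", bx, by, bz, coeffs, optimize=True)


def histogram_mode(values, bins: int = 128, central_pct: float = 99.0):
    """Mode of a sample estimated from a histogram with parabolic refinement.

    The histogram spans the central ``central_pct`` percent of the sample so
    stray outliers cannot stretch the binning. The mode is the vertex of the
    parabola through the tallest bin and its two neighbors, clamped to stay
    within half a bin of the peak.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("histogram_mode: empty sample")
    tail = (100.0 - central_pct) / 2.0
    lo, hi = np.percentile(v, [tail, 100.0 - tail])
    scale = max(abs(lo), abs(hi), 1e-300)
    if (hi - lo) <= 1e-9 * scale:  # degenerate (e.g. near-constant sample)
        return float(np.median(v))
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    i = int(np.argmax(counts))
    if i == 0 or i == bins - 1:
        return float(centers[i])
    c_m, c_0, c_p = counts[i - 1], counts[i], counts[i + 1]
    denom = c_m - 2.0 * c_0 + c_p
    if denom == 0:
        return float(centers[i])
    offset = 0.5 * (c_m - c_p) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    return float(centers[i] + offset * width)
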