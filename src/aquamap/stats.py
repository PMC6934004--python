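"""Tissue-class distribution summaries, test-retest variability,
distribution comparison and the oedema threshold rule."""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit

from ._utils import histogram_mode
from .calibration import WaterContentMap

__all__ = [
    "ClassStats",
    "TissueStats",
    "tissue_statistics",
    "voxelwise_retest",
    "oedema_mask",
    "compare_distributions",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclasses.dataclass
class ClassStats:
    mean: float
    sd: float
    gaussian_mean: float
    gaussian_fwhm: float
    n_voxels: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray


@dataclasses.dataclass
class TissueStats:
    classes: dict[str, ClassStats]
    ratio_gm_wm: float | None

    def to_dict(self) -> dict:
        out = {}
        for name, cs in self.classes.items():
            out[name] = {"mean": cs.mean, "sd": cs.sd,
                         "gaussian_mean": cs.gaussian_mean,
                         "gaussian_fwhm": cs.gaussian_fwhm,
                         "n_voxels": cs.n_voxels}
        if self.ratio_gm_wm is not None:
            out["ratio_gm_wm"] = self.ratio_gm_wm
        return out


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_histogram(edges: np.ndarray, counts: np.ndarray):
    """Least-squares Gaussian fit to a histogram; returns (center, fwhm).

    Falls back to (weighted mean, bin width) when the histogram is too
    concentrated (fewer than 3 occupied bins) for a stable fit.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    total = counts.sum()
    if total == 0:
        return float("nan"), float("nan")
    wmean = float((centers * counts).sum() / total)
    if (counts > 0).sum() < 3:
        return wmean, float(width)
    wsd = float(np.sqrt(((centers - wmean) ** 2 * counts).sum() / total))
    try:
        popt, _ = curve_fit(_gaussian, centers, counts,
                            p0=(counts.max(), wmean, max(wsd, width)),
                            maxfev=10000)
        return float(popt[1]), float(abs(popt[2]) * FWHM_PER_SIGMA)
    except RuntimeError:
        return wmean, float(wsd * FWHM_PER_SIGMA)


def tissue_statistics(wmap: WaterContentMap, bins: int = 64,
                      value_range: tuple[float, float] = (40.0, 110.0)) -> TissueStats:
    """Per-class histograms, Gaussian-fit centers/FWHM, arithmetic
    mean/sd, and the GM/WM mean ratio. Empty classes are skipped with a
    warning."""
    classes: dict[str, ClassStats] = {}
    for name in ("WM", "GM", "CSF"):
        mask = wmap.masks.get(name)
        if mask is None or not np.any(mask):
            warnings.warn(f"tissue class {name} empty; omitted", RuntimeWarning,
                          stacklevel=2)
            continue
        vals = wmap.h2o[mask]
        vals = vals[np.isfinite(vals)]
        counts, edges = np.histogram(vals, bins=bins, range=value_range)
        center, fwhm = fit_gaussian_histogram(edges, counts)
        classes[name] = ClassStats(
            mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            gaussian_mean=center, gaussian_fwhm=fwhm, n_voxels=int(vals.size),
            hist_edges=edges, hist_counts=counts)
    ratio = None
    if "WM" in classes and "GM" in classes and classes["WM"].mean != 0:
        ratio = classes["GM"].mean / classes["WM"].mean
    return TissueStats(classes=classes, ratio_gm_wm=ratio)


def voxelwise_retest(maps: list[WaterContentMap], mask: np.ndarray | None = None):
    """Per-voxel mean and sd of water content across aligned repeat maps.

    Alignment is the caller's responsibility (no registration is performed;
    synthetic repeats are aligned by construction). Returns
    ``(mean_map, sd_map, summary)`` with the summary holding the mean and
    the histogram mode of the sd within the mask.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    shapes = {m.h2o.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError("maps have mismatched grids; no registration is performed")
    stack = np.stack([m.h2o for m in maps])
    if mask is None:
        brain = [m.masks.get("brain") for m in maps if m.masks.get("brain") is not None]
        mask = np.logical_and.reduce(brain) if brain else np.ones(stack.shape[1:], bool)
    mean_map = stack.mean(axis=0)
    sd_map = stack.std(axis=0, ddof=1)
    sd_vals = sd_map[mask & np.isfinite(sd_map)]
    summary = {
        "n_maps": len(maps),
        "mean_sd": float(sd_vals.mean()),
        "mode_sd": histogram_mode(sd_vals, bins=128),
        "n_voxels": int(sd_vals.size),
    }
    return mean_map, sd_map, summary


def oedema_mask(wmap: WaterContentMap, wm_mean: float, wm_sd: float,
                k: float = 1.5) -> np.ndarray:
    """Voxels whose water content exceeds ``wm_mean + k * wm_sd``,
    restricted to the brain mask when available."""
    if wm_sd < 0:
        raise ValueError("wm_sd must be >= 0")
    mask = wmap.h2o > (wm_mean + k * wm_sd)
    brain = wmap.masks.get("brain")
    if brain is not None:
        mask = mask & brain
    return mask


def compare_distributions(sample_a, sample_b, method: str = "ks_two_sample"):
    """Two-sample distribution comparison; returns (statistic, p-value).

    ``ks_two_sample`` runs the Kolmogorov-Smirnov test on voxel samples;
    ``anova_means`` a one-way ANOVA. Reported, never used as an internal
    pass/fail gate.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("samples too small to compare")
    if method == "ks_two_sample":
        res = sps.ks_2samp(a, b)
    elif method == "anova_means":
        res = sps.f_oneway(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
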