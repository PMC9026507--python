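"""PSNR/SSIM image-quality metrics and the paired model comparison.

PSNR is 20*log10(MAX / RMSE) in dB; SSIM is the windowed structural
similarity index with an 11x11 Gaussian window (sigma 1.5) and the usual
stabilizers c1 = (k1*L)^2, c2 = (k2*L)^2 with k1 = 0.01, k2 = 0.03. Images in
the generator's [-1, 1] range are rescaled to [0, 1] before metric
computation, so the default dynamic range is 1. Model comparisons use the
two-sided Wilcoxon signed-rank test on paired per-image records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import convolve


@dataclass(frozen=True)
class MetricConfig:
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0  # L, after rescaling to [0, 1]
    psnr_max: float = 1.0  # MAX_x in the PSNR formula
    ssim_window: int = 11
    ssim_sigma: float = 1.5

    def __post_init__(self):
        if self.ssim_window % 2 == 0 or self.ssim_window < 3:
            raise ValueError("ssim_window must be an odd integer >= 3")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def _check_pair(x, x_hat):
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return x, x_hat


def rescale_unit(image) -> np.ndarray:
    """Map a [-1, 1] image onto the [0, 1] metric scale."""
    return (np.asarray(image, dtype=np.float64) + 1.0) / 2.0


def psnr(x, x_hat, config: MetricConfig = MetricConfig()) -> float:
    """Peak signal-to-noise ratio in dB; identical images give math.inf."""
    x, x_hat = _check_pair(x, x_hat)
    rmse = math.sqrt(float(np.mean((x - x_hat) ** 2)))
    if rmse == 0.0:
        return math.inf
    return 20.0 * math.log10(config.psnr_max / rmse)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(x, x_hat, config: MetricConfig = MetricConfig(),
         return_map: bool = False):
    """Mean structural similarity over Gaussian-weighted local windows.

    Local means, variances and covariance are weighted by the window; the map
    is evaluated where the window fits entirely inside the image and averaged.
    """
    x, x_hat = _check_pair(x, x_hat)
    win = config.ssim_window
    if min(x.shape) < win:
        raise ValueError(f"window {win} larger than image {x.shape}")
    kernel = _gaussian_kernel(win, config.ssim_sigma)

    def filt(img):
        return convolve(img, kernel, mode="constant")

    pad = win // 2
    crop = (slice(pad, x.shape[0] - pad), slice(pad, x.shape[1] - pad))
    mu_x = filt(x)[crop]
    mu_y = filt(x_hat)[crop]
    sxx = filt(x * x)[crop] - mu_x**2
    syy = filt(x_hat * x_hat)[crop] - mu_y**2
    sxy = filt(x * x_hat)[crop] - mu_x * mu_y
    c1, c2 = config.c1, config.c2
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * sxy + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2))
    if return_map:
        return ssim_map
    return float(ssim_map.mean())


def paired_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-image metrics.

    Exact null distribution for n <= 25 without zero differences; otherwise
    the normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired records")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    diffs = a - b
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero; "
                         "the signed-rank test is degenerate")
    method = "exact" if (len(a) <= 25 and not np.any(diffs == 0)) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


@dataclass
class MetricTable:
    """Per-image PSNR/SSIM records and their mean +/- std summary."""

    records: pd.DataFrame  # columns: method, direction, index, psnr, ssim
    summary: pd.DataFrame  # mean/std per (method, direction, metric)

    def per_image(self, method: str, direction: str, metric: str) -> np.ndarray:
        sel = self.records[(self.records.method == method)
                           & (self.records.direction == direction)]
        return sel.sort_values("index")[metric].to_numpy()

    def formatted(self) -> str:
        lines = []
        for (method, direction), grp in self.summary.groupby(
                ["method", "direction"], sort=False):
            row = grp.set_index("metric")
            lines.append(
                f"{method:12s} {direction}: "
                f"PSNR {row.loc['psnr','mean']:.3f} +/- {row.loc['psnr','std']:.3f}  "
                f"SSIM {row.loc['ssim','mean']:.3f} +/- {row.loc['ssim','std']:.3f}")
        return "\n".join(lines)


def evaluate(pairs_by_direction: dict, config: MetricConfig = MetricConfig(),
             method: str = "model", assume_unit_range: bool = True) -> MetricTable:
    """Score registered (synthesized, target) pairs per direction.

    ``pairs_by_direction`` maps a direction label (e.g. 'a2b') to a list of
    (synthesized, target) image pairs. With ``assume_unit_range`` the images
    are taken to be in [-1, 1] and rescaled to [0, 1] first. Infinite PSNR
    values (identical pairs) are kept in the per-image records but excluded
    from the mean/std with a warning.
    """
    rows = []
    for direction, pairs in pairs_by_direction.items():
        if not pairs:
            raise ValueError(f"no image pairs for direction {direction!r}")
        for i, (synth, target) in enumerate(pairs):
            if assume_unit_range:
                synth, target = rescale_unit(synth), rescale_unit(target)
            rows.append({
                "method": method,
                "direction": direction,
                "index": i,
                "psnr": psnr(target, synth, config),
                "ssim": ssim(target, synth, config),
            })
    records = pd.DataFrame(rows)
    summary_rows = []
    for (m, d), grp in records.groupby(["method", "direction"], sort=False):
        for metric in ("psnr", "ssim"):
            vals = grp[metric].to_numpy()
            finite = vals[np.isfinite(vals)]
            if len(finite) < len(vals):
                warnings.warn(
                    f"{len(vals) - len(finite)} infinite {metric} value(s) "
                    f"excluded from the {m}/{d} summary", stacklevel=2)
            summary_rows.append({
                "method": m, "direction": d, "metric": metric,
                "mean": float(np.mean(finite)),
                "std": float(np.std(finite, ddof=0)),
                "n": len(vals),
            })
    return MetricTable(records=records, summary=pd.DataFrame(summary_rows))


def combine_tables(tables) -> MetricTable:
    """Stack per-method MetricTables into one (Table-1-style) comparison."""
    return MetricTable(
        records=pd.concat([t.records for t in tables], ignore_index=True),
        summary=pd.concat([t.summary for t in tables], ignore_index=True),
    )
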