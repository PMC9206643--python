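"""Quantitative comparison of virtual and true H&E in CIELAB.

Both images are converted to the perceptually correlated Lab color space
(sRGB companding, D65 standard observer) before computing patchwise SSIM
and RMSE over randomly sampled square patches; the report aggregates
mean +- sd. SSIM is computed per Lab channel (dynamic range 100 on L, 255
on a/b) and averaged; RMSE is pooled over the three Lab channels. Units of
the reported RMSE are native Lab units and are recorded in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.color import rgb2lab

from .core import StainedImage

__all__ = ["MetricsReport", "rgb_to_lab", "ssim", "rmse", "evaluate_pair"]

#: SSIM dynamic range per Lab channel (L; a; b).
LAB_RANGES = (100.0, 255.0, 255.0)


@dataclass
class MetricsReport:
    ssim_mean: float
    ssim_sd: float
    rmse_mean: float
    rmse_sd: float
    n_patches: int
    patch_px: int
    color_space: str = "CIELAB (D65, sRGB companding); RMSE in native Lab units"
    seed: int | None = None
    ssim_channel_handling: str = "per-channel SSIM averaged over (L, a, b)"
    rmse_channel_handling: str = "pooled over (L, a, b)"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ssim_mean <= 1.0):
            raise ValueError("ssim_mean must lie in [-1, 1]")
        if self.rmse_mean < 0:
            raise ValueError("rmse_mean must be nonnegative")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __str__(self) -> str:
        return (
            f"SSIM {self.ssim_mean:.4f} +- {self.ssim_sd:.4f} | "
            f"RMSE {self.rmse_mean:.4f} +- {self.rmse_sd:.4f} "
            f"({self.n_patches} patches of {self.patch_px} px, {self.color_space})"
        )


def rgb_to_lab(image: StainedImage | np.ndarray) -> np.ndarray:
    """sRGB in [0, 1] -> CIELAB (D65): L in [0, 100], a/b roughly
    [-128, 127]. Out-of-range input is clipped with a warning."""
    rgb = image.rgb if isinstance(image, StainedImage) else np.asarray(image, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if rgb.min() < 0 or rgb.max() > 1:
        warnings.warn("RGB values outside [0, 1]; clipping before Lab conversion")
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb2lab(rgb)


def ssim(a: np.ndarray, b: np.ndarray, window_px: int = 7, dynamic_range: float = 1.0) -> float:
    """Mean structural similarity over sliding windows.

    Standard luminance-contrast-structure form with stabilizing constants
    ``C1 = (0.01 R)^2``, ``C2 = (0.03 R)^2`` for dynamic range ``R``;
    uniform ``window_px`` window, sample (unbiased) covariances, mean taken
    over windows fully inside the image. Symmetric and bounded in [-1, 1];
    ``ssim(x, x) == 1`` for any x.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("inputs must share a shape")
    if a.ndim != 2:
        raise ValueError("ssim operates on single-channel rasters")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    if min(a.shape) < window_px:
        raise ValueError("image smaller than the SSIM window")

    npx = window_px * window_px
    cov_norm = npx / (npx - 1)  # unbiased sample covariance
    ux = uniform_filter(a, window_px)
    uy = uniform_filter(b, window_px)
    uxx = uniform_filter(a * a, window_px)
    uyy = uniform_filter(b * b, window_px)
    uxy = uniform_filter(a * b, window_px)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)

    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    num = (2 * ux * uy + c1) * (2 * vxy + c2)
    den = (ux**2 + uy**2 + c1) * (vx + vy + c2)
    smap = num / den
    pad = (window_px - 1) // 2
    return float(smap[pad : smap.shape[0] - pad, pad : smap.shape[1] - pad].mean())


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square error over all pixels (and channels, if present)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("inputs must share a shape")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def evaluate_pair(
    pred: StainedImage | np.ndarray,
    truth: StainedImage | np.ndarray,
    n_patches: int = 1000,
    patch_px: int = 256,
    seed: int = 0,
    window_px: int = 7,
) -> MetricsReport:
    """Patchwise Lab-space SSIM/RMSE between aligned equal-shape images.

    ``n_patches`` patch locations are sampled uniformly with replacement
    (seeded). Per patch: SSIM per Lab channel at its dynamic range,
    averaged; RMSE pooled over channels. If the images are smaller than
    ``patch_px``, the patch size is reduced to fit with a warning.
    """
    lab_p = rgb_to_lab(pred)
    lab_t = rgb_to_lab(truth)
    if lab_p.shape != lab_t.shape:
        raise ValueError("images must share a shape")
    h, w = lab_p.shape[:2]
    if patch_px > min(h, w):
        warnings.warn(
            f"patch_px {patch_px} exceeds image extent {min(h, w)}; reducing"
        )
        patch_px = min(h, w)
    if patch_px < window_px:
        raise ValueError("patch smaller than the SSIM window")

    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - patch_px + 1, n_patches)
    cols = rng.integers(0, w - patch_px + 1, n_patches)
    ssims = np.empty(n_patches)
    rmses = np.empty(n_patches)
    for i, (r, c) in enumerate(zip(rows, cols)):
        pp = lab_p[r : r + patch_px, c : c + patch_px]
        pt = lab_t[r : r + patch_px, c : c + patch_px]
        ssims[i] = np.mean(
            [
                ssim(pp[:, :, k], pt[:, :, k], window_px, LAB_RANGES[k])
                for k in range(3)
            ]
        )
        rmses[i] = rmse(pp, pt)
    sd = (lambda v: float(np.std(v, ddof=1)) if n_patches > 1 else 0.0)
    return MetricsReport(
        ssim_mean=float(ssims.mean()),
        ssim_sd=sd(ssims),
        rmse_mean=float(rmses.mean()),
        rmse_sd=sd(rmses),
        n_patches=int(n_patches),
        patch_px=int(patch_px),
        seed=seed,
    )
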