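"""Differentiable image-quality terms: SSIM, MS-SSIM and the mixed
MS-SSIM + Gaussian-weighted L1 training loss.

All functions take NCHW Tensors with values on the normalized [0, 1]
scale and return scalar (or map) Tensors that participate in the
autograd graph, so they can be used directly as training objectives.
"""

from __future__ import annotations

import logging

import numpy as np

from .tensor import Tensor

logger = logging.getLogger(__name__)

__all__ = ["gaussian_kernel", "ssim_parts", "ms_ssim", "gaussian_l1",
           "msssim_l1", "MS_SSIM_WEIGHTS", "WINDOW_SIZE", "WINDOW_SIGMA"]

WINDOW_SIZE = 11
WINDOW_SIGMA = 1.5
K1, K2 = 0.01, 0.03
#: Canonical five-scale weights of the multi-scale SSIM formulation.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def gaussian_kernel(size: int = WINDOW_SIZE, sigma: float = WINDOW_SIGMA) -> np.ndarray:
    """Normalized 2-D Gaussian window."""
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _window_tensor(channels: int, size: int, sigma: float) -> Tensor:
    k = gaussian_kernel(size, sigma)
    w = np.zeros((channels, channels, size, size))
    for c in range(channels):
        w[c, c] = k
    return Tensor(w)


def _filter(x: Tensor, window: Tensor) -> Tensor:
    # valid convolution: statistics only where the window fits entirely
    return x.conv2d(window, padding=0)


def ssim_parts(pred: Tensor, target: Tensor, data_range: float = 1.0,
               size: int = WINDOW_SIZE, sigma: float = WINDOW_SIGMA
               ) -> tuple[Tensor, Tensor]:
    """Per-pixel SSIM map and contrast-structure (cs) map."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    n, c, h, w = pred.shape
    if min(h, w) < size:
        raise ValueError(
            f"image side {min(h, w)} smaller than SSIM window {size}")
    win = _window_tensor(c, size, sigma)
    c1 = (K1 * data_range) ** 2
    c2 = (K2 * data_range) ** 2
    mu1 = _filter(pred, win)
    mu2 = _filter(target, win)
    mu1_sq, mu2_sq, mu12 = mu1 * mu1, mu2 * mu2, mu1 * mu2
    sigma1_sq = _filter(pred * pred, win) - mu1_sq
    sigma2_sq = _filter(target * target, win) - mu2_sq
    sigma12 = _filter(pred * target, win) - mu12
    cs = (2.0 * sigma12 + c2) / (sigma1_sq + sigma2_sq + c2)
    ssim_map = ((2.0 * mu12 + c1) / (mu1_sq + mu2_sq + c1)) * cs
    return ssim_map, cs


def supported_levels(h: int, w: int, size: int = WINDOW_SIZE,
                     max_levels: int = len(MS_SSIM_WEIGHTS)) -> int:
    """Largest pyramid depth with window-sized images at the coarsest level."""
    levels = 0
    side = min(h, w)
    while levels < max_levels and side >= size:
        levels += 1
        side //= 2
    return levels


def ms_ssim(pred: Tensor, target: Tensor, data_range: float = 1.0,
            weights: tuple[float, ...] = MS_SSIM_WEIGHTS) -> Tensor:
    """Multi-scale SSIM; the pyramid depth shrinks automatically for
    images too small for the requested number of scales."""
    n, c, h, w = pred.shape
    levels = supported_levels(h, w, max_levels=len(weights))
    if levels == 0:
        raise ValueError(
            f"image side {min(h, w)} below the minimum of {WINDOW_SIZE} "
            f"pixels required by the SSIM window")
    if levels < len(weights):
        logger.info("MS-SSIM reduced from %d to %d scales for %dx%d input",
                    len(weights), levels, h, w)
    wts = np.asarray(weights[:levels], dtype=np.float64)
    wts = wts / wts.sum()
    terms: list[Tensor] = []
    x, y = pred, target
    for lv in range(levels):
        ssim_map, cs_map = ssim_parts(x, y, data_range)
        if lv < levels - 1:
            terms.append(cs_map.relu().mean() ** wts[lv])
            _, _, lh, lw = x.shape
            if lh % 2 or lw % 2:  # drop the odd row/column before pooling
                x = x.crop2d(lh - lh % 2, lw - lw % 2)
                y = y.crop2d(lh - lh % 2, lw - lw % 2)
            x = x.avg_pool2d(2)
            y = y.avg_pool2d(2)
        else:
            terms.append(ssim_map.relu().mean() ** wts[lv])
    out = terms[0]
    for t in terms[1:]:
        out = out * t
    return out


def gaussian_l1(pred: Tensor, target: Tensor,
                size: int = WINDOW_SIZE, sigma: float = WINDOW_SIGMA) -> Tensor:
    """Mean of the Gaussian-window-filtered absolute error."""
    n, c, h, w = pred.shape
    if min(h, w) < size:
        raise ValueError(
            f"image side {min(h, w)} smaller than SSIM window {size}")
    win = _window_tensor(c, size, sigma)
    return _filter((pred - target).abs(), win).mean()


def msssim_l1(pred: Tensor, target: Tensor, alpha: float = 0.84,
              data_range: float = 1.0) -> Tensor:
    """alpha * (1 - MS-SSIM) + (1 - alpha) * Gaussian-weighted L1."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if alpha == 0.0:
        return gaussian_l1(pred, target)
    ms_term = 1.0 - ms_ssim(pred, target, data_range)
    if alpha == 1.0:
        return ms_term
    return alpha * ms_term + (1.0 - alpha) * gaussian_l1(pred, target)
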