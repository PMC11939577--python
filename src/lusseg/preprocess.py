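"""Image-enhancement chain for B-mode lung ultrasound frames.

Three stages, applied in this order on [0,1] grayscale images:

1. non-local means denoising — suppresses speckle while preserving the bright
   line artifacts (patchwise self-similarity averaging);
2. CLAHE — contrast-limited adaptive histogram equalization, lifting faint
   A-/B-lines out of the low-contrast far field;
3. unsharp masking — ``img + amount * (img - gaussian(img, sigma))``,
   sharpening artifact edges that speckle and beam-width blur soften.

Denoising precedes contrast enhancement and sharpening so that neither of the
latter amplifies speckle.  Every stage maps [0,1] to [0,1] (clipped), keeps
the shape, and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, restoration

__all__ = ["PreprocessConfig", "nlm_denoise", "clahe", "unsharp_mask",
           "preprocess"]


@dataclass
class PreprocessConfig:
    """Filter parameters; intensities are on the [0,1] scale.

    ``clahe_clip`` follows the common 8-bit convention (multiples of the mean
    per-bin count with 256 bins; 2.0 is the usual ultrasound setting) and is
    converted internally to the equivalent [0,1] clip fraction.
    """

    nlm_strength: float = 0.08
    nlm_patch: int = 7
    nlm_search: int = 21
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    unsharp_sigma: float = 1.0
    unsharp_amount: float = 1.0

    def __post_init__(self) -> None:
        for name in ("nlm_patch", "nlm_search"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {v}")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")
        if self.unsharp_sigma < 0:
            raise ValueError("unsharp_sigma must be non-negative")
        if self.unsharp_amount < 0:
            raise ValueError("unsharp_amount must be non-negative")


def _check_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def nlm_denoise(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Non-local means speckle reduction."""
    cfg = cfg or PreprocessConfig()
    arr = _check_image(img)
    if cfg.nlm_strength == 0:
        return np.clip(arr, 0.0, 1.0)
    out = restoration.denoise_nl_means(
        arr, h=cfg.nlm_strength, patch_size=cfg.nlm_patch,
        patch_distance=(cfg.nlm_search - 1) // 2, fast_mode=True)
    return np.clip(out, 0.0, 1.0)


def clahe(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (256 bins)."""
    cfg = cfg or PreprocessConfig()
    arr = _check_image(img)
    ty, tx = cfg.clahe_tiles
    kh, kw = arr.shape[0] // ty, arr.shape[1] // tx
    if kh < 1 or kw < 1:
        raise ValueError(
            f"CLAHE tile grid {cfg.clahe_tiles} larger than image {arr.shape}")
    out = exposure.equalize_adapthist(
        np.clip(arr, 0.0, 1.0), kernel_size=(kh, kw),
        clip_limit=cfg.clahe_clip / 256.0, nbins=256)
    return np.clip(out, 0.0, 1.0)


def unsharp_mask(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Edge sharpening by subtracting a Gaussian-blurred copy."""
    cfg = cfg or PreprocessConfig()
    arr = _check_image(img)
    if cfg.unsharp_amount == 0 or cfg.unsharp_sigma == 0:
        return np.clip(arr, 0.0, 1.0)
    blurred = ndimage.gaussian_filter(arr, sigma=cfg.unsharp_sigma)
    return np.clip(arr + cfg.unsharp_amount * (arr - blurred), 0.0, 1.0)


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: denoise, then contrast-enhance, then sharpen."""
    cfg = cfg or PreprocessConfig()
    return unsharp_mask(clahe(nlm_denoise(img, cfg), cfg), cfg)
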